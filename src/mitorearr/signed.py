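"""Generic signed circular sequences.

Breakpoint and cluster computations are defined for any circular sequence of
signed, unique labels, not only for full 37-gene mitogenomes; toy circles
like ``(1, 2, -3, 4)`` are first-class inputs (signed integers: negative
means opposite strand).  This module holds the conversion helpers.
"""

from __future__ import annotations

from typing import Any, Hashable, Iterable, Sequence

SignedGene = tuple[Hashable, int]  # (label, strand in {+1, -1})


def flip(g: SignedGene) -> SignedGene:
    return (g[0], -g[1])


def _coerce_one(item: Any) -> SignedGene:
    if hasattr(item, "name") and hasattr(item, "strand"):
        return (item.name, item.strand)
    if isinstance(item, int):
        if item == 0:
            raise ValueError("0 is not a valid signed gene")
        return (abs(item), 1 if item > 0 else -1)
    if isinstance(item, tuple) and len(item) == 2 and item[1] in (1, -1):
        return (item[0], item[1])
    if isinstance(item, str):
        if item.startswith("-"):
            return (item[1:], -1)
        return (item, 1)
    raise TypeError(f"cannot interpret {item!r} as a signed gene")


def as_signed(order: Any) -> tuple[SignedGene, ...]:
    """Coerce a GeneOrder / iterable of labels / signed ints to SignedGene tuple."""
    if hasattr(order, "genes"):
        order = order.genes
    return tuple(_coerce_one(x) for x in order)


def taxon_of(order: Any, default: str) -> str:
    return getattr(order, "taxon_id", default)


def signed_str(g: SignedGene) -> str:
    return ("" if g[1] == 1 else "-") + str(g[0])


def names_of(seq: Iterable[SignedGene]) -> frozenset:
    return frozenset(g[0] for g in seq)


def validate_unique(seq: Sequence[SignedGene], what: str = "sequence") -> None:
    names = [g[0] for g in seq]
    if len(set(names)) != len(names):
        raise ValueError(f"{what} has repeated gene names")
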