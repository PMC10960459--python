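"""Breakpoint distance between signed circular gene orders.

An adjacency is an ordered pair of neighbouring signed genes on the circle;
reading the molecule from the other strand turns ``(a, b)`` into
``(-b, -a)``, so the two forms are identified.  The breakpoint distance
between two genomes of identical gene content is the number of adjacencies
of one that are not conserved (up to reading direction) in the other:
``Bp = n - |shared adjacencies|``, with the wrap-around adjacency included
because the molecules are circular.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import pandas as pd

from .signed import SignedGene, as_signed, flip, names_of, taxon_of, validate_unique


def normalize_adjacency(a: SignedGene, b: SignedGene) -> tuple[SignedGene, SignedGene]:
    """Direction-normalized form so that (a,b) and (-b,-a) collide."""
    fwd = (a, b)
    rev = (flip(b), flip(a))
    # deterministic representative: lexicographically smaller by string key
    key = lambda adj: (str(adj[0][0]), adj[0][1], str(adj[1][0]), adj[1][1])
    return fwd if key(fwd) <= key(rev) else rev


def adjacencies(order: Any) -> frozenset:
    """The n direction-normalized adjacencies of a circular order."""
    seq = as_signed(order)
    validate_unique(seq, "gene order")
    n = len(seq)
    return frozenset(
        normalize_adjacency(seq[i], seq[(i + 1) % n]) for i in range(n)
    )


@dataclass(frozen=True)
class BreakpointResult:
    taxon_a: str
    taxon_b: str
    n_genes: int
    conserved: int
    breakpoints: int


def breakpoint_distance(a: Any, b: Any) -> BreakpointResult:
    """Breakpoints between two circular orders of identical gene content."""
    sa, sb = as_signed(a), as_signed(b)
    if names_of(sa) != names_of(sb):
        only_a = sorted(map(str, names_of(sa) - names_of(sb)))
        only_b = sorted(map(str, names_of(sb) - names_of(sa)))
        raise ValueError(
            "gene content differs between orders "
            f"(only in first: {only_a}; only in second: {only_b})"
        )
    shared = adjacencies(sa) & adjacencies(sb)
    n = len(sa)
    return BreakpointResult(
        taxon_a=taxon_of(a, "a"),
        taxon_b=taxon_of(b, "b"),
        n_genes=n,
        conserved=len(shared),
        breakpoints=n - len(shared),
    )


def breakpoint_matrix(
    orders: Sequence[Any],
    reference: Any = None,
    all_pairs: bool = False,
) -> pd.DataFrame:
    """Per-taxon breakpoints versus a reference, or all pairwise distances."""
    if reference is None and not all_pairs:
        raise ValueError("need a reference order unless all_pairs=True")
    rows = []
    if all_pairs:
        for i, a in enumerate(orders):
            for b in orders[i + 1:]:
                r = breakpoint_distance(a, b)
                rows.append(r)
    else:
        for a in orders:
            rows.append(breakpoint_distance(a, reference))
    return pd.DataFrame(
        [
            {
                "taxon_a": r.taxon_a,
                "taxon_b": r.taxon_b,
                "n_genes": r.n_genes,
                "conserved": r.conserved,
                "breakpoints": r.breakpoints,
            }
            for r in rows
        ]
    )
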