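"""Signed circular mitochondrial gene orders.

A genome is modelled as a signed circular permutation of the 37 canonical
genes: each gene carries an orientation (+1 = same transcription strand as
cox1 in the reference reading, -1 = opposite strand).  Two physical readings
of the same molecule — rotated, or read from the other strand (sequence
reversed, all orientations flipped) — describe the same arrangement, so
pattern comparison goes through :func:`canonicalize`, which rotates cox1 to
the front and, if cox1 is on the minus strand, reflects the whole order
first.  Arrangement equality then reduces to tuple equality.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genes import CANONICAL_GENES, CANONICAL_SET, normalize_gene_name

N_GENES = len(CANONICAL_GENES)  # 37


@dataclass(frozen=True, order=True)
class GeneLabel:
    """A gene name with its transcription orientation (+1 or -1)."""

    name: str
    strand: int = 1

    def __post_init__(self):
        if self.name not in CANONICAL_SET:
            raise ValueError(f"unknown gene token: {self.name!r}")
        if self.strand not in (1, -1):
            raise ValueError("strand must be +1 or -1")

    def __neg__(self) -> "GeneLabel":
        return GeneLabel(self.name, -self.strand)

    def __str__(self) -> str:
        return self.name if self.strand == 1 else "-" + self.name


@dataclass(frozen=True)
class GeneOrder:
    """A taxon's circular, signed order of the 37 mitochondrial genes."""

    taxon_id: str
    genes: tuple[GeneLabel, ...]
    circular: bool = True

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        names = [g.name for g in self.genes]
        seen = set()
        dups = sorted({n for n in names if n in seen or seen.add(n)})
        if dups:
            raise ValueError(
                f"taxon {self.taxon_id!r}: duplicated gene(s): {', '.join(dups)}"
            )
        missing = sorted(CANONICAL_SET - set(names))
        if missing:
            raise ValueError(
                f"taxon {self.taxon_id!r}: missing gene "
                + ", ".join(missing)
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def position_of(self, name: str) -> int:
        for i, g in enumerate(self.genes):
            if g.name == name:
                return i
        raise KeyError(name)

    def rotated(self, k: int) -> "GeneOrder":
        """Rotate so that index ``k`` comes first (same circular reading)."""
        n = len(self.genes)
        k %= n
        return GeneOrder(self.taxon_id, self.genes[k:] + self.genes[:k])

    def reflected(self) -> "GeneOrder":
        """Read the circle in the opposite direction on the other strand."""
        return GeneOrder(self.taxon_id, tuple(-g for g in reversed(self.genes)))

    def with_taxon(self, taxon_id: str) -> "GeneOrder":
        return GeneOrder(taxon_id, self.genes)


def canonicalize(order: GeneOrder) -> GeneOrder:
    """Canonical representative of the rotation/reflection orbit.

    Rotates cox1 to the front; if cox1 sits on the minus strand the order is
    reflected first so that cox1 is always ``+``.  Idempotent, and constant
    on every orbit: all rotations and the strand-flipped reading of one
    molecule map to the same tuple.
    """
    i = order.position_of("cox1")
    if order.genes[i].strand == -1:
        order = order.reflected()
        i = order.position_of("cox1")
    return order.rotated(i)


def canonical_key(order: GeneOrder) -> tuple[GeneLabel, ...]:
    return canonicalize(order).genes


@dataclass
class ArrangementPattern:
    """An equivalence class of gene orders under rotation/reflection."""

    pattern_id: int
    canonical_order: GeneOrder
    members: list[str] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.members)


def dedup_patterns(orders: Sequence[GeneOrder]) -> list[ArrangementPattern]:
    """Partition taxa into arrangement patterns.

    Pattern ids are assigned in first-seen input order starting at 1,
    mirroring how distinct arrangements are numbered when genomes are
    compared one by one.
    """
    if not orders:
        raise ValueError("no gene orders supplied")
    seen_taxa: set[str] = set()
    by_key: dict[tuple, ArrangementPattern] = {}
    out: list[ArrangementPattern] = []
    for order in orders:
        if order.taxon_id in seen_taxa:
            raise ValueError(f"duplicate taxon_id: {order.taxon_id!r}")
        seen_taxa.add(order.taxon_id)
        key = canonical_key(order)
        pat = by_key.get(key)
        if pat is None:
            pat = ArrangementPattern(
                pattern_id=len(out) + 1,
                canonical_order=canonicalize(order).with_taxon(
                    f"pattern_{len(out) + 1}"
                ),
            )
            by_key[key] = pat
            out.append(pat)
        pat.members.append(order.taxon_id)
    return out


# ---------------------------------------------------------------------------
# Hypothetical ancestral arthropod arrangement (matches the horseshoe crab
# Limulus polyphemus mitogenome; identical to the fruit-fly order except that
# trnL2 lies next to trnL1 between nad1 and rrnL).
# ---------------------------------------------------------------------------

_ANCESTOR_TOKENS = (
    "trnI -trnQ trnM nad2 trnW -trnC -trnY cox1 cox2 trnK trnD atp8 atp6 "
    "cox3 trnG nad3 trnA trnR trnN trnS1 trnE -trnF -nad5 -trnH -nad4 "
    "-nad4L trnT -trnP nad6 cob trnS2 -nad1 -trnL2 -trnL1 -rrnL -trnV -rrnS"
)


def _parse_tokens(tokens: Iterable[str]) -> tuple[GeneLabel, ...]:
    out = []
    for pos, tok in enumerate(tokens):
        strand = 1
        body = tok
        if tok.startswith("-"):
            strand = -1
            body = tok[1:]
        if body not in CANONICAL_SET:
            raise ValueError(
                f"unknown gene token {body!r} at position {pos + 1}"
            )
        out.append(GeneLabel(body, strand))
    return tuple(out)


def ancestral_arrangement() -> GeneOrder:
    """The hypothetical ancestral arthropod gene order (fresh copy)."""
    return GeneOrder("arthropod_ancestor", _parse_tokens(_ANCESTOR_TOKENS.split()))


ANCESTOR = ancestral_arrangement()


# ---------------------------------------------------------------------------
# Text I/O: one genome per line, taxon_id TAB signed whitespace-separated
# tokens ("-" prefix = opposite strand).
# ---------------------------------------------------------------------------

def parse_order_text(line: str) -> GeneOrder:
    """Parse ``taxon_id<TAB>tok tok -tok ...`` into a GeneOrder."""
    line = line.rstrip("\n")
    if "\t" not in line:
        raise ValueError("expected 'taxon_id<TAB>gene tokens'")
    taxon_id, rest = line.split("\t", 1)
    tokens = rest.split()
    if len(tokens) != N_GENES:
        raise ValueError(
            f"taxon {taxon_id!r}: expected {N_GENES} genes, got {len(tokens)}"
        )
    return GeneOrder(taxon_id, _parse_tokens(tokens))


def format_order_text(order: GeneOrder) -> str:
    return order.taxon_id + "\t" + " ".join(str(g) for g in order.genes)


def read_orders(path_or_stream) -> list[GeneOrder]:
    """Read a gene-order text file; blank lines and ``#`` comments skipped."""
    if hasattr(path_or_stream, "read"):
        text = path_or_stream.read()
    else:
        with open(path_or_stream) as fh:
            text = fh.read()
    orders = []
    for line in text.splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        orders.append(parse_order_text(line))
    return orders


def write_orders(orders: Sequence[GeneOrder], path_or_stream) -> None:
    text = "".join(format_order_text(o) + "\n" for o in orders)
    if hasattr(path_or_stream, "write"):
        path_or_stream.write(text)
    else:
        with open(path_or_stream, "w") as fh:
            fh.write(text)


def write_patterns_tsv(patterns: Sequence[ArrangementPattern], stream) -> None:
    stream.write("pattern_id\tn_members\tmember_ids\tcanonical_order\n")
    for p in patterns:
        stream.write(
            f"{p.pattern_id}\t{p.n_members}\t{','.join(p.members)}\t"
            + " ".join(str(g) for g in p.canonical_order.genes)
            + "\n"
        )


# ---------------------------------------------------------------------------
# GenBank I/O (annotation features only; sequence content is irrelevant to
# gene-order analysis and synthesized as placeholder nucleotides on write).
# ---------------------------------------------------------------------------

_FEATURE_TYPES = ("CDS", "tRNA", "rRNA")


def parse_genbank(handle) -> list[GeneOrder]:
    """Extract one GeneOrder per GenBank record.

    Genes are taken from CDS/tRNA/rRNA features, ordered by start
    coordinate, with orientation from the feature strand.  Names go through
    the synonym table; unknown names, or records with missing/duplicated
    canonical genes, raise with the taxon and offending genes named.
    """
    from Bio import SeqIO

    if isinstance(handle, str):
        with open(handle) as fh:
            return parse_genbank(fh)

    orders = []
    for rec in SeqIO.parse(handle, "genbank"):
        taxon = rec.annotations.get("organism") or rec.name or rec.id
        feats = []
        for feat in rec.features:
            if feat.type not in _FEATURE_TYPES:
                continue
            raw = None
            for key in ("gene", "product"):
                if key in feat.qualifiers and feat.qualifiers[key]:
                    raw = feat.qualifiers[key][0]
                    break
            if raw is None:
                raise ValueError(
                    f"record {taxon!r}: {feat.type} feature without "
                    "gene/product qualifier"
                )
            try:
                name = normalize_gene_name(raw)
            except ValueError as exc:
                raise ValueError(f"record {taxon!r}: {exc}") from exc
            strand = 1 if (feat.location.strand or 1) >= 0 else -1
            feats.append((int(feat.location.start), GeneLabel(name, strand)))
        feats.sort(key=lambda t: t[0])
        orders.append(GeneOrder(taxon, tuple(g for _, g in feats)))
    if not orders:
        raise ValueError("no GenBank records found")
    return orders


def write_genbank(orders: Sequence[GeneOrder], handle) -> None:
    """Render gene orders as minimal annotated GenBank records."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    gene_len, spacer = 60, 40
    records = []
    for order in orders:
        n = len(order.genes)
        total = n * (gene_len + spacer)
        rec = SeqRecord(
            Seq("a" * total),
            id=order.taxon_id[:16] or "genome",
            name=(order.taxon_id[:16] or "genome").replace(" ", "_"),
            description="synthetic mitochondrial genome rendering",
            annotations={
                "molecule_type": "DNA",
                "topology": "circular",
                "organism": order.taxon_id,
            },
        )
        for i, g in enumerate(order.genes):
            start = i * (gene_len + spacer)
            ftype = (
                "tRNA" if g.name.startswith("trn")
                else "rRNA" if g.name.startswith("rrn")
                else "CDS"
            )
            rec.features.append(
                SeqFeature(
                    SimpleLocation(start, start + gene_len, strand=g.strand),
                    type=ftype,
                    qualifiers={"gene": [g.name]},
                )
            )
        records.append(rec)
    if isinstance(handle, str):
        with open(handle, "w") as fh:
            SeqIO.write(records, fh, "genbank")
    else:
        SeqIO.write(records, handle, "genbank")


def genbank_roundtrip(orders: Sequence[GeneOrder]) -> list[GeneOrder]:
    buf = io.StringIO()
    write_genbank(orders, buf)
    buf.seek(0)
    return parse_genbank(buf)
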