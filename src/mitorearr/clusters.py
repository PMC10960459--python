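"""Shared derived gene clusters and cladogram assembly.

A gene cluster is an ordered, oriented run of >=2 genes.  A genome contains
the cluster if its genes occur contiguously on the circle in the stated
sequence and orientations, or wholly direction-reversed with flipped
strands; a bounded number of intervening genes ("insertions") can be
tolerated to express variants such as a cluster interrupted by one
translocated tRNA.  Clusters present in every member of a group but absent
from the ancestral arrangement and from all non-members are the gene-order
analogue of morphological synapomorphies; a laminar (nested-or-disjoint)
family of such supported taxon sets is exactly a rooted tree, which is the
cladogram this module builds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Optional, Sequence

from .breakpoints import adjacencies, normalize_adjacency
from .signed import SignedGene, as_signed, flip, names_of, signed_str, taxon_of, validate_unique


def _revflip(genes: tuple[SignedGene, ...]) -> tuple[SignedGene, ...]:
    return tuple(flip(g) for g in reversed(genes))


def _str_key(genes: tuple[SignedGene, ...]):
    return tuple((str(g[0]), g[1]) for g in genes)


@dataclass(frozen=True)
class GeneCluster:
    """An ordered, oriented run of >=2 genes used as a candidate synapomorphy."""

    genes: tuple[SignedGene, ...]

    def __post_init__(self):
        object.__setattr__(self, "genes", as_signed(self.genes))
        validate_unique(self.genes, "cluster")
        if len(self.genes) < 2:
            raise ValueError("a gene cluster needs at least 2 genes")

    @property
    def label(self) -> str:
        """Hyphenated display form; '~' marks minus-strand genes."""
        return "-".join(
            ("~" if g[1] == -1 else "") + str(g[0]) for g in self.genes
        )

    def reversed_flipped(self) -> "GeneCluster":
        return GeneCluster(_revflip(self.genes))

    def canonical_form(self) -> tuple[SignedGene, ...]:
        """Direction-normalized identity (cluster == its reversed-flipped form)."""
        rev = _revflip(self.genes)
        return self.genes if _str_key(self.genes) <= _str_key(rev) else rev

    def __len__(self) -> int:
        return len(self.genes)

    def __str__(self) -> str:
        return self.label


def cluster(*tokens) -> GeneCluster:
    """Convenience constructor: cluster('nad6', 'trnT', 'cob') or ints."""
    return GeneCluster(as_signed(tokens))


@dataclass(frozen=True)
class ClusterMatch:
    cluster: GeneCluster
    taxon_id: str
    exact: bool
    insertions_used: int


def contains_cluster(
    order: Any, clu: GeneCluster | Iterable, max_insertions: int = 0
) -> Optional[ClusterMatch]:
    """Locate a cluster in a circular order, or return None.

    Matching is contiguity-, order- and orientation-sensitive up to reading
    direction: ``(a, b, c)`` also matches ``(-c, -b, -a)``.  At most
    ``max_insertions`` intervening genes are tolerated in total, and the
    reported count is minimal over the two reading directions.
    """
    if max_insertions < 0:
        raise ValueError("max_insertions must be >= 0")
    if not isinstance(clu, GeneCluster):
        clu = GeneCluster(as_signed(clu))
    seq = as_signed(order)
    n = len(seq)
    pos = {g[0]: (i, g[1]) for i, g in enumerate(seq)}
    absent = [str(g[0]) for g in clu.genes if g[0] not in pos]
    if absent:
        raise ValueError(
            "cluster gene(s) absent from the order's alphabet: "
            + ", ".join(absent)
        )

    best: Optional[int] = None
    for reading in (clu.genes, _revflip(clu.genes)):
        if any(pos[g[0]][1] != g[1] for g in reading):
            continue
        ins = 0
        for a, b in zip(reading, reading[1:]):
            ins += (pos[b[0]][0] - pos[a[0]][0] - 1) % n
        if len(reading) + ins > n:  # walk would lap the circle
            continue
        if best is None or ins < best:
            best = ins
    if best is None or best > max_insertions:
        return None
    return ClusterMatch(
        cluster=clu,
        taxon_id=taxon_of(order, "?"),
        exact=(best == 0),
        insertions_used=best,
    )


def find_shared_clusters(
    orders: Sequence[Any],
    min_len: int = 2,
    max_len: Optional[int] = None,
) -> list[GeneCluster]:
    """Maximal clusters exactly shared by every input order.

    A run is shared iff each of its internal adjacencies is conserved (up to
    reading direction) in every order; maximal runs cannot be extended left
    or right without losing a member.  With ``max_len`` set, longer maximal
    runs are dropped.  Orders identical up to rotation/reflection share the
    whole circle as a single cluster.
    """
    if not orders:
        raise ValueError("no orders supplied")
    seqs = [as_signed(o) for o in orders]
    content = names_of(seqs[0])
    if any(names_of(s) != content for s in seqs[1:]):
        raise ValueError("orders differ in gene content")

    shared_adj = adjacencies(seqs[0])
    for s in seqs[1:]:
        shared_adj &= adjacencies(s)

    base = seqs[0]
    n = len(base)
    conserved = [
        normalize_adjacency(base[i], base[(i + 1) % n]) in shared_adj
        for i in range(n)
    ]

    def keep(c: GeneCluster) -> bool:
        return len(c) >= min_len and (max_len is None or len(c) <= max_len)

    if all(conserved):
        whole = GeneCluster(base)
        return [whole] if keep(whole) else []

    out: list[GeneCluster] = []
    # runs start right after a broken adjacency
    for s in range(n):
        if conserved[s - 1] if s > 0 else conserved[n - 1]:
            continue
        m = 0
        while m < n and conserved[(s + m) % n]:
            m += 1
        if m >= 1:
            genes = tuple(base[(s + j) % n] for j in range(m + 1))
            c = GeneCluster(genes)
            if keep(c):
                out.append(c)
    return out


def derived_clusters(
    ingroup: Sequence[Any],
    ancestor: Any,
    outgroup: Sequence[Any] = (),
    max_insertions: int = 0,
    min_len: int = 2,
    max_len: Optional[int] = None,
) -> list[GeneCluster]:
    """Synapomorphy candidates for the ingroup.

    Clusters exactly shared by all ingroup members that are absent (even
    allowing ``max_insertions``) from the ancestral arrangement and from
    every outgroup member.
    """
    shared = find_shared_clusters(ingroup, min_len=min_len, max_len=max_len)
    out = []
    for c in shared:
        if contains_cluster(ancestor, c, max_insertions) is not None:
            continue
        if any(contains_cluster(o, c, max_insertions) for o in outgroup):
            continue
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# Cladogram assembly
# ---------------------------------------------------------------------------

@dataclass
class CladeHypothesis:
    taxa: frozenset
    supporting_clusters: list[GeneCluster]
    exclusive: bool = True

    @property
    def support(self) -> int:
        return len(self.supporting_clusters)


@dataclass
class CladeNode:
    taxa: frozenset
    clade: Optional[CladeHypothesis] = None
    children: list = field(default_factory=list)
    leaf: Optional[str] = None

    def newick_label(self) -> str:
        if self.leaf is not None:
            return self.leaf
        if self.clade is None or not self.clade.supporting_clusters:
            return ""
        return "|".join(c.label for c in self.clade.supporting_clusters)


@dataclass
class Cladogram:
    root: CladeNode
    clades: list[CladeHypothesis]
    conflicts: list[dict]
    taxa: list[str]

    def clade_sets(self) -> set:
        """Accepted non-trivial clades (excluding the root set and leaves)."""
        full = frozenset(self.taxa)
        return {
            c.taxa for c in self.clades
            if 1 < len(c.taxa) < len(full)
        }

    def to_newick(self) -> str:
        def render(node: CladeNode) -> str:
            if node.leaf is not None:
                return node.leaf
            inner = ",".join(render(ch) for ch in node.children)
            label = node.newick_label()
            return f"({inner}){label}"

        return render(self.root) + ";"


def _laminar_with(s: frozenset, accepted: Iterable[frozenset]) -> Optional[frozenset]:
    """Return the first accepted set that crosses s, or None if compatible."""
    for t in accepted:
        inter = s & t
        if inter and inter != s and inter != t:
            return t
    return None


def build_cladogram(
    orders: Sequence[Any],
    ancestor: Any,
    outgroup: Sequence[Any] = (),
    candidate_clades: Optional[Sequence[Iterable[str]]] = None,
    named_clusters: Optional[Sequence[tuple[GeneCluster, int]]] = None,
    max_insertions: int = 0,
    min_len: int = 2,
    max_len: int = 8,
) -> Cladogram:
    """Assemble a cladogram from shared derived gene clusters.

    Candidate clade hypotheses come from, in order of preference: explicit
    ``named_clusters`` (each with its own insertion tolerance; its clade is
    the set of taxa matching it), explicit ``candidate_clades`` (taxon sets,
    supported by their derived clusters), or — by default — the atomic
    derived characters: every adjacency absent from the ancestor defines the
    set of taxa carrying it (exclusive by construction), and each such set
    is then corroborated by the maximal derived clusters (up to ``max_len``
    genes) its members share exclusively.

    Overlapping, non-nested hypotheses are resolved by (1) more supporting
    clusters, then (2) larger taxon set, then (3) lexicographically smallest
    member id; every rejection is logged.  The result is a laminar family,
    i.e. a rooted tree; taxa not placed by any accepted clade attach as a
    polytomy at the deepest compatible node.
    """
    taxa = [taxon_of(o, f"taxon{i}") for i, o in enumerate(orders)]
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon ids")
    by_taxon = dict(zip(taxa, orders))
    full = frozenset(taxa)

    hypotheses: dict[frozenset, CladeHypothesis] = {}

    def add_support(taxon_set: frozenset, clu: GeneCluster, exclusive: bool = True):
        hyp = hypotheses.get(taxon_set)
        if hyp is None:
            hyp = CladeHypothesis(taxon_set, [], exclusive)
            hypotheses[taxon_set] = hyp
        if clu.canonical_form() not in {
            c.canonical_form() for c in hyp.supporting_clusters
        }:
            hyp.supporting_clusters.append(clu)
        hyp.exclusive = hyp.exclusive and exclusive

    if named_clusters is not None:
        for clu, tol in named_clusters:
            if contains_cluster(ancestor, clu, tol) is not None:
                continue  # not derived
            members = frozenset(
                t for t in taxa
                if contains_cluster(by_taxon[t], clu, tol) is not None
            )
            if len(members) < 2:
                continue
            outside = any(
                contains_cluster(o, clu, tol) is not None for o in outgroup
            )
            add_support(members, clu, exclusive=not outside)
    elif candidate_clades is not None:
        for cand in candidate_clades:
            members = frozenset(cand)
            ingroup = [by_taxon[t] for t in members]
            rest = [by_taxon[t] for t in taxa if t not in members] + list(outgroup)
            for clu in derived_clusters(
                ingroup, ancestor, rest,
                max_insertions=max_insertions, min_len=min_len, max_len=max_len,
            ):
                add_support(members, clu)
    else:
        anc_adj = adjacencies(ancestor)
        out_adj = [adjacencies(o) for o in outgroup]
        taxon_adj = {t: adjacencies(by_taxon[t]) for t in taxa}
        seen: set = set()
        for o in orders:
            seq = as_signed(o)
            n = len(seq)
            for i in range(n):
                pair = (seq[i], seq[(i + 1) % n])
                adj = normalize_adjacency(*pair)
                if adj in seen or adj in anc_adj:
                    continue
                seen.add(adj)
                if any(adj in oa for oa in out_adj):
                    continue
                members = frozenset(
                    t for t in taxa if adj in taxon_adj[t]
                )
                if len(members) < 2:
                    continue
                add_support(members, GeneCluster(pair))
        # corroborate each adjacency-defined set with the longer maximal
        # clusters its members share exclusively
        for taxon_set in list(hypotheses):
            members = [by_taxon[t] for t in sorted(taxon_set)]
            rest = [by_taxon[t] for t in taxa if t not in taxon_set]
            for clu in derived_clusters(
                members, ancestor, rest + list(outgroup),
                max_insertions=max_insertions,
                min_len=max(min_len, 3), max_len=max_len,
            ):
                add_support(taxon_set, clu)

    # conflict resolution: support desc, size desc, lexicographically smallest
    ordered = sorted(
        hypotheses.values(),
        key=lambda h: (-h.support, -len(h.taxa), min(h.taxa)),
    )
    accepted: list[CladeHypothesis] = []
    conflicts: list[dict] = []
    for hyp in ordered:
        crosser = _laminar_with(hyp.taxa, [a.taxa for a in accepted])
        if crosser is not None:
            conflicts.append(
                {
                    "taxa": ",".join(sorted(hyp.taxa)),
                    "clusters": "|".join(
                        c.label for c in hyp.supporting_clusters
                    ),
                    "support": hyp.support,
                    "conflicts_with": ",".join(sorted(crosser)),
                }
            )
            continue
        accepted.append(hyp)

    # assemble the rooted tree from the laminar family
    root = CladeNode(taxa=full, clade=hypotheses.get(full))
    inner = [h for h in accepted if h.taxa != full]
    nodes = {full: root}
    for hyp in sorted(inner, key=lambda h: -len(h.taxa)):
        parent = min(
            (s for s in nodes if hyp.taxa < s), key=len, default=full
        )
        node = CladeNode(taxa=hyp.taxa, clade=hyp)
        nodes[parent].children.append(node)
        nodes[hyp.taxa] = node
    for t in taxa:  # input order keeps output deterministic
        parent = min((s for s in nodes if t in s), key=len)
        nodes[parent].children.append(CladeNode(taxa=frozenset([t]), leaf=t))

    return Cladogram(root=root, clades=accepted, conflicts=conflicts, taxa=taxa)
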