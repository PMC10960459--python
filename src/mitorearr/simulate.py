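"""Tree-structured simulation of mitochondrial gene-order rearrangement.

Gene orders evolve along a rooted tree by three event kinds — inversion,
transposition and inverted transposition — drawn as Poisson counts per edge
(mean = rate x branch length) with geometric segment lengths.  Every event
is logged, and replaying the log from the root arrangement reproduces each
tip exactly, which is what makes the simulator usable as ground truth for
pattern counting, breakpoint laws and synapomorphy recovery.

Codon-sequence simulation with known synonymous/nonsynonymous rates lives
here too, as ground truth for the NG86 estimator.

Randomness: a single global seed; per-edge substreams are derived
deterministically from (seed, edge id) so a subtree's draws do not depend on
edits elsewhere in the tree.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .breakpoints import adjacencies, normalize_adjacency
from .gene_order import (
    ANCESTOR,
    GeneLabel,
    GeneOrder,
    ancestral_arrangement,
    format_order_text,
    write_genbank,
    write_orders,
)
from .trees import balanced_newick, load_tree, pectinate_newick, random_newick

EVENT_KINDS = ("inversion", "transposition", "inverted_transposition")

_RATE_ALIASES = {
    "inv": "inversion", "inversion": "inversion",
    "trans": "transposition", "transposition": "transposition",
    "invtrans": "inverted_transposition",
    "inverted_transposition": "inverted_transposition",
}


def _revflip(seg):
    return tuple(-g for g in reversed(seg))


@dataclass(frozen=True)
class RearrangementEvent:
    """One rearrangement: a segment of ``length`` genes starting at ``start``
    (indices into the current representation, segment rotated to the front
    before application), optionally re-inserted at gap ``dest`` of the
    remainder (transpositions only, 1 <= dest <= n-length-1)."""

    kind: str
    start: int
    length: int
    dest: Optional[int] = None
    edge_id: str = ""

    def apply(self, genes: tuple[GeneLabel, ...]) -> tuple[GeneLabel, ...]:
        n = len(genes)
        if not (1 <= self.length <= n - 2):
            raise ValueError("segment length must be in [1, n-2]")
        rot = genes[self.start:] + genes[:self.start]
        seg, rest = rot[: self.length], rot[self.length:]
        if self.kind == "inversion":
            out = _revflip(seg) + rest
        elif self.kind in ("transposition", "inverted_transposition"):
            d = self.dest
            if d is None or not (1 <= d <= len(rest) - 1):
                raise ValueError("transposition needs 1 <= dest <= n-length-1")
            body = seg if self.kind == "transposition" else _revflip(seg)
            out = rest[:d] + body + rest[d:]
        else:
            raise ValueError(f"unknown event kind: {self.kind!r}")
        # re-anchor on the input's first gene so that genes outside the
        # segment keep their positions (the circle itself has no origin)
        anchor = genes[0].name
        k = next(i for i, g in enumerate(out) if g.name == anchor)
        return out[k:] + out[:k]

    def adjacency_change(self, genes: tuple[GeneLabel, ...]):
        """(created, broken) direction-normalized adjacency sets."""
        pre = adjacencies(genes)
        post = adjacencies(self.apply(genes))
        return post - pre, pre - post


@dataclass
class SimulationResult:
    newick: str
    root_order: GeneOrder
    tip_orders: dict[str, GeneOrder]
    events: dict[str, list[RearrangementEvent]]
    seed: int
    #: created/broken adjacency sets per edge, in event order
    adjacency_log: dict[str, list[tuple[frozenset, frozenset]]] = field(
        default_factory=dict
    )

    def edge_leafsets(self) -> dict[str, frozenset]:
        return {eid: frozenset(eid.split(",")) for eid in self.events}

    def events_on_path(self, tip: str) -> list[RearrangementEvent]:
        """Root-to-tip event list (edges ordered by decreasing clade size)."""
        edges = [
            (eid, leaves)
            for eid, leaves in self.edge_leafsets().items()
            if tip in leaves
        ]
        edges.sort(key=lambda t: -len(t[1]))
        out = []
        for eid, _ in edges:
            out.extend(self.events[eid])
        return out

    def replay(self) -> dict[str, GeneOrder]:
        """Re-apply the event log from the root; returns recomputed tips."""
        tree = load_tree(self.newick)
        tips: dict[str, GeneOrder] = {}

        def walk(node, genes):
            for child in node.child_nodes():
                eid = _edge_id(child)
                g = genes
                for ev in self.events.get(eid, []):
                    g = ev.apply(g)
                if child.is_leaf():
                    tips[child.taxon.label] = GeneOrder(child.taxon.label, g)
                else:
                    walk(child, g)

        walk(tree.seed_node, self.root_order.genes)
        return tips


def _edge_id(child_node) -> str:
    return ",".join(sorted(lf.taxon.label for lf in child_node.leaf_iter()))


def _edge_rng(seed: int, edge_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(edge_id.encode())])


def _draw_length(rng, n: int, seg_p: float) -> int:
    return int(min(rng.geometric(seg_p), n - 2))


def _sample_event(rng, n: int, kind: str, seg_p: float, edge_id: str) -> RearrangementEvent:
    length = _draw_length(rng, n, seg_p)
    start = int(rng.integers(n))
    dest = None
    if kind != "inversion":
        dest = int(rng.integers(1, n - length))
    return RearrangementEvent(kind, start, length, dest, edge_id)


def normalize_rates(rates: dict) -> dict[str, float]:
    out = {k: 0.0 for k in EVENT_KINDS}
    for key, val in rates.items():
        canon = _RATE_ALIASES.get(key.lower())
        if canon is None:
            raise ValueError(f"unknown event kind: {key!r}")
        if val < 0:
            raise ValueError("rates must be >= 0")
        out[canon] = float(val)
    return out


def simulate_rearrangements(
    tree,
    root: GeneOrder = None,
    rates: dict = None,
    seg_p: float = 0.5,
    seed: int = 0,
) -> SimulationResult:
    """Evolve a gene order along a tree under Poisson rearrangement rates.

    ``tree`` is a newick string or dendropy Tree; ``rates`` maps event kinds
    (``inversion``/``transposition``/``inverted_transposition``, or the
    short forms inv/trans/invtrans) to expected events per unit branch
    length.  Branch lengths default to 1.
    """
    if root is None:
        root = ancestral_arrangement()
    rates = normalize_rates(rates or {})
    t = load_tree(tree) if isinstance(tree, str) else tree
    leaves = [lf.taxon.label for lf in t.leaf_node_iter()]
    if not leaves:
        raise ValueError("degenerate tree: no leaves")

    events: dict[str, list[RearrangementEvent]] = {}
    adjacency_log: dict[str, list] = {}
    tips: dict[str, GeneOrder] = {}
    n = len(root.genes)

    def walk(node, genes):
        for child in node.child_nodes():
            eid = _edge_id(child)
            rng = _edge_rng(seed, eid)
            blen = child.edge.length if child.edge.length is not None else 1.0
            kinds = []
            for kind in EVENT_KINDS:
                kinds.extend([kind] * rng.poisson(rates[kind] * blen))
            order = rng.permutation(len(kinds)) if kinds else []
            evs, log, g = [], [], genes
            for idx in order:
                ev = _sample_event(rng, n, kinds[idx], seg_p, eid)
                created, broken = ev.adjacency_change(g)
                evs.append(ev)
                log.append((frozenset(created), frozenset(broken)))
                g = ev.apply(g)
            events[eid] = evs
            adjacency_log[eid] = log
            if child.is_leaf():
                tips[child.taxon.label] = GeneOrder(child.taxon.label, g)
            else:
                walk(child, g)

    walk(t.seed_node, root.genes)
    return SimulationResult(
        newick=t.as_string(schema="newick").strip(),
        root_order=root,
        tip_orders=tips,
        events=events,
        seed=seed,
        adjacency_log=adjacency_log,
    )


# ---------------------------------------------------------------------------
# Clade-marker regime: one uniquely-identifiable event per internal edge
# ---------------------------------------------------------------------------

def _shape_newick(n_taxa: int, shape: str, rng: np.random.Generator) -> str:
    if shape == "balanced":
        return balanced_newick(n_taxa)
    if shape == "pectinate":
        return pectinate_newick(n_taxa)
    if shape == "random":
        return random_newick(n_taxa, rng)
    raise ValueError(f"unknown tree shape: {shape!r}")


def simulate_clade_markers(
    n_taxa: int,
    shape: str = "random",
    seed: int = 0,
    seg_p: float = 0.5,
    root: GeneOrder = None,
    max_tries: int = 50,
    per_edge_tries: int = 500,
) -> SimulationResult:
    """Simulate exactly one clade-marking event per internal edge.

    Events are rejection-sampled so that the adjacencies each event creates
    are globally novel (absent from the root arrangement and from every
    other event's creations) and are never broken by any later event on a
    descendant edge.  In this regime every derived adjacency is carried by
    exactly the tips of one clade, so grouping by shared derived adjacency
    characters recovers the true topology.
    """
    if n_taxa < 4:
        raise ValueError("need n_taxa >= 4")
    if root is None:
        root = ancestral_arrangement()
    n = len(root.genes)
    root_adj = adjacencies(root.genes)

    for attempt in range(max_tries):
        rng_tree = np.random.default_rng([seed, 1_000_003, attempt])
        newick = _shape_newick(n_taxa, shape, rng_tree)
        tree = load_tree(newick)
        events: dict[str, list[RearrangementEvent]] = {}
        adjacency_log: dict[str, list] = {}
        tips: dict[str, GeneOrder] = {}
        global_created: set = set()
        ok = True

        def walk(node, genes, protected):
            nonlocal ok
            if not ok:
                return
            for child in node.child_nodes():
                eid = _edge_id(child)
                if child.is_leaf():
                    events[eid] = []
                    adjacency_log[eid] = []
                    tips[child.taxon.label] = GeneOrder(child.taxon.label, genes)
                    continue
                rng = _edge_rng(seed + attempt, eid)
                chosen = None
                for _ in range(per_edge_tries):
                    kind = EVENT_KINDS[int(rng.integers(3))]
                    ev = _sample_event(rng, n, kind, seg_p, eid)
                    created, broken = ev.adjacency_change(genes)
                    if broken & protected:  # would erase an older junction
                        continue
                    if created & (root_adj | global_created):
                        continue
                    chosen = (ev, created, broken)
                    break
                if chosen is None:
                    ok = False
                    return
                ev, created, broken = chosen
                events[eid] = [ev]
                adjacency_log[eid] = [(frozenset(created), frozenset(broken))]
                global_created.update(created)
                walk(child, ev.apply(genes), protected | created)

        walk(tree.seed_node, root.genes, set())
        if not ok:
            continue

        result = SimulationResult(
            newick=newick,
            root_order=root,
            tip_orders=tips,
            events=events,
            seed=seed,
            adjacency_log=adjacency_log,
        )
        if _markers_check(result, root_adj):
            return result

    raise RuntimeError(
        "rejection budget exceeded for clade-marker simulation; "
        "try fewer taxa or a smaller segment length (higher seg_p)"
    )


def _markers_check(result: SimulationResult, root_adj) -> bool:
    """Every internal edge's created adjacencies: present in all descendant
    tips, absent everywhere else (and from the root)."""
    tip_adj = {t: adjacencies(o.genes) for t, o in result.tip_orders.items()}
    leafsets = result.edge_leafsets()
    for eid, log in result.adjacency_log.items():
        below = leafsets[eid]
        if len(below) < 2:
            continue
        for created, _broken in log:
            for adj in created:
                if adj in root_adj:
                    return False
                for tip, adjs in tip_adj.items():
                    if (tip in below) != (adj in adjs):
                        return False
    return True


# ---------------------------------------------------------------------------
# Codon-pair simulation with known Ka/Ks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonPair:
    """An ancestral/derived codon-aligned pair with logged ground truth."""

    ancestor: str
    derived: str
    table_id: int
    n_codons: int
    target_ka: float
    target_ks: float
    n_syn_events: int
    n_nonsyn_events: int


def _codon_mutation_info(table_id: int):
    from .kaks import _code, _codon_sites

    fwd, stops = _code(table_id)
    info = {}
    for codon in fwd:
        if codon in stops:
            continue
        syn_muts, nonsyn_muts = [], []
        for pos in range(3):
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                mut = codon[:pos] + nt + codon[pos + 1:]
                if mut in stops:
                    continue
                (syn_muts if fwd[mut] == fwd[codon] else nonsyn_muts).append(mut)
        S_c, N_c = _codon_sites(codon, table_id)
        info[codon] = (syn_muts, nonsyn_muts, S_c, N_c)
    return info


def _forward_p(k: float) -> float:
    """Jukes-Cantor forward map: expected observed proportion at rate k."""
    return 0.75 * (1.0 - math.exp(-4.0 * k / 3.0))


def simulate_codon_pair(
    n_codons: int,
    target_ka: float,
    target_ks: float,
    table_id: int = 5,
    seed: int = 0,
) -> CodonPair:
    """Generate a codon-aligned pair whose true rates are known.

    The ancestor is uniform over stop-free codons; the descendant receives
    at most one substitution per codon, drawn so that the expected NG86
    synonymous/nonsynonymous difference counts equal the Jukes-Cantor
    forward-mapped targets.  Nonsynonymous draws whose mutation space
    includes stop codons are realized as a non-stop nonsynonymous change so
    both sequences stay translatable.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if target_ka < 0 or target_ks < 0:
        raise ValueError("targets must be >= 0")
    pN = _forward_p(target_ka)
    pS = _forward_p(target_ks)
    info = _codon_mutation_info(table_id)
    codons = sorted(info)
    worst = max(pS * info[c][2] + pN * info[c][3] for c in codons)
    if worst > 1.0:
        raise ValueError(
            "infeasible targets: per-codon substitution probability exceeds 1 "
            "(beyond saturation)"
        )

    rng = np.random.default_rng(seed)
    anc = [codons[i] for i in rng.integers(len(codons), size=n_codons)]
    der = []
    n_syn = n_nonsyn = 0
    for codon in anc:
        syn_muts, nonsyn_muts, S_c, N_c = info[codon]
        u = rng.random()
        if u < pS * S_c and syn_muts:
            der.append(syn_muts[int(rng.integers(len(syn_muts)))])
            n_syn += 1
        elif u < pS * S_c + pN * N_c and nonsyn_muts:
            der.append(nonsyn_muts[int(rng.integers(len(nonsyn_muts)))])
            n_nonsyn += 1
        else:
            der.append(codon)
    return CodonPair(
        ancestor="".join(anc),
        derived="".join(der),
        table_id=table_id,
        n_codons=n_codons,
        target_ka=target_ka,
        target_ks=target_ks,
        n_syn_events=n_syn,
        n_nonsyn_events=n_nonsyn,
    )


# ---------------------------------------------------------------------------
# fig1_mini: a 12-taxon fixture carrying scaled-down analogues of the
# published synapomorphy clusters
# ---------------------------------------------------------------------------

def _move(
    genes: tuple[GeneLabel, ...],
    segment: Sequence[str],
    after: str,
    invert: bool = False,
) -> tuple[GeneLabel, ...]:
    """Move the named contiguous segment to just after gene ``after``."""
    names = [g.name for g in genes]
    idx = [names.index(s) for s in segment]
    n = len(genes)
    if any((idx[i + 1] - idx[i]) % n != 1 for i in range(len(idx) - 1)):
        raise ValueError(f"segment {segment} not contiguous")
    seg = tuple(genes[i] for i in idx)
    rest = tuple(g for i, g in enumerate(genes) if i not in set(idx))
    if invert:
        seg = _revflip(seg)
    rest_names = [g.name for g in rest]
    j = rest_names.index(after) + 1
    return rest[:j] + seg + rest[j:]


FIG1_MINI_NEWICK = (
    "(t01,t02,t03,(t04,t05)N,(t06,t07,(t08,t09,(t10,t11,t12)ATA)S)M);"
)

#: Named clusters with per-cluster insertion tolerances (display label,
#: signed gene tokens, max_insertions).
FIG1_MINI_CLUSTERS = (
    ("nad6-trnT-cob", ("nad6", "trnT", "cob"), 0),
    ("trnR-trnI", ("trnR", "trnI"), 0),
    ("nad2-trnM", ("nad2", "trnM"), 1),
    ("trnS1-trnI", ("trnS1", "trnI"), 0),
    (
        "trnY-trnQ-trnV-trnL2-rrnS-rrnL",
        ("trnY", "trnQ", "trnV", "trnL2", "rrnS", "rrnL"),
        0,
    ),
)


def fig1_mini() -> dict:
    """12 engineered gene orders with nested derived clusters.

    Clades: all 12 taxa (nad6-trnT-cob), {t04,t05} (trnR-trnI),
    {t06..t12} (nad2-trnM; t09 carries the 1-insertion variant
    nad2-trnC-trnM), {t08..t12} (trnS1-trnI) and {t10,t11,t12}
    (the rRNA block trnY-trnQ-trnV-trnL2-rrnS-rrnL).
    """
    base = _move(ANCESTOR.genes, ["trnT"], after="nad6")  # all taxa

    notho = _move(base, ["trnI"], after="trnR")           # t04, t05
    m_grp = _move(base, ["trnM"], after="nad2")           # t06..t12
    s_grp = _move(m_grp, ["trnI"], after="trnS1")         # t08..t12
    t09 = _move(s_grp, ["trnC"], after="nad2")            # variant member
    ata = _move(s_grp, ["rrnS"], after="rrnL")
    ata = _move(ata, ["trnL2"], after="rrnS")
    ata = _move(ata, ["nad2", "trnM", "trnW", "trnC"], after="cox1")

    assignment = {
        "t01": base, "t02": base, "t03": base,
        "t04": notho, "t05": notho,
        "t06": m_grp, "t07": m_grp,
        "t08": s_grp, "t09": t09,
        "t10": ata, "t11": ata, "t12": ata,
    }
    orders = [GeneOrder(t, g) for t, g in assignment.items()]
    from .clusters import GeneCluster

    named = [
        (GeneCluster(tokens), tol) for _label, tokens, tol in FIG1_MINI_CLUSTERS
    ]
    return {
        "orders": orders,
        "ancestor": ancestral_arrangement(),
        "newick": FIG1_MINI_NEWICK,
        "named_clusters": named,
        "variant_taxon": "t09",
        "clades": {
            "all": frozenset(assignment),
            "N": frozenset(["t04", "t05"]),
            "M": frozenset(["t06", "t07", "t08", "t09", "t10", "t11", "t12"]),
            "S": frozenset(["t08", "t09", "t10", "t11", "t12"]),
            "ATA": frozenset(["t10", "t11", "t12"]),
        },
    }


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

def write_events_tsv(result: SimulationResult, stream) -> None:
    stream.write("edge_id\tindex\tkind\tstart\tlength\tdest\tcreated\tbroken\n")
    for eid in sorted(result.events):
        for i, ev in enumerate(result.events[eid]):
            created, broken = result.adjacency_log[eid][i]

            def fmt(adjs):
                return ";".join(
                    sorted(
                        "{}{}|{}{}".format(
                            "-" if a[1] == -1 else "", a[0],
                            "-" if b[1] == -1 else "", b[0],
                        )
                        for a, b in adjs
                    )
                )

            stream.write(
                f"{eid}\t{i}\t{ev.kind}\t{ev.start}\t{ev.length}\t"
                f"{'' if ev.dest is None else ev.dest}\t"
                f"{fmt(created)}\t{fmt(broken)}\n"
            )


def write_fixture_set(out_dir, config: dict) -> list[str]:
    """Emit a coherent fixture directory (orders text, GenBank rendering,
    newick truth, event log TSV, codon FASTA) per a config mapping."""
    import os

    if not config:
        raise ValueError("empty fixture config")
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    def path(name):
        p = os.path.join(out_dir, name)
        written.append(p)
        return p

    if config.get("fig1_mini"):
        fix = fig1_mini()
        write_orders(fix["orders"], path("orders.txt"))
        write_genbank(fix["orders"], path("genomes.gbk"))
        with open(path("tree.nwk"), "w") as fh:
            fh.write(fix["newick"] + "\n")
        with open(path("clusters.tsv"), "w") as fh:
            fh.write("label\tgenes\tmax_insertions\n")
            for label, tokens, tol in FIG1_MINI_CLUSTERS:
                fh.write(f"{label}\t{' '.join(tokens)}\t{tol}\n")
    else:
        seed = int(config.get("seed", 0))
        if "tree" in config:
            newick = config["tree"]
        elif "shape" in config:
            shape, _, k = config["shape"].partition(":")
            rng = np.random.default_rng([seed, 7])
            newick = _shape_newick(int(k or 8), shape, rng)
        else:
            raise ValueError("config needs 'tree', 'shape' or 'fig1_mini'")
        result = simulate_rearrangements(
            newick,
            rates=config.get("rates", {"inversion": 0.5, "transposition": 0.3,
                                       "inverted_transposition": 0.1}),
            seg_p=float(config.get("seg_p", 0.5)),
            seed=seed,
        )
        write_orders(list(result.tip_orders.values()), path("orders.txt"))
        write_genbank(list(result.tip_orders.values()), path("genomes.gbk"))
        with open(path("tree.nwk"), "w") as fh:
            fh.write(result.newick + "\n")
        with open(path("events.tsv"), "w") as fh:
            write_events_tsv(result, fh)

    if "n_codons" in config:
        pair = simulate_codon_pair(
            int(config["n_codons"]),
            float(config.get("target_ka", 0.1)),
            float(config.get("target_ks", 0.5)),
            table_id=int(config.get("code", 5)),
            seed=int(config.get("seed", 0)),
        )
        with open(path("codons.fasta"), "w") as fh:
            fh.write(f">ancestor\n{pair.ancestor}\n>derived\n{pair.derived}\n")

    return written
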