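"""Cluster matching, shared/derived cluster discovery, cladogram assembly."""

import numpy as np
import pytest

from mitorearr.clusters import (
    GeneCluster,
    build_cladogram,
    cluster,
    contains_cluster,
    derived_clusters,
    find_shared_clusters,
)
from mitorearr.gene_order import GeneOrder
from mitorearr.signed import as_signed

from conftest import random_gene_order, random_signed_circle


def oracle_contains(order, clu_genes, max_insertions):
    """Brute-force scan: all rotations, both readings, leading-anchor match."""
    seq = list(as_signed(order))
    n = len(seq)

    def revflip(s):
        return [(g[0], -g[1]) for g in reversed(s)]

    best = None
    for reading in (list(clu_genes), revflip(list(clu_genes))):
        for rot in range(n):
            lin = seq[rot:] + seq[:rot]
            if lin[0] != reading[0]:
                continue
            i, used = 1, 0
            for target in reading[1:]:
                while i < n and lin[i] != target:
                    i += 1
                    used += 1
                if i >= n:
                    used = None
                    break
                i += 1
            if used is not None:
                used -= 0  # insertions = skipped genes between matches
                if best is None or used < best:
                    best = used
    if best is None or best > max_insertions:
        return None
    return best


class TestContainsCluster:
    def test_ancestral_pairs(self, ancestor):
        assert contains_cluster(ancestor, cluster("nad6", "cob")).exact
        assert contains_cluster(ancestor, cluster("nad6", "trnT", "cob")) is None

    def test_insertion_variant(self, ancestor):
        # nad2 ... trnW sits between nad2 and -trnC in the ancestor; a
        # two-gene cluster spanning one intervening gene needs tolerance 1
        m = contains_cluster(ancestor, cluster("nad2", "-trnC"), max_insertions=1)
        assert m is not None and m.insertions_used == 1 and not m.exact
        assert contains_cluster(ancestor, cluster("nad2", "-trnC")) is None

    def test_direction_reversal_rule(self, ancestor):
        # ancestor holds trnI ... and -trnQ: cluster (trnQ, -trnI) matches
        # only through the reversed reading (trnI, -trnQ)
        assert contains_cluster(ancestor, cluster("trnQ", "-trnI")) is not None

    def test_absent_gene_raises(self):
        with pytest.raises(ValueError, match="absent from the order"):
            contains_cluster((1, 2, 3, 4), cluster(1, 5))

    def test_agrees_with_bruteforce_scan(self, rng):
        for _ in range(1000):
            n = int(rng.integers(5, 13))
            order = random_signed_circle(rng, n)
            k = int(rng.integers(2, 5))
            tol = int(rng.integers(0, 3))
            # random cluster over the same alphabet
            labels = rng.choice(n, size=k, replace=False) + 1
            signs = rng.integers(0, 2, size=k) * 2 - 1
            clu = tuple(int(l * s) for l, s in zip(labels, signs))
            got = contains_cluster(order, clu, tol)
            want = oracle_contains(order, as_signed(clu), tol)
            if want is None:
                assert got is None
            else:
                assert got is not None and got.insertions_used == want


class TestFindSharedClusters:
    def test_identical_orders_share_whole_circle(self, ancestor):
        out = find_shared_clusters([ancestor, ancestor.with_taxon("b")])
        assert len(out) == 1 and len(out[0]) == 37

    def test_toy_transposition(self):
        got = find_shared_clusters([(1, 2, 3, 4, 5), (1, 2, 4, 3, 5)])
        forms = {c.canonical_form() for c in got}
        assert forms == {GeneCluster((5, 1, 2)).canonical_form()}

    def test_single_inversion_leaves_complement_run(self, ancestor):
        from mitorearr.simulate import RearrangementEvent

        post = RearrangementEvent("inversion", 5, 4).apply(ancestor.genes)
        out = find_shared_clusters(
            [ancestor, GeneOrder("inv", post)], max_len=None
        )
        # complement of a 4-gene inversion: one unbroken 33-gene run plus the
        # inverted segment itself (conserved internally, up to direction)
        lengths = sorted(len(c) for c in out)
        assert lengths == [4, 33]

    def test_results_are_shared_and_maximal(self, rng):
        for i in range(20):
            orders = [random_signed_circle(rng, 8) for _ in range(2)]
            out = find_shared_clusters(orders, max_len=None)
            for clu in out:
                for o in orders:
                    assert contains_cluster(o, clu) is not None
            forms = [c.canonical_form() for c in out]
            assert len(set(forms)) == len(forms)


class TestDerivedClusters:
    def test_ancestor_ingroup_has_nothing_derived(self, ancestor):
        assert derived_clusters([ancestor], ancestor) == []

    def test_unique_clade_inversion_is_recovered(self, ancestor):
        from mitorearr.simulate import RearrangementEvent

        ev = RearrangementEvent("inversion", 10, 2)
        post = GeneOrder("in1", ev.apply(ancestor.genes))
        out = derived_clusters(
            [post, post.with_taxon("in2")], ancestor, [ancestor.with_taxon("og")]
        )
        assert out, "the inversion junctions must yield derived clusters"
        for clu in out:
            assert contains_cluster(ancestor, clu) is None


class TestBuildCladogram:
    def _orders_for(self, taxa):
        rng = np.random.default_rng(1)
        return {t: random_gene_order(rng, t) for t in taxa}

    def test_nested_named_clusters_give_pectinate_tree(self, ancestor):
        from mitorearr.simulate import fig1_mini

        fix = fig1_mini()
        by_id = {o.taxon_id: o for o in fix["orders"]}
        orders = [by_id[t] for t in ("t06", "t07", "t08", "t10")]
        named = [
            (cluster("nad2", "trnM"), 0),    # all four
            (cluster("trnS1", "trnI"), 0),   # t08, t10
            (
                cluster("trnY", "trnQ", "trnV", "trnL2", "rrnS", "rrnL"),
                0,
            ),  # t10 only: below the 2-taxon floor, ignored
        ]
        cg = build_cladogram(orders, fix["ancestor"], named_clusters=named)
        assert cg.to_newick() == "((t08,t10)trnS1-trnI,t06,t07)nad2-trnM;"

    def test_no_derived_clusters_star_tree(self, ancestor):
        orders = [ancestor.rotated(k).with_taxon(f"t{k}") for k in range(4)]
        cg = build_cladogram(orders, ancestor)
        assert cg.clade_sets() == set()
        assert cg.to_newick() == "(t0,t1,t2,t3);"

    def test_conflict_tiebreak_and_log(self, ancestor):
        # P supports {A,B}, Q supports {B,C}: equal support, equal size ->
        # lexicographically smallest member wins; Q is logged
        from mitorearr.simulate import RearrangementEvent

        evP = RearrangementEvent("inversion", 4, 2)
        evQ = RearrangementEvent("inversion", 20, 2)
        gA = evP.apply(ancestor.genes)
        gB = evQ.apply(evP.apply(ancestor.genes))
        gC = evQ.apply(ancestor.genes)
        orders = [
            GeneOrder("A", gA), GeneOrder("B", gB), GeneOrder("C", gC)
        ]
        p_clu = derived_clusters([orders[0], orders[1]], ancestor, [orders[2]])
        q_clu = derived_clusters([orders[1], orders[2]], ancestor, [orders[0]])
        named = [(p_clu[0], 0), (q_clu[0], 0)]
        cg = build_cladogram(orders, ancestor, named_clusters=named)
        assert cg.clade_sets() == {frozenset(["A", "B"])}
        assert len(cg.conflicts) == 1
        assert cg.conflicts[0]["taxa"] == "B,C"

    def test_laminar_family_and_exclusivity(self):
        from mitorearr.simulate import simulate_clade_markers

        res = simulate_clade_markers(10, shape="random", seed=7)
        orders = list(res.tip_orders.values())
        cg = build_cladogram(orders, res.root_order)
        sets = list(cg.clade_sets())
        for i, s in enumerate(sets):
            for t in sets[i + 1:]:
                inter = s & t
                assert inter in (frozenset(), s, t), "clades must be laminar"
        by_id = {o.taxon_id: o for o in orders}
        for clade in cg.clades:
            for clu in clade.supporting_clusters:
                for taxon, order in by_id.items():
                    match = contains_cluster(order, clu) is not None
                    assert match == (taxon in clade.taxa)

    def test_recovery_in_marker_regime(self):
        from mitorearr.simulate import simulate_clade_markers
        from mitorearr.trees import clade_sets_from_newick, rf_rooted

        hits = 0
        for rep in range(30):
            n = 8 + rep % 9
            res = simulate_clade_markers(n, shape="random", seed=100 + rep)
            cg = build_cladogram(
                list(res.tip_orders.values()), res.root_order
            )
            rf = rf_rooted(cg.clade_sets(), clade_sets_from_newick(res.newick))
            hits += rf == 0
        assert hits >= 27
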