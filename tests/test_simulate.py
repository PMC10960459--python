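"""Rearrangement and codon simulators: determinism, replay, event laws."""

import numpy as np
import pytest

from mitorearr.breakpoints import adjacencies, breakpoint_distance
from mitorearr.clusters import contains_cluster, derived_clusters
from mitorearr.gene_order import dedup_patterns, parse_genbank, read_orders
from mitorearr.simulate import (
    RearrangementEvent,
    fig1_mini,
    simulate_clade_markers,
    simulate_codon_pair,
    simulate_rearrangements,
    write_fixture_set,
)

BAL4 = "((a:1,b:1):1,(c:1,d:1):1);"


class TestSimulateRearrangements:
    def test_zero_rates_single_pattern(self):
        res = simulate_rearrangements(BAL4, rates={}, seed=1)
        assert len(dedup_patterns(list(res.tip_orders.values()))) == 1
        for order in res.tip_orders.values():
            assert order.genes == res.root_order.genes

    def test_replay_reproduces_tips(self):
        res = simulate_rearrangements(
            BAL4, rates={"inv": 1.5, "trans": 0.7, "invtrans": 0.4}, seed=9
        )
        replayed = res.replay()
        for tip, order in res.tip_orders.items():
            assert replayed[tip].genes == order.genes

    def test_same_seed_identical(self):
        kw = dict(rates={"inv": 1.0, "trans": 0.5}, seed=11)
        r1 = simulate_rearrangements(BAL4, **kw)
        r2 = simulate_rearrangements(BAL4, **kw)
        assert r1.events == r2.events
        for tip in r1.tip_orders:
            assert r1.tip_orders[tip].genes == r2.tip_orders[tip].genes

    def test_different_seeds_differ(self):
        r1 = simulate_rearrangements(BAL4, rates={"inv": 2.0}, seed=1)
        r2 = simulate_rearrangements(BAL4, rates={"inv": 2.0}, seed=2)
        assert any(
            r1.tip_orders[t].genes != r2.tip_orders[t].genes
            for t in r1.tip_orders
        )

    def test_poisson_event_counts_on_star_tree(self):
        lam = 2.0
        star = "(" + ",".join(f"s{i}:1" for i in range(100)) + ");"
        res = simulate_rearrangements(star, rates={"inv": lam}, seed=3)
        counts = [len(evs) for evs in res.events.values()]
        mean = np.mean(counts)
        assert abs(mean - lam) <= 3 * np.sqrt(lam / 100)

    def test_forced_clade_inversion_yields_synapomorphy(self):
        # one inversion on the edge subtending {c,d}, nothing elsewhere:
        # the clade shares derived clusters that the others lack
        res = simulate_rearrangements(BAL4, rates={}, seed=0)
        anc = res.root_order
        ev = RearrangementEvent("inversion", 12, 3)
        tips = {
            t: (o if t in ("a", "b") else o.__class__(t, ev.apply(o.genes)))
            for t, o in res.tip_orders.items()
        }
        found = derived_clusters(
            [tips["c"], tips["d"]], anc, [tips["a"], tips["b"]]
        )
        assert found
        created, _ = ev.adjacency_change(anc.genes)
        covered = set()
        for clu in found:
            for i in range(len(clu.genes) - 1):
                from mitorearr.breakpoints import normalize_adjacency

                covered.add(normalize_adjacency(clu.genes[i], clu.genes[i + 1]))
        assert created <= covered

    def test_unequal_rate_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown event kind"):
            simulate_rearrangements(BAL4, rates={"duplication": 1.0})

    def test_empty_tree_rejected(self):
        with pytest.raises(Exception):
            simulate_rearrangements(";", rates={})


class TestEventApplication:
    def test_event_length_bounds(self, ancestor):
        with pytest.raises(ValueError, match="segment length"):
            RearrangementEvent("inversion", 0, 36).apply(ancestor.genes)

    def test_transposition_needs_destination(self, ancestor):
        with pytest.raises(ValueError, match="dest"):
            RearrangementEvent("transposition", 0, 2).apply(ancestor.genes)

    def test_gene_content_preserved(self, ancestor, rng):
        for kind in ("inversion", "transposition", "inverted_transposition"):
            for _ in range(30):
                length = int(min(rng.geometric(0.5), 35))
                start = int(rng.integers(37))
                dest = None if kind == "inversion" else int(
                    rng.integers(1, 37 - length)
                )
                post = RearrangementEvent(kind, start, length, dest).apply(
                    ancestor.genes
                )
                assert sorted(g.name for g in post) == sorted(
                    g.name for g in ancestor.genes
                )


class TestCladeMarkers:
    def test_marker_junctions_unique_to_their_clade(self):
        res = simulate_clade_markers(12, shape="random", seed=21)
        tip_adj = {t: adjacencies(o) for t, o in res.tip_orders.items()}
        root_adj = adjacencies(res.root_order)
        leafsets = res.edge_leafsets()
        for eid, log in res.adjacency_log.items():
            below = leafsets[eid]
            for created, _ in log:
                for adj in created:
                    assert adj not in root_adj
                    for tip, adjs in tip_adj.items():
                        assert (adj in adjs) == (tip in below)

    def test_pectinate_four_taxa_two_clades_recovered(self):
        from mitorearr.clusters import build_cladogram
        from mitorearr.trees import clade_sets_from_newick, rf_rooted

        res = simulate_clade_markers(4, shape="pectinate", seed=2)
        cg = build_cladogram(list(res.tip_orders.values()), res.root_order)
        true_sets = clade_sets_from_newick(res.newick)
        assert len(true_sets) == 2
        assert rf_rooted(cg.clade_sets(), true_sets) == 0

    def test_same_seed_identical(self):
        r1 = simulate_clade_markers(8, shape="balanced", seed=5)
        r2 = simulate_clade_markers(8, shape="balanced", seed=5)
        assert r1.events == r2.events
        assert r1.newick == r2.newick

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="n_taxa"):
            simulate_clade_markers(3)

    def test_breakpoint_accounting_inversion_only_path(self):
        # with unique junctions and no reuse, each inversion adds exactly 2
        # breakpoints relative to the root
        for seed in range(5):
            res = simulate_clade_markers(8, shape="balanced", seed=30 + seed)
            for tip, order in res.tip_orders.items():
                path = res.events_on_path(tip)
                if not all(ev.kind == "inversion" for ev in path):
                    continue
                bp = breakpoint_distance(order, res.root_order).breakpoints
                assert bp == 2 * len(path)


class TestCodonPair:
    def test_zero_targets_identical(self):
        pair = simulate_codon_pair(200, 0.0, 0.0, seed=4)
        assert pair.ancestor == pair.derived
        from mitorearr.kaks import kaks

        r = kaks(pair.ancestor, pair.derived)
        assert (r.Ka, r.Ks) == (0.0, 0.0)

    def test_same_seed_identical(self):
        p1 = simulate_codon_pair(500, 0.2, 0.4, seed=8)
        p2 = simulate_codon_pair(500, 0.2, 0.4, seed=8)
        assert p1 == p2

    def test_sequences_are_stop_free(self):
        from mitorearr.kaks import count_sites

        pair = simulate_codon_pair(1000, 0.3, 0.5, seed=10)
        count_sites(pair.ancestor)  # raises on internal stops
        count_sites(pair.derived)

    def test_infeasible_targets_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_codon_pair(100, 5.0, 5.0, seed=0)


class TestFixtureSet:
    def test_empty_config_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="empty fixture config"):
            write_fixture_set(str(tmp_path), {})

    def test_simulated_fixture_roundtrips(self, tmp_path):
        out = tmp_path / "fix"
        config = {
            "shape": "balanced:8",
            "rates": {"inv": 0.8, "trans": 0.3},
            "seed": 13,
            "n_codons": 200,
            "target_ka": 0.1,
            "target_ks": 0.3,
        }
        paths = write_fixture_set(str(out), config)
        assert all(p.startswith(str(out)) for p in paths)
        orders = read_orders(str(out / "orders.txt"))
        assert len(orders) == 8
        gb = parse_genbank(str(out / "genomes.gbk"))
        assert [o.genes for o in gb] == [o.genes for o in orders]
        from Bio import SeqIO

        recs = list(SeqIO.parse(str(out / "codons.fasta"), "fasta"))
        assert len(recs) == 2 and len(recs[0].seq) == 600

    def test_fig1_mini_fixture_files(self, tmp_path):
        out = tmp_path / "fig1"
        write_fixture_set(str(out), {"fig1_mini": True})
        orders = read_orders(str(out / "orders.txt"))
        assert len(orders) == 12
        fix = fig1_mini()
        assert [o.genes for o in orders] == [o.genes for o in fix["orders"]]
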