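"""Weighted node features: neighbourhoods, vocabularies, the three approaches."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import agewalk as aw
from agewalk.features import (
    N_BINS,
    WeightVocabulary,
    round_half_away,
)
from agewalk.network import DataError

from conftest import make_weighted_snapshot


def brute_force_cvm(a, b):
    """Independent direct transcription of the two-sample statistic."""
    a, b = list(a), list(b)
    n, m = len(a), len(b)

    def F(sample, x):
        return sum(1 for s in sample if s <= x) / len(sample)

    total = sum((F(a, x) - F(b, x)) ** 2 for x in a)
    total += sum((F(a, x) - F(b, x)) ** 2 for x in b)
    return n * m / (n + m) ** 2 * total


class TestNeighborhoods:
    def test_triangle_center(self, triangle):
        snap = aw.Snapshot("s", triangle)
        assert aw.neighborhood_edges(snap, "a", "t1") == {
            frozenset(("a", "b")),
            frozenset(("a", "c")),
        }
        assert aw.neighborhood_edges(snap, "a", "t2") == {frozenset(("b", "c"))}
        assert aw.neighborhood_edges(snap, "a", "t3") == set()
        assert aw.neighborhood_edges(snap, "a", "t4") == set()

    def test_path_endpoint(self, path4):
        snap = aw.Snapshot("s", path4)
        assert aw.neighborhood_edges(snap, "a", "t1") == {frozenset(("a", "b"))}
        assert aw.neighborhood_edges(snap, "a", "t2") == set()
        assert aw.neighborhood_edges(snap, "a", "t3") == {frozenset(("b", "c"))}
        # c-d has one end at distance 3 from a, so it is not a T4 edge
        assert aw.neighborhood_edges(snap, "a", "t4") == set()

    def test_isolated_node_all_empty(self):
        g = nx.Graph()
        g.add_node("x")
        g.add_edge("a", "b")
        snap = aw.Snapshot("s", g)
        for t in ("t1", "t2", "t3", "t4"):
            assert aw.neighborhood_edges(snap, "x", t) == set()

    def test_absent_node_rejected(self, triangle):
        with pytest.raises(KeyError):
            aw.neighborhood_edges(aw.Snapshot("s", triangle), "zzz", "t1")

    def test_two_hop_means_distance_exactly_two(self):
        # star plus pendant: from the centre every node is at distance 1,
        # so T4 must be empty even though leaves interconnect via the centre
        g = nx.star_graph(4)
        snap = aw.Snapshot("s", g)
        assert aw.neighborhood_edges(snap, 0, "t3") == set()
        assert aw.neighborhood_edges(snap, 0, "t4") == set()


class TestVocabulary:
    def test_raw_union_and_sort(self, toy_weighted_dynamic):
        vocab = aw.build_vocabulary(toy_weighted_dynamic, encoding="raw")
        assert vocab.values == (-20.0, 10.0, 50.0)
        assert vocab.W == 3

    def test_binned_always_200(self, toy_weighted_dynamic):
        vocab = aw.build_vocabulary(toy_weighted_dynamic, encoding="binned")
        assert vocab.W == N_BINS == 200

    def test_rounding_half_away_from_zero(self):
        s = make_weighted_snapshot([("a", "b", 1.234), ("b", "c", 1.235)])
        dyn = aw.DynamicNetwork([s], weighted=True)
        vocab = aw.build_vocabulary(dyn, encoding="raw", rounding_decimals=2)
        assert vocab.values == (1.23, 1.24)

    def test_unweighted_rejected(self, triangle):
        dyn = aw.DynamicNetwork([aw.Snapshot("s", triangle)], weighted=False)
        with pytest.raises(DataError):
            aw.build_vocabulary(dyn)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(min_value=-1e3, max_value=1e3), st.integers(0, 4))
    def test_round_half_away_magnitude(self, x, d):
        r = float(round_half_away(x, d))
        assert abs(r - x) <= 0.5 * 10 ** (-d) + 1e-12
        assert np.sign(r) in (0.0, np.sign(x))


class TestBinIndex:
    @pytest.mark.parametrize(
        "w, idx",
        [(-100.0, 0), (100.0, 199), (-0.5, 99), (0.0, 100), (99.999, 199)],
    )
    def test_examples(self, w, idx):
        assert aw.bin_index(w) == idx

    @pytest.mark.parametrize("w", [-100.001, 100.001])
    def test_out_of_range(self, w):
        with pytest.raises(ValueError):
            aw.bin_index(w)


class TestWeightCountVector:
    def test_counts(self):
        vocab = WeightVocabulary(
            encoding="raw", values=(-20.0, 10.0, 50.0), rounding_decimals=2
        )
        counts = aw.weight_count_vector([10.0, 10.0, 50.0], vocab)
        np.testing.assert_array_equal(counts, [0, 2, 1])

    def test_empty_edge_set(self):
        vocab = WeightVocabulary(encoding="raw", values=(1.0,), rounding_decimals=2)
        np.testing.assert_array_equal(aw.weight_count_vector([], vocab), [0])

    def test_conservation(self):
        rng = np.random.default_rng(4)
        vocab = WeightVocabulary(
            encoding="binned",
            values=tuple(float(b) for b in range(-100, 100)),
        )
        w = rng.uniform(-100, 100, size=37)
        assert aw.weight_count_vector(w, vocab).sum() == 37


class TestApproach1:
    def test_per_type_length(self, toy_weighted_dynamic):
        vocab = aw.build_vocabulary(toy_weighted_dynamic, encoding="raw")
        fm = aw.approach1_features(toy_weighted_dynamic, "t1", vocab)
        assert fm.length == vocab.W * toy_weighted_dynamic.n == 6

    def test_all_type_length(self, toy_weighted_dynamic):
        vocab = aw.build_vocabulary(toy_weighted_dynamic, encoding="raw")
        fm = aw.approach1_features(toy_weighted_dynamic, "all", vocab)
        assert fm.length == vocab.W * 4 * toy_weighted_dynamic.n == 24

    def test_count_conservation(self, toy_weighted_dynamic):
        dyn = toy_weighted_dynamic
        vocab = aw.build_vocabulary(dyn, encoding="raw")
        fm = aw.approach1_features(dyn, "t1", vocab)
        for gi, g in enumerate(fm.genes):
            for si, snap in enumerate(dyn):
                block = fm.X[gi, si * vocab.W : (si + 1) * vocab.W]
                expected = len(aw.neighborhood_edges(snap, g, "t1"))
                assert block.sum() == expected

    def test_absent_node_zero_block(self):
        s0 = make_weighted_snapshot([("a", "b", 1.0)], age="s0")
        s1 = make_weighted_snapshot([("c", "d", 2.0)], age="s1")
        dyn = aw.DynamicNetwork([s0, s1], weighted=True)
        vocab = aw.build_vocabulary(dyn, encoding="raw")
        fm = aw.approach1_features(dyn, "t1", vocab)
        row = fm.X[fm.genes.index("a")]
        assert row[: vocab.W].sum() == 1  # present in snapshot 0
        assert row[vocab.W :].sum() == 0  # absent from snapshot 1

    def test_all_block_consistency(self, toy_weighted_dynamic):
        """ALL interleaves the per-type W-blocks within each snapshot."""
        dyn = toy_weighted_dynamic
        vocab = aw.build_vocabulary(dyn, encoding="raw")
        fm_all = aw.approach1_features(dyn, "all", vocab)
        per_type = {
            t: aw.approach1_features(dyn, t, vocab) for t in ("t1", "t2", "t3", "t4")
        }
        W, N = vocab.W, dyn.n
        for gi in range(len(fm_all.genes)):
            for si in range(N):
                for ti, t in enumerate(("t1", "t2", "t3", "t4")):
                    start = si * 4 * W + ti * W
                    np.testing.assert_array_equal(
                        fm_all.X[gi, start : start + W],
                        per_type[t].X[gi, si * W : (si + 1) * W],
                    )


class TestApproach2:
    def test_identical_nonconstant_counts_correlate_one(self):
        # counts over vocab {1, 2} are (1, 2) in both snapshots: identical
        # and non-constant, so every pairwise correlation is 1
        s0 = make_weighted_snapshot(
            [("a", "b", 1.0), ("a", "c", 2.0), ("a", "d", 2.0)], age="s0"
        )
        s1 = make_weighted_snapshot(
            [("a", "b", 1.0), ("a", "c", 2.0), ("a", "d", 2.0)], age="s1"
        )
        dyn = aw.DynamicNetwork([s0, s1], weighted=True)
        vocab = aw.build_vocabulary(dyn, encoding="raw")
        fm = aw.approach2_features(dyn, "t1", vocab)
        row = fm.X[fm.genes.index("a")]
        np.testing.assert_allclose(row, 1.0)

    def test_length_closed_form(self):
        snaps = [
            make_weighted_snapshot([("a", "b", float(i + 1))], age=f"s{i}")
            for i in range(36)
        ]
        dyn = aw.DynamicNetwork(snaps, weighted=True)
        vocab = aw.build_vocabulary(dyn, encoding="binned")
        fm = aw.approach2_features(dyn, "t1", vocab)
        assert fm.length == 36 * 35 // 2 == 630

    def test_pearson_value(self):
        from agewalk.features import _pearson_upper

        counts = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        np.testing.assert_allclose(_pearson_upper(counts), [-0.5])

    def test_zero_variance_convention(self):
        from agewalk.features import _pearson_upper

        counts = np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
        np.testing.assert_allclose(_pearson_upper(counts), [0.0])

    def test_single_snapshot_rejected(self):
        s = make_weighted_snapshot([("a", "b", 1.0)])
        dyn = aw.DynamicNetwork([s], weighted=True)
        vocab = aw.build_vocabulary(dyn, encoding="raw")
        with pytest.raises(DataError):
            aw.approach2_features(dyn, "t1", vocab)


class TestCramerVonMises:
    def test_identical_samples_zero(self):
        assert aw.cramer_von_mises([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_singleton_samples(self):
        assert aw.cramer_von_mises([1.0], [2.0]) == pytest.approx(
            brute_force_cvm([1.0], [2.0])
        )

    def test_symmetric(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=10), rng.normal(1, 1, size=7)
        assert aw.cramer_von_mises(a, b) == pytest.approx(aw.cramer_von_mises(b, a))

    def test_matches_brute_force_on_random_samples(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            n, m = int(rng.integers(1, 50)), int(rng.integers(1, 50))
            a = rng.normal(size=n)
            b = rng.normal(rng.uniform(-1, 1), 1, size=m)
            if rng.random() < 0.3:  # exercise ties
                b[: min(n, m) // 2] = a[: min(n, m) // 2]
            assert aw.cramer_von_mises(a, b) == pytest.approx(
                brute_force_cvm(a, b), abs=1e-12
            )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            aw.cramer_von_mises([], [1.0])


class TestApproach3:
    def test_length_per_type(self, toy_weighted_dynamic):
        fm = aw.approach3_features(toy_weighted_dynamic, "t1")
        assert fm.length == toy_weighted_dynamic.n == 2

    def test_all_concatenates_types(self, toy_weighted_dynamic):
        fm_all = aw.approach3_features(toy_weighted_dynamic, "all")
        parts = [
            aw.approach3_features(toy_weighted_dynamic, t)
            for t in ("t1", "t2", "t3", "t4")
        ]
        np.testing.assert_array_equal(
            fm_all.X, np.concatenate([p.X for p in parts], axis=1)
        )

    def test_neighborhood_equal_to_pool_gives_zero(self):
        # one snapshot, every edge weight equal: every neighbourhood
        # distribution coincides with the pooled distribution
        s = make_weighted_snapshot(
            [("a", "b", 3.0), ("b", "c", 3.0), ("a", "c", 3.0)]
        )
        dyn = aw.DynamicNetwork([s], weighted=True)
        fm = aw.approach3_features(dyn, "t1")
        np.testing.assert_allclose(fm.X, 0.0)

    def test_empty_neighborhood_zero(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        g.add_node("x")
        dyn = aw.DynamicNetwork([aw.Snapshot("s", g)], weighted=True)
        fm = aw.approach3_features(dyn, "t1")
        assert fm.X[fm.genes.index("x")].sum() == 0.0


class TestAllProposedFeatures:
    def test_thirty_matrices(self, toy_weighted_dynamic):
        feats = aw.all_proposed_features(toy_weighted_dynamic)
        assert len(feats) == 30
        raw = [n for n in feats if "-nobin" in n]
        binned = [n for n in feats if "-bin" in n and "-nobin" not in n]
        assert len(raw) == 15 and len(binned) == 15

    def test_naming_convention(self, toy_weighted_dynamic):
        feats = aw.all_proposed_features(toy_weighted_dynamic)
        for expected in ("Diff-nobin-2", "Diff-bin-1", "Diff-nobin-cor-2",
                         "Diff-bin-cvm-all", "Diff-nobin-cvm-4"):
            assert expected in feats

    def test_declared_lengths_consistent(self, toy_weighted_dynamic):
        feats = aw.all_proposed_features(toy_weighted_dynamic)
        for fm in feats.values():
            assert fm.meta["length"] == fm.X.shape[1]

    def test_closed_form_lengths(self, toy_weighted_dynamic):
        dyn = toy_weighted_dynamic
        N = dyn.n
        feats = aw.all_proposed_features(dyn)
        W_raw = aw.build_vocabulary(dyn, encoding="raw").W
        assert feats["Diff-nobin-1"].length == W_raw * N
        assert feats["Diff-nobin-all"].length == W_raw * 4 * N
        assert feats["Diff-bin-1"].length == 200 * N
        assert feats["Diff-nobin-cor-3"].length == N * (N - 1) // 2
        assert feats["Diff-bin-cor-all"].length == 4 * N * (N - 1) // 2
        assert feats["Diff-nobin-cvm-2"].length == N
        assert feats["Diff-bin-cvm-all"].length == 4 * N

    def test_permutation_invariance(self, toy_weighted_dynamic):
        """Relabelling genes permutes rows but leaves vectors unchanged."""
        mapping = {"a": "zz", "b": "mm", "c": "aa"}
        relabeled = aw.DynamicNetwork(
            [
                aw.Snapshot(s.age_label, nx.relabel_nodes(s.graph, mapping))
                for s in toy_weighted_dynamic
            ],
            weighted=True,
        )
        f1 = aw.all_proposed_features(toy_weighted_dynamic)["Diff-nobin-all"]
        f2 = aw.all_proposed_features(relabeled)["Diff-nobin-all"]
        for old, new in mapping.items():
            np.testing.assert_array_equal(f1.vector(old), f2.vector(new))


class TestStaticCounterparts:
    def make_static(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.3)
        g.add_edge("b", "c", weight=0.7)
        g.add_edge("a", "c", weight=0.7)
        return g

    def test_nobin_t2_counts(self):
        fm = aw.static_counterpart_features(self.make_static(), approach=1, t="t2")
        assert fm.name == "Static-nobin-2"
        assert fm.length == 2  # W = |{0.3, 0.7}|
        # T2 of node a = edge (b, c) with weight 0.7
        np.testing.assert_array_equal(fm.vector("a"), [0.0, 1.0])

    def test_binned_length_200(self):
        fm = aw.static_counterpart_features(
            self.make_static(), approach=1, t="t1", encoding="binned"
        )
        assert fm.length == 200

    def test_approach2_falls_back_to_approach1(self, caplog):
        with caplog.at_level("INFO"):
            fm = aw.static_counterpart_features(self.make_static(), approach=2, t="t2")
        assert fm.name == "Static-nobin-2"
        assert fm.meta["approach"] == 1


class TestWeightedCentralities:
    def test_uniform_triangle_strength(self):
        g = nx.Graph()
        for u, v in [("a", "b"), ("b", "c"), ("a", "c")]:
            g.add_edge(u, v, weight=0.4)
        dyn = aw.DynamicNetwork([aw.Snapshot("s", g)], weighted=True)
        feats = aw.weighted_centrality_features(dyn)
        assert set(feats) == {"DegC-wt", "ClusC-wt", "CloseC-wt", "BetwC-wt", "EigenC-wt"}
        np.testing.assert_allclose(feats["DegC-wt"].X[:, 0], 0.8)

    def test_star_center_betweenness(self):
        g = nx.Graph()
        for leaf in ("x", "y", "z"):
            g.add_edge("hub", leaf, weight=1.0)
        dyn = aw.DynamicNetwork([aw.Snapshot("s", g)], weighted=True)
        feats = aw.weighted_centrality_features(dyn)
        fm = feats["BetwC-wt"]
        assert fm.vector("hub")[0] == pytest.approx(3.0)  # 3 leaf pairs via hub

    def test_uniform_triangle_eigenvector_equal(self):
        g = nx.Graph()
        for u, v in [("a", "b"), ("b", "c"), ("a", "c")]:
            g.add_edge(u, v, weight=0.4)
        dyn = aw.DynamicNetwork([aw.Snapshot("s", g)], weighted=True)
        eig = aw.weighted_centrality_features(dyn)["EigenC-wt"].X[:, 0]
        np.testing.assert_allclose(eig, eig[0])

    def test_length_is_snapshot_count(self, small_suite):
        feats = aw.weighted_centrality_features(small_suite.w_netwalk_dynamic_nondiff)
        N = small_suite.w_netwalk_dynamic_nondiff.n
        for fm in feats.values():
            assert fm.length == N
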