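"""Threshold graphs, HC, bottleneck MSTs and the k-subset extrema."""

import itertools

import networkx as nx
import numpy as np
import pytest

import hapconn as h
from hapconn.errors import InputError

from conftest import exhaustive_hc_extrema, random_symmetric_matrix

SUBSET_B = ["b2", "b4", "b6", "b8", "b10", "b12"]


def threshold_scan_hc(D, Y):
    """Independent oracle: smallest t in the sorted distance list (plus 0)
    with G_t(Y) connected, checked with networkx connectivity."""
    idx = D.subset_indices(Y)
    if len(idx) == 1:
        return 0.0
    sub = D.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    for t in np.unique(np.concatenate(([0.0], sub[iu]))):
        g = nx.Graph()
        g.add_nodes_from(range(len(idx)))
        mask = sub[iu] <= t
        g.add_edges_from(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))
        if nx.is_connected(g):
            return float(t)
    raise AssertionError("complete graph must be connected")


class TestThresholdGraph:
    def test_figure1b_subset_disconnected_at_t2(self, fig1b_dist):
        g = h.threshold_graph(fig1b_dist, SUBSET_B, 2)
        assert not g.is_connected

    def test_large_threshold_gives_complete_graph(self, fig1b_dist):
        t = float(fig1b_dist.values.max())
        g = h.threshold_graph(fig1b_dist, None, t)
        n = fig1b_dist.n
        assert len(g.edges) == n * (n - 1) // 2

    def test_zero_threshold_edgeless(self, fig1a_dist):
        g = h.threshold_graph(fig1a_dist, None, 0)
        assert len(g.edges) == 0

    def test_unknown_label_rejected(self, fig1a_dist):
        with pytest.raises(InputError, match="unknown"):
            h.threshold_graph(fig1a_dist, ["a1", "nope"], 1)

    def test_edge_weights_bounded_by_threshold(self, fig1b_dist):
        g = h.threshold_graph(fig1b_dist, None, 3)
        assert all(w <= 3 for _, w in g.edges)


class TestHaplotypeConnectivity:
    def test_figure1a_full_set(self, fig1a_dist):
        assert h.haplotype_connectivity(fig1a_dist) == 2

    def test_figure1b_even_subset(self, fig1b_dist):
        assert h.haplotype_connectivity(fig1b_dist, SUBSET_B) == 5

    def test_singleton_is_zero(self, fig1a_dist):
        assert h.haplotype_connectivity(fig1a_dist, ["a3"]) == 0

    def test_empty_subset_rejected(self, fig1a_dist):
        with pytest.raises(InputError, match="non-empty"):
            h.haplotype_connectivity(fig1a_dist, [])

    def test_matches_threshold_scan_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            D = random_symmetric_matrix(rng, 8)
            assert h.haplotype_connectivity(D) == threshold_scan_hc(D, None)
            sub = list(rng.choice(D.labels, 4, replace=False))
            assert h.haplotype_connectivity(D, sub) == threshold_scan_hc(
                D, sub
            )

    def test_duplicate_haplotypes_at_distance_zero(self):
        D = h.validate_distance_matrix(
            [[0, 0, 2], [0, 0, 2], [2, 2, 0]], ["a", "a2", "b"]
        )
        assert h.haplotype_connectivity(D) == 2
        assert h.haplotype_connectivity(D, ["a", "a2"]) == 0


class TestBottleneckSpanningTree:
    def test_singleton_tree(self, fig1a_dist):
        res = h.bottleneck_spanning_tree(fig1a_dist, ["a1"])
        assert res.edges == ()
        assert res.bottleneck == 0

    def test_figure1b_subset_bottleneck(self, fig1b_dist):
        res = h.bottleneck_spanning_tree(fig1b_dist, SUBSET_B)
        assert res.bottleneck == 5

    def test_is_spanning_tree_with_correct_bottleneck(self):
        rng = np.random.default_rng(23)
        for _ in range(15):
            D = random_symmetric_matrix(rng, 10)
            res = h.bottleneck_spanning_tree(D)
            g = nx.Graph((u, v) for u, v, _ in res.edges)
            assert g.number_of_edges() == D.n - 1
            assert nx.is_connected(g)
            assert res.bottleneck == max(w for _, _, w in res.edges)
            assert res.bottleneck == h.haplotype_connectivity(D)


class TestExtrema:
    def test_trivial_k_values(self, fig1b_dist):
        n = fig1b_dist.n
        hc_full = h.haplotype_connectivity(fig1b_dist)
        assert h.hc_min(fig1b_dist, 1) == 0
        assert h.hc_max(fig1b_dist, 1) == 0
        assert h.hc_min(fig1b_dist, n) == hc_full
        assert h.hc_max(fig1b_dist, n) == hc_full

    def test_k_out_of_range_rejected(self, fig1a_dist):
        with pytest.raises(InputError, match="out of range"):
            h.hc_min(fig1a_dist, 0)
        with pytest.raises(InputError, match="out of range"):
            h.hc_max(fig1a_dist, fig1a_dist.n + 1)

    def test_extrema_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(29)
        for _ in range(10):
            n = int(rng.integers(5, 10))
            D = random_symmetric_matrix(rng, n)
            prof = h.ConnectivityProfile(D)
            for k in range(2, n):
                lo, hi = exhaustive_hc_extrema(D, k)
                assert prof.hc_min(k) == lo
                assert prof.hc_max(k) == hi

    def test_bounds_agree_with_separate_calls(self):
        rng = np.random.default_rng(31)
        D = random_symmetric_matrix(rng, 8)
        for k in range(1, 9):
            b = h.connectivity_bounds(D, k)
            assert b.hc_min == h.hc_min(D, k)
            assert b.hc_max == h.hc_max(D, k)

    def test_hc_min_monotone_in_k(self):
        # pruning a leaf off a bottleneck tree of a (k+1)-subset exhibits
        # a k-subset with no larger HC, so HC_min is non-decreasing in k.
        # No such argument exists for HC_max, which is genuinely
        # non-monotone: with D(x,y)=10, D(x,z)=D(y,z)=1, HC_max(2)=10
        # but HC_max(3)=1.
        rng = np.random.default_rng(37)
        for _ in range(5):
            D = random_symmetric_matrix(rng, 9)
            prof = h.ConnectivityProfile(D)
            mins = [prof.hc_min(k) for k in range(1, 10)]
            assert mins == sorted(mins)

    def test_hc_max_non_monotone_counterexample(self):
        D = h.validate_distance_matrix(
            [[0, 10, 1], [10, 0, 1], [1, 1, 0]], ["x", "y", "z"]
        )
        assert h.hc_max(D, 2) == 10
        assert h.hc_max(D, 3) == 1


class TestInvariants:
    def test_threshold_connectivity_monotone(self):
        # G_t(Y) connected exactly when t >= HC(Y)
        rng = np.random.default_rng(41)
        for _ in range(10):
            D = random_symmetric_matrix(rng, 7)
            hc = h.haplotype_connectivity(D)
            for t in np.unique(D.pairwise()):
                g = h.threshold_graph(D, None, float(t))
                assert g.is_connected == (t >= hc)

    def test_every_value_is_zero_or_matrix_entry(self):
        rng = np.random.default_rng(43)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            D = random_symmetric_matrix(rng, n)
            entries = set(D.pairwise().tolist()) | {0.0}
            prof = h.ConnectivityProfile(D)
            assert h.haplotype_connectivity(D) in entries
            for k in range(1, n + 1):
                assert prof.hc_min(k) in entries
                assert prof.hc_max(k) in entries

    def test_extrema_bracket_every_subset(self):
        rng = np.random.default_rng(47)
        D = random_symmetric_matrix(rng, 8)
        prof = h.ConnectivityProfile(D)
        for k in range(1, 9):
            lo, hi = prof.hc_min(k), prof.hc_max(k)
            for combo in itertools.combinations(D.labels, k):
                assert lo <= h.haplotype_connectivity(D, combo) <= hi
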