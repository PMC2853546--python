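"""PD, AD, their k-subset extrema, and the diversity spectrum."""

import itertools
from math import comb

import numpy as np
import pytest

import hapconn as h
from hapconn.errors import CapacityError, InputError

from conftest import (
    exhaustive_pd_extrema,
    random_labeled_tree,
    random_symmetric_matrix,
)


class TestPD:
    def test_pair_equals_phyletic_distance(self, fig1b):
        D = h.phyletic_distances(fig1b)
        for x, y in [("b1", "b6"), ("b2", "b10"), ("b8", "b13")]:
            assert h.pd(fig1b, [x, y]) == D.value(x, y)

    def test_fully_labeled_tree_gives_total_length(self):
        phylo = h.HaplotypePhylogeny(
            [("a", "b", 2.0), ("b", "c", 3.0)],
            {"a": "a", "b": "b", "c": "c"},
        )
        assert h.pd(phylo) == 5.0

    def test_singleton_is_zero(self, fig1a):
        assert h.pd(fig1a, ["a5"]) == 0

    def test_matches_path_union_oracle_on_unit_trees(self):
        import networkx as nx

        rng = np.random.default_rng(7)
        for _ in range(10):
            tree = random_labeled_tree(rng, 12, 6, unit_edges=True)
            Y = list(
                rng.choice(tree.labels, int(rng.integers(2, 6)), replace=False)
            )
            union = set()
            for x, y in itertools.combinations(Y, 2):
                path = nx.shortest_path(
                    tree.graph, tree.vertex_of(x), tree.vertex_of(y)
                )
                union |= set(zip(path, path[1:]))
            union = {frozenset(e) for e in union}
            assert h.pd(tree, Y) == len(union)

    def test_monotone_under_inclusion(self, fig1a):
        rng = np.random.default_rng(9)
        labels = list(fig1a.labels)
        for _ in range(10):
            small = list(rng.choice(labels, 4, replace=False))
            extra = [x for x in labels if x not in small][:3]
            assert h.pd(fig1a, small) <= h.pd(fig1a, small + extra)

    def test_network_rejected(self):
        network = h.HaplotypePhylogeny(
            [("a", "b"), ("b", "c"), ("c", "a")], {"a": "a", "b": "b"}
        )
        with pytest.raises(InputError, match="tree"):
            h.pd(network)


class TestPDExtrema:
    def test_k_full_and_k2_special_cases(self, fig1b):
        D = h.phyletic_distances(fig1b)
        L = len(fig1b.labels)
        full = h.pd(fig1b)
        assert h.pd_min(fig1b, L) == full
        assert h.pd_max(fig1b, L) == full
        assert h.pd_min(fig1b, 1) == 0
        assert h.pd_max(fig1b, 2) == float(D.values.max())
        assert h.pd_min(fig1b, 2) == float(
            np.min(D.pairwise())
        )

    def test_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(8):
            tree = random_labeled_tree(rng, 14, int(rng.integers(5, 10)))
            L = len(tree.labels)
            for k in range(2, L + 1):
                lo, hi = exhaustive_pd_extrema(tree, k)
                assert h.pd_min(tree, k) == pytest.approx(lo)
                assert h.pd_max(tree, k) == pytest.approx(hi)

    def test_internal_vertex_labels_supported(self):
        # sampled haplotypes on interior vertices, as in parsimony networks
        tree = h.HaplotypePhylogeny(
            [("r", "m", 1.0), ("m", "l1", 1.0), ("m", "l2", 1.0)],
            {"x": "m", "y": "l1", "z": "l2"},
        )
        assert h.pd_min(tree, 2) == 1.0  # {x, y} or {x, z}
        assert h.pd_max(tree, 2) == 2.0  # {y, z}

    def test_extrema_bracket_every_subset(self, fig1a):
        for k in (3, 6):
            lo, hi = h.pd_min(fig1a, k), h.pd_max(fig1a, k)
            for combo in itertools.combinations(fig1a.labels, k):
                assert lo <= h.pd(fig1a, combo) <= hi


class TestAD:
    def test_pair_is_squared_distance(self):
        D = h.validate_distance_matrix([[0, 3], [3, 0]], ["x", "y"])
        assert h.ad(D) == 9.0
        assert h.ad(D, exponent=1) == 3.0

    def test_all_zero_distances(self):
        D = h.validate_distance_matrix(np.zeros((3, 3)), list("abc"))
        assert h.ad(D) == 0.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            D = random_symmetric_matrix(rng, 7)
            labels = D.labels
            total = sum(
                D.value(x, y) ** 2
                for x, y in itertools.combinations(labels, 2)
            )
            assert h.ad(D) == pytest.approx(total / comb(7, 2))

    def test_scaling_and_relabeling_invariance(self):
        rng = np.random.default_rng(21)
        D = random_symmetric_matrix(rng, 6)
        c = 3.0
        scaled = h.validate_distance_matrix(c * D.values, D.labels)
        assert h.ad(scaled) == pytest.approx(c**2 * h.ad(D))
        perm = list(reversed(range(6)))
        relabeled = h.validate_distance_matrix(
            D.values[np.ix_(perm, perm)], [D.labels[i] for i in perm]
        )
        assert h.ad(relabeled) == pytest.approx(h.ad(D))


class TestADExtrema:
    def test_k_full_set_both_modes(self):
        rng = np.random.default_rng(23)
        D = random_symmetric_matrix(rng, 8)
        full = h.ad(D)
        assert h.ad_extrema(D, 8, "min") == pytest.approx(full)
        assert h.ad_extrema(D, 8, "max") == pytest.approx(full)

    def test_k2_is_extreme_squared_distance(self):
        rng = np.random.default_rng(29)
        D = random_symmetric_matrix(rng, 7)
        tri = D.pairwise()
        assert h.ad_extrema(D, 2, "min") == pytest.approx(min(tri) ** 2)
        assert h.ad_extrema(D, 2, "max") == pytest.approx(max(tri) ** 2)

    def test_branch_and_bound_matches_exhaustive(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            D = random_symmetric_matrix(rng, 10)
            for k in range(3, 9):
                for mode in ("min", "max"):
                    bnb = h.ad_extrema(
                        D, k, mode, method="branch-and-bound"
                    )
                    exact = h.ad_extrema(D, k, mode, method="exhaustive")
                    assert bnb == pytest.approx(exact)

    def test_capacity_error_above_cap(self):
        rng = np.random.default_rng(37)
        D = random_symmetric_matrix(rng, 12)
        with pytest.raises(CapacityError, match="cap"):
            h.ad_extrema(D, 5, "max", cap=10)


class TestGDS:
    def test_three_haplotype_example(self):
        D = h.validate_distance_matrix(
            [[0, 1, 1], [1, 0, 2], [1, 2, 0]], list("xyz")
        )
        spectrum = h.gds(D)
        assert spectrum.as_dict() == {1.0: 2, 2.0: 1}

    def test_counts_conserve_pair_total(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            n = int(rng.integers(3, 10))
            D = random_symmetric_matrix(rng, n)
            assert h.gds(D).n_pairs == comb(n, 2)

    def test_matches_counting_loop(self):
        rng = np.random.default_rng(43)
        D = random_symmetric_matrix(rng, 8)
        from collections import Counter

        expected = Counter(
            D.value(x, y)
            for x, y in itertools.combinations(D.labels, 2)
        )
        assert h.gds(D).as_dict() == dict(expected)

    def test_singleton_warns_and_is_empty(self, fig1a_dist):
        with pytest.warns(UserWarning, match="single"):
            spectrum = h.gds(fig1a_dist, ["a1"])
        assert spectrum.n_pairs == 0

    def test_binning(self):
        D = h.validate_distance_matrix(
            [[0, 0.4, 1.2], [0.4, 0, 0.6], [1.2, 0.6, 0]], list("abc")
        )
        spectrum = h.gds(D, bin_width=0.5)
        assert spectrum.as_dict() == {0.0: 1, 0.5: 1, 1.0: 1}
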