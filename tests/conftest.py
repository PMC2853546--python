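import itertools

import numpy as np
import pytest

import hapconn as h


@pytest.fixture(scope="session")
def fig1a():
    return h.figure1_tree("a")


@pytest.fixture(scope="session")
def fig1b():
    return h.figure1_tree("b")


@pytest.fixture(scope="session")
def fig1a_dist(fig1a):
    return h.phyletic_distances(fig1a)


@pytest.fixture(scope="session")
def fig1b_dist(fig1b):
    return h.phyletic_distances(fig1b)


def random_symmetric_matrix(rng, n, scale=10.0, decimals=1):
    """Random symmetric non-negative matrix with zero diagonal."""
    a = np.round(rng.random((n, n)) * scale, decimals)
    d = np.triu(a, 1)
    d = d + d.T
    labels = [f"x{i}" for i in range(n)]
    return h.validate_distance_matrix(d, labels)


def random_labeled_tree(rng, n_vertices, n_labeled, unit_edges=False):
    """Random tree by sequential attachment with randomly placed labels."""
    edges = []
    for i in range(1, n_vertices):
        j = int(rng.integers(0, i))
        length = 1.0 if unit_edges else float(rng.integers(1, 5))
        edges.append((f"v{j}", f"v{i}", length))
    chosen = rng.choice(n_vertices, n_labeled, replace=False)
    labeling = {f"L{k}": f"v{int(v)}" for k, v in enumerate(sorted(chosen))}
    return h.HaplotypePhylogeny(edges, labeling)


def exhaustive_hc_extrema(D, k):
    """Min and max HC over all k-subsets by direct enumeration."""
    values = [
        h.haplotype_connectivity(D, combo)
        for combo in itertools.combinations(D.labels, k)
    ]
    return min(values), max(values)


def exhaustive_pd_extrema(tree, k):
    values = [
        h.pd(tree, combo)
        for combo in itertools.combinations(tree.labels, k)
    ]
    return min(values), max(values)
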