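"""Haplotype connectivity HC(Y) and its k-subset extrema.

The haplotype connectivity of a subset Y of haplotypes, relative to a
distance matrix D, is the smallest threshold t such that the threshold
graph G_t(Y) — vertex set Y, edges between pairs at distance <= t — is
connected.  It quantifies how hard it is to link any two haplotypes of Y
through intermediate haplotypes also in Y.  Low HC with high diversity is
the signature of a hot-spot (in-situ diversification); high HC with high
diversity suggests a melting-pot (secondary contact of divergent groups).

HC(Y) equals the bottleneck value (maximum edge weight) of a bottleneck
minimum spanning tree of the complete distance graph on Y, and every
ordinary MST is such a tree, so HC is computed here with a dense Prim
sweep in O(|Y|^2).

The extrema over all k-subsets of X:

* ``hc_min(k)`` — the bottleneck k-MST value — via a single Kruskal-style
  union-find sweep: the smallest t at which some component of G_t(X)
  reaches k vertices (prune a spanning tree of that component to k
  vertices to exhibit a witness subset);
* ``hc_max(k)`` — via binary search on the sorted distinct distances:
  every k-subset is connected at threshold t iff the vertex connectivity
  of G_t(X) exceeds |X| - k (Menger / max-flow; a complete graph has
  connectivity |X| - 1 by convention).

``ConnectivityProfile`` caches the sorted distance list and the
union-find merge sequence so extrema for many k are cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .distances import DistanceMatrix
from .errors import InputError

__all__ = [
    "ThresholdGraph",
    "SpanningTreeResult",
    "ConnectivityBounds",
    "threshold_graph",
    "haplotype_connectivity",
    "bottleneck_spanning_tree",
    "hc_min",
    "hc_max",
    "connectivity_bounds",
    "ConnectivityProfile",
]


@dataclass(frozen=True)
class ThresholdGraph:
    """G_t(Y): the graph on Y whose edges are pairs at distance <= t."""

    labels: tuple[str, ...]
    threshold: float
    #: edges as ((x, y), weight) with weight = D(x, y) <= t
    edges: tuple[tuple[tuple[str, str], float], ...]

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        for (x, y), w in self.edges:
            g.add_edge(x, y, weight=w)
        return g

    @property
    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)


@dataclass(frozen=True)
class SpanningTreeResult:
    """A spanning tree of the complete distance graph on Y.

    ``bottleneck`` is the maximum edge weight, which for a minimum
    spanning tree equals HC(Y).
    """

    labels: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]
    bottleneck: float


@dataclass(frozen=True)
class ConnectivityBounds:
    """Extremal haplotype connectivity over all k-subsets of X."""

    k: int
    hc_min: float
    hc_max: float


def threshold_graph(
    D: DistanceMatrix, Y: Iterable[str] | None, t: float
) -> ThresholdGraph:
    """Build the threshold graph G_t(Y); the comparison is inclusive."""
    if t < 0:
        raise InputError(f"threshold must be >= 0, got {t}")
    idx = D.subset_indices(Y)
    labels = tuple(D.labels[i] for i in idx)
    edges = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            w = D.values[idx[a], idx[b]]
            if w <= t:
                edges.append(((labels[a], labels[b]), float(w)))
    return ThresholdGraph(labels, float(t), tuple(edges))


def _prim_bottleneck(sub: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Dense Prim MST; returns edges (as index pairs) and the max weight."""
    n = sub.shape[0]
    if n == 1:
        return [], 0.0
    in_tree = np.zeros(n, dtype=bool)
    best = np.full(n, np.inf)
    parent = np.full(n, -1, dtype=np.intp)
    in_tree[0] = True
    best = sub[0].copy()
    parent[:] = 0
    best[0] = np.inf
    edges: list[tuple[int, int]] = []
    bottleneck = 0.0
    for _ in range(n - 1):
        j = int(np.argmin(np.where(in_tree, np.inf, best)))
        w = float(best[j])
        edges.append((int(parent[j]), j))
        bottleneck = max(bottleneck, w)
        in_tree[j] = True
        improved = sub[j] < best
        best = np.where(improved, sub[j], best)
        parent = np.where(improved, j, parent)
        best[in_tree] = np.inf
    return edges, bottleneck


def bottleneck_spanning_tree(
    D: DistanceMatrix, Y: Iterable[str] | None = None
) -> SpanningTreeResult:
    """A minimum spanning tree of the complete distance graph on Y.

    Any MST minimizes the maximum edge weight, so its bottleneck value
    equals HC(Y).  A singleton Y yields a tree with no edges and
    bottleneck 0.
    """
    idx = D.subset_indices(Y)
    labels = tuple(D.labels[i] for i in idx)
    sub = D.values[np.ix_(idx, idx)]
    edge_idx, bottleneck = _prim_bottleneck(sub)
    edges = tuple(
        (labels[a], labels[b], float(sub[a, b])) for a, b in edge_idx
    )
    return SpanningTreeResult(labels, edges, float(bottleneck))


def haplotype_connectivity(
    D: DistanceMatrix, Y: Iterable[str] | None = None
) -> float:
    """HC(Y): smallest t with G_t(Y) connected.

    Equals the bottleneck value of a minimum spanning tree of the complete
    graph on Y, and hence is 0 or equal to D(x, y) for some pair in Y.
    HC of a singleton is 0; the empty set is an error.
    """
    return bottleneck_spanning_tree(D, Y).bottleneck


class ConnectivityProfile:
    """Cached machinery for HC extrema at many subset sizes k.

    Precomputes the sorted distinct distance thresholds and, for
    ``hc_min``, the union-find merge trajectory (largest component size
    after all edges at each threshold are inserted); ``hc_max`` values
    are resolved by binary search over the thresholds with vertex
    connectivity checks, memoized per threshold.
    """

    def __init__(self, D: DistanceMatrix) -> None:
        self.D = D
        self.n = D.n
        tri = D.pairwise()
        self.thresholds: np.ndarray = np.unique(np.concatenate(([0.0], tri)))
        self._maxcomp = self._merge_trajectory()
        self._kappa_cache: dict[int, int] = {}
        self._hc_full: float | None = None

    # -- hc_min: union-find sweep ---------------------------------------

    def _merge_trajectory(self) -> np.ndarray:
        """maxcomp[i] = largest component of G_t(X) at t = thresholds[i]."""
        n = self.n
        parent = np.arange(n)
        size = np.ones(n, dtype=np.intp)

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        iu, ju = np.triu_indices(n, k=1)
        w = self.D.values[iu, ju]
        order = np.argsort(w, kind="stable")
        iu, ju, w = iu[order], ju[order], w[order]
        maxcomp = np.empty(len(self.thresholds), dtype=np.intp)
        biggest = 1
        e = 0
        for ti, t in enumerate(self.thresholds):
            while e < len(w) and w[e] <= t:
                ra, rb = find(int(iu[e])), find(int(ju[e]))
                if ra != rb:
                    if size[ra] < size[rb]:
                        ra, rb = rb, ra
                    parent[rb] = ra
                    size[ra] += size[rb]
                    biggest = max(biggest, int(size[ra]))
                e += 1
            maxcomp[ti] = biggest
        return maxcomp

    def hc_min(self, k: int) -> float:
        """Minimum HC over all k-subsets (the bottleneck k-MST value).

        A k-subset with connected threshold graph at level t exists iff
        some component of G_t(X) has >= k vertices (prune a spanning tree
        of the component down to k vertices).
        """
        self._check_k(k)
        if k == 1:
            return 0.0
        ti = int(np.searchsorted(self._maxcomp, k, side="left"))
        return float(self.thresholds[ti])

    # -- hc_max: binary search over thresholds with kappa checks ---------

    def _all_k_subsets_connected(self, ti: int, k: int) -> bool:
        """True iff every k-subset is connected in G_t(X), t=thresholds[ti].

        Equivalent to kappa(G_t(X)) > |X| - k: any vertex separator must
        be too large to isolate a k-subset (Menger; a complete graph has
        kappa = n - 1 by convention, so the full set is covered too).
        """
        if k == 1:
            return True
        if ti not in self._kappa_cache:
            t = self.thresholds[ti]
            g = nx.Graph()
            g.add_nodes_from(range(self.n))
            iu, ju = np.triu_indices(self.n, k=1)
            mask = self.D.values[iu, ju] <= t
            g.add_edges_from(zip(iu[mask].tolist(), ju[mask].tolist()))
            self._kappa_cache[ti] = int(nx.node_connectivity(g))
        return self._kappa_cache[ti] > self.n - k

    def hc_max(self, k: int) -> float:
        """Maximum HC over all k-subsets.

        The smallest threshold t such that G_t(Z) is connected for every
        k-subset Z; found by binary search over the sorted distinct
        distances (the predicate is monotone in t).
        """
        self._check_k(k)
        if k == 1:
            return 0.0
        lo, hi = 0, len(self.thresholds) - 1
        # the predicate always holds at the largest distance (complete graph)
        while lo < hi:
            mid = (lo + hi) // 2
            if self._all_k_subsets_connected(mid, k):
                hi = mid
            else:
                lo = mid + 1
        return float(self.thresholds[lo])

    def bounds(self, k: int) -> ConnectivityBounds:
        return ConnectivityBounds(k, self.hc_min(k), self.hc_max(k))

    def _check_k(self, k: int) -> None:
        if not 1 <= k <= self.n:
            raise InputError(
                f"subset size k={k} out of range 1..{self.n}"
            )


def hc_min(D: DistanceMatrix, k: int) -> float:
    """Minimum HC over all k-subsets of X.  See ConnectivityProfile.hc_min."""
    return ConnectivityProfile(D).hc_min(k)


def hc_max(D: DistanceMatrix, k: int) -> float:
    """Maximum HC over all k-subsets of X.  See ConnectivityProfile.hc_max."""
    return ConnectivityProfile(D).hc_max(k)


def connectivity_bounds(D: DistanceMatrix, k: int) -> ConnectivityBounds:
    """Both HC extrema at size k.  Use ConnectivityProfile for many k."""
    return ConnectivityProfile(D).bounds(k)
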