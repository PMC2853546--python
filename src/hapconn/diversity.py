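"""Genetic diversity of haplotype subsets and its k-subset extrema.

Two measures:

* **PD(Y)** — phylogenetic diversity: the total edge length of the
  minimal subtree of a haplotype phylogeny spanning the vertices labeled
  by Y.  Sampled haplotypes may label internal vertices, so the relevant
  subtree is the Steiner subtree of the labeled vertex set, not a
  leaf-spanning subtree.  ``pd_max`` uses the greedy chain (provably
  optimal for PD maximization); ``pd_min`` a dynamic program over the
  rooted tree (the i-tree problem).
* **AD(Y)** — average squared pairwise distance within Y (exponent
  configurable; the unsquared mean pairwise distance is ``p=1``).
  Its k-subset extrema are NP-hard (MAXISUM facility dispersion), so
  ``ad_extrema`` is exact-only: exhaustive enumeration for small sets,
  branch-and-bound up to a hard cap, and a :class:`~hapconn.errors.CapacityError`
  beyond it — no silent heuristic.

``gds`` computes the genetic diversity spectrum: the frequency
distribution of pairwise distances, whose bimodality is itself a
melting-pot signature.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb
from typing import Iterable

import networkx as nx
import numpy as np

from .distances import DistanceMatrix, HaplotypePhylogeny
from .errors import CapacityError, InputError

__all__ = [
    "DiversityResult",
    "DiversitySpectrum",
    "pd",
    "pd_min",
    "pd_max",
    "ad",
    "ad_extrema",
    "gds",
]

#: above this many haplotypes exact AD extrema are refused
DEFAULT_EXACT_CAP = 25
#: below this many haplotypes plain enumeration is used instead of B&B
EXHAUSTIVE_LIMIT = 16


@dataclass(frozen=True)
class DiversityResult:
    """Raw diversity of Y together with the extrema over |Y|-subsets."""

    measure: str  # "PD" | "AD"
    raw: float
    minimum: float
    maximum: float


@dataclass(frozen=True)
class DiversitySpectrum:
    """Counts of haplotype pairs at each pairwise distance (the GDS)."""

    distances: tuple[float, ...]
    counts: tuple[int, ...]

    @property
    def n_pairs(self) -> int:
        return sum(self.counts)

    def as_dict(self) -> dict[float, int]:
        return dict(zip(self.distances, self.counts))


# ---------------------------------------------------------------------------
# Phylogenetic diversity
# ---------------------------------------------------------------------------

def _require_tree(phylogeny: HaplotypePhylogeny) -> None:
    if not phylogeny.is_tree:
        raise InputError(
            "phylogenetic diversity requires a tree phylogeny; "
            "got a network with cycles"
        )


def pd(phylogeny: HaplotypePhylogeny, Y: Iterable[str] | None = None) -> float:
    """PD(Y): total length of the minimal subtree spanning the labels Y.

    Computed by pruning unlabeled leaves off the tree until every leaf is
    a terminal, i.e. the Steiner subtree of the vertex set {vertex(y)}.
    PD of a singleton is 0.
    """
    _require_tree(phylogeny)
    labels = tuple(phylogeny.labels) if Y is None else tuple(Y)
    if not labels:
        raise InputError("subset must be non-empty")
    terminals = {phylogeny.vertex_of(y) for y in labels}
    if len(terminals) == 1:
        return 0.0
    g = phylogeny.graph.copy()
    # iteratively strip non-terminal leaves; what remains is the Steiner tree
    leaves = [v for v in g if g.degree(v) == 1 and v not in terminals]
    while leaves:
        v = leaves.pop()
        (u,) = g.neighbors(v)
        g.remove_node(v)
        if g.degree(u) == 1 and u not in terminals:
            leaves.append(u)
    return float(sum(d["length"] for _, _, d in g.edges(data=True)))


def pd_min(phylogeny: HaplotypePhylogeny, k: int) -> float:
    """Minimum PD over all k-subsets of labeled vertices (i-tree DP).

    Root the tree arbitrarily; for each vertex v and count j, compute the
    minimal length of a subtree hanging at v that contains exactly j
    labeled vertices.  The answer is the minimum over all v of the j = k
    state.  Runs in O(n * k^2).
    """
    _require_tree(phylogeny)
    n_labeled = len(phylogeny.labels)
    if not 1 <= k <= n_labeled:
        raise InputError(f"k={k} out of range 1..{n_labeled}")
    if k == 1:
        return 0.0
    g = phylogeny.graph
    labeled_vertices = set(phylogeny.labeling.values())
    root = next(iter(g.nodes))
    order = list(nx.dfs_postorder_nodes(g, root))
    parent = dict(nx.dfs_predecessors(g, root))
    INF = float("inf")
    dp: dict[object, list[float]] = {}
    best = INF
    for v in order:
        has = 1 if v in labeled_vertices else 0
        state = [INF] * (k + 1)
        state[has] = 0.0
        for c in g.neighbors(v):
            if parent.get(c) is not v:
                continue
            w = g[v][c]["length"]
            child = dp.pop(c)
            merged = state[:]
            for j in range(k + 1):
                if state[j] == INF:
                    continue
                # attaching a child subtree with 0 labels never helps
                for jc in range(1, k + 1 - j):
                    if child[jc] == INF:
                        continue
                    cost = state[j] + child[jc] + w
                    if cost < merged[j + jc]:
                        merged[j + jc] = cost
            state = merged
        dp[v] = state
        if state[k] < best:
            best = state[k]
    if best == INF:  # pragma: no cover - guarded by the k range check
        raise InputError(f"no subtree with {k} labeled vertices")
    return float(best)


def pd_max(phylogeny: HaplotypePhylogeny, k: int) -> float:
    """Maximum PD over all k-subsets of labeled vertices (greedy chain).

    Start from the labeled pair at maximum phyletic distance, then
    repeatedly add the labeled vertex farthest from the current subtree.
    The greedy chain is optimal for PD maximization at every k.
    """
    _require_tree(phylogeny)
    labels = list(phylogeny.labels)
    if not 1 <= k <= len(labels):
        raise InputError(f"k={k} out of range 1..{len(labels)}")
    if k == 1:
        return 0.0
    g = phylogeny.graph
    vertex = {y: phylogeny.vertex_of(y) for y in labels}
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    # farthest labeled pair (deterministic tie-break by label order)
    best_pair, best_d = None, -1.0
    for x, y in itertools.combinations(labels, 2):
        d = dist[vertex[x]][vertex[y]]
        if d > best_d:
            best_pair, best_d = (x, y), d
    assert best_pair is not None
    x0, y0 = best_pair
    in_subtree = set(nx.shortest_path(g, vertex[x0], vertex[y0]))
    total = best_d
    chosen = {x0, y0}
    for _ in range(k - 2):
        best_y, best_inc, best_attach = None, -1.0, None
        for y in labels:
            if y in chosen:
                continue
            v = vertex[y]
            # distance from v to the (connected) current subtree
            attach = min(in_subtree, key=lambda s: dist[v][s])
            inc = dist[v][attach]
            if inc > best_inc:
                best_y, best_inc, best_attach = y, inc, attach
        assert best_y is not None
        total += best_inc
        chosen.add(best_y)
        in_subtree.update(
            nx.shortest_path(g, vertex[best_y], best_attach)
        )
    return float(total)


# ---------------------------------------------------------------------------
# Average (squared) pairwise distance
# ---------------------------------------------------------------------------

def ad(
    D: DistanceMatrix,
    Y: Iterable[str] | None = None,
    *,
    exponent: int = 2,
) -> float:
    """AD(Y): average of D(x, y)**exponent over all pairs in Y.

    Default exponent 2 (average *squared* pairwise distance); exponent 1
    gives the plain mean pairwise distance.  AD of a singleton is 0.
    """
    tri = D.pairwise(Y)
    if len(tri) == 0:
        return 0.0
    return float(np.mean(tri ** exponent))


def _pair_sum_extrema_exhaustive(
    W: np.ndarray, k: int, mode: str
) -> float:
    n = W.shape[0]
    best = None
    for combo in itertools.combinations(range(n), k):
        idx = np.asarray(combo)
        s = W[np.ix_(idx, idx)].sum() / 2.0
        if best is None or (s < best if mode == "min" else s > best):
            best = s
    assert best is not None
    return float(best)


def _pair_sum_max_bnb(W: np.ndarray, k: int) -> float:
    """Exact maximum pairwise-weight sum over k-subsets (MAXISUM dispersion).

    Depth-first branch-and-bound over vertices in fixed order.  Upper
    bound at a node: current sum plus, for the r vertices still to pick,
    the r largest optimistic gains g(j) = (weight of j to the chosen set)
    + half the sum of j's r-1 largest weights to other candidates (each
    candidate-candidate pair is counted once from each endpoint).
    """
    n = W.shape[0]
    to_chosen = np.zeros(n)
    best = -np.inf

    def greedy_value(chosen: list[int], cand: list[int], cur: float) -> float:
        # feasible completion to seed the incumbent
        c = list(chosen)
        s = cur
        pool = list(cand)
        while len(c) < k:
            gains = [W[j, c].sum() if c else 0.0 for j in pool]
            i = int(np.argmax(gains))
            s += gains[i]
            c.append(pool.pop(i))
        return s

    def rec(start: int, chosen: list[int], cur: float) -> None:
        nonlocal best
        r = k - len(chosen)
        if r == 0:
            if cur > best:
                best = cur
            return
        cand = list(range(start, n))
        if len(cand) < r:
            return
        # optimistic gain per candidate
        gains = np.empty(len(cand))
        for ii, j in enumerate(cand):
            others = np.asarray([c for c in cand if c != j], dtype=np.intp)
            wjo = np.sort(W[j, others])[::-1][: r - 1] if r > 1 else []
            gains[ii] = to_chosen[j] + 0.5 * float(np.sum(wjo))
        ub = cur + float(np.sum(np.sort(gains)[::-1][:r]))
        if ub <= best + 1e-12:
            return
        for ii, j in enumerate(cand):
            # prune: not enough candidates left after j
            if n - j < r:
                break
            gain = float(to_chosen[j])
            chosen.append(j)
            to_chosen[j + 1 :] += W[j, j + 1 :]
            rec(j + 1, chosen, cur + gain)
            to_chosen[j + 1 :] -= W[j, j + 1 :]
            chosen.pop()
        return

    best = greedy_value([], list(range(n)), 0.0)
    rec(0, [], 0.0)
    return float(best)


def ad_extrema(
    D: DistanceMatrix,
    k: int,
    mode: str,
    *,
    exponent: int = 2,
    cap: int = DEFAULT_EXACT_CAP,
    method: str = "auto",
) -> float:
    """Exact min/max AD over all k-subsets of X.

    NP-hard in general; this routine is exact-only.  ``method`` is
    "exhaustive", "branch-and-bound", or "auto" (enumeration below
    ``EXHAUSTIVE_LIMIT`` haplotypes, branch-and-bound up to ``cap``).
    Above ``cap`` a :class:`CapacityError` is raised rather than silently
    approximating.
    """
    if mode not in ("min", "max"):
        raise InputError(f"mode must be 'min' or 'max', got {mode!r}")
    n = D.n
    if not 2 <= k <= n:
        raise InputError(f"k={k} out of range 2..{n}")
    if n > cap:
        raise CapacityError(
            f"exact AD extrema refused for {n} haplotypes (cap {cap}); "
            "restrict the haplotype set or raise the cap"
        )
    W = D.values ** exponent
    n_pairs = comb(k, 2)
    if method == "auto":
        method = "exhaustive" if n < EXHAUSTIVE_LIMIT else "branch-and-bound"
    if method == "exhaustive":
        return _pair_sum_extrema_exhaustive(W, k, mode) / n_pairs
    if method != "branch-and-bound":
        raise InputError(f"unknown method {method!r}")
    if mode == "max":
        return _pair_sum_max_bnb(W, k) / n_pairs
    # minimize by maximizing the complementary weights w' = wmax - w
    wmax = float(W.max())
    Wc = wmax - W
    np.fill_diagonal(Wc, 0.0)
    return (n_pairs * wmax - _pair_sum_max_bnb(Wc, k)) / n_pairs


# ---------------------------------------------------------------------------
# Genetic diversity spectrum
# ---------------------------------------------------------------------------

def gds(
    D: DistanceMatrix,
    Y: Iterable[str] | None = None,
    *,
    bin_width: float | None = None,
) -> DiversitySpectrum:
    """Frequency distribution of pairwise distances within Y.

    Exact counts per distinct distance value; set ``bin_width`` to pool
    non-integer distances into bins ``[i*w, (i+1)*w)`` keyed by their
    left edge.  Counts always sum to C(|Y|, 2).
    """
    tri = D.pairwise(Y)
    if len(tri) == 0:
        warnings.warn(
            "GDS of a single haplotype is empty", stacklevel=2
        )
        return DiversitySpectrum((), ())
    if bin_width is not None:
        if bin_width <= 0:
            raise InputError("bin_width must be positive")
        tri = np.floor(tri / bin_width) * bin_width
    values, counts = np.unique(tri, return_counts=True)
    return DiversitySpectrum(
        tuple(float(v) for v in values), tuple(int(c) for c in counts)
    )
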