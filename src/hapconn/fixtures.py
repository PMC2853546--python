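"""Packaged toy phylogenies and synthetic scenario generators.

``figure1_tree`` returns the two 13-haplotype unit-edge toy phylogenies
used throughout the documentation and tests: variant "a" is a hot-spot
scenario (sampled haplotypes dispersed along the tree, haplotype
connectivity 2) and variant "b" a melting-pot scenario (two groups of
sampled haplotypes separated by a path of hypothetical intermediates,
haplotype connectivity 5).  Both trees have total length 16, so their
phylogenetic diversity is identical — connectivity, not diversity, tells
them apart.

``simulate_scenario`` generates random datasets with the same two kinds
of structure for simulation studies:

* *hot_spot* — a random unit-edge tree grown by sequential vertex
  attachment, with the sampled (labeled) vertices spread uniformly over
  the tree;
* *melting_pot* — several such trees joined by unlabeled bridge paths
  (mimicking extinct or unsampled intermediates between long-isolated
  gene pools), with the sampled vertices confined to the clusters.

The focal region holds a fixed fraction of the haplotypes — drawn evenly
from all clusters in the melting-pot case, as in a zone of secondary
contact — and the remaining haplotypes form a background region, so
normalized scores are non-degenerate.  Output is fully determined by the
spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .distances import DistanceMatrix, HaplotypePhylogeny, phyletic_distances
from .errors import InputError
from .scoring import RegionTable

__all__ = ["ScenarioSpec", "figure1_tree", "simulate_scenario"]


def _load_fixture(stem: str) -> HaplotypePhylogeny:
    data = resources.files("hapconn.data")
    edges = []
    with (data / f"{stem}_edges.tsv").open() as fh:
        next(fh)
        for line in fh:
            u, v, length = line.split()
            edges.append((u, v, float(length)))
    labeling = {}
    with (data / f"{stem}_labels.tsv").open() as fh:
        next(fh)
        for line in fh:
            vertex, label = line.split()
            labeling[label] = vertex
    return HaplotypePhylogeny(edges, labeling)


def figure1_tree(variant: str) -> HaplotypePhylogeny:
    """The packaged 13-haplotype toy phylogeny, variant "a" or "b".

    Variant "a": hot-spot structure, labels a1..a13, HC = 2.
    Variant "b": melting-pot structure, labels b1..b13, HC = 5.
    All edges have length 1; both trees have total length 16.
    """
    if variant not in ("a", "b"):
        raise InputError(f"unknown figure-1 variant {variant!r}")
    return _load_fixture(f"figure1{variant}")


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a synthetic hot-spot or melting-pot dataset.

    ``n_vertices`` counts *all* tree vertices including unlabeled
    intermediates; with unit edges the total tree length is
    ``n_vertices - 1``, so scenarios with equal ``n_vertices`` are
    matched in total tree length.  ``separation`` is the length of each
    unlabeled bridge path between clusters (melting-pot only) and must
    exceed the within-cluster spread for the scenario to be meaningful.
    """

    scenario: str  # "hot_spot" | "melting_pot"
    n_haplotypes: int = 20
    n_vertices: int = 40
    n_clusters: int = 2
    separation: int = 10
    focal_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("hot_spot", "melting_pot"):
            raise InputError(f"unknown scenario {self.scenario!r}")
        if self.n_haplotypes < 2:
            raise InputError("need at least 2 haplotypes")
        if self.n_haplotypes > self.n_vertices:
            raise InputError(
                f"{self.n_haplotypes} haplotypes exceed "
                f"{self.n_vertices} vertices"
            )
        if not 0 < self.focal_fraction <= 1:
            raise InputError("focal_fraction must be in (0, 1]")
        if self.scenario == "melting_pot":
            if self.n_clusters < 2:
                raise InputError("melting-pot needs >= 2 clusters")
            if self.separation < 2:
                raise InputError("separation must be >= 2")
            interior = (self.n_clusters - 1) * (self.separation - 1)
            cluster_total = self.n_vertices - interior
            if cluster_total < self.n_clusters:
                raise InputError(
                    "bridge intermediates leave no room for clusters"
                )
            per = -(-self.n_haplotypes // self.n_clusters)
            if per > cluster_total // self.n_clusters:
                raise InputError("labels exceed cluster vertices")


def _grow_tree(rng: np.random.Generator, names: list[str]) -> list[tuple]:
    """Random tree by sequential uniform attachment; unit edges."""
    edges = []
    for i in range(1, len(names)):
        j = int(rng.integers(0, i))
        edges.append((names[j], names[i], 1.0))
    return edges


def simulate_scenario(
    spec: ScenarioSpec,
) -> tuple[HaplotypePhylogeny, DistanceMatrix, RegionTable]:
    """Generate a (phylogeny, distance matrix, region table) triple.

    The distance matrix is the phyletic (path-length) distance on the
    generated tree.  Haplotype labels are h01, h02, ...; the region
    table has a "focal" region and, when any haplotypes remain, a
    "background" region.
    """
    rng = np.random.default_rng(spec.seed)
    labels = [f"h{i + 1:02d}" for i in range(spec.n_haplotypes)]

    if spec.scenario == "hot_spot":
        names = [f"v{i}" for i in range(spec.n_vertices)]
        edges = _grow_tree(rng, names)
        chosen = rng.choice(spec.n_vertices, spec.n_haplotypes, replace=False)
        labeling = {lab: names[int(v)] for lab, v in zip(labels, chosen)}
    else:
        interior = (spec.n_clusters - 1) * (spec.separation - 1)
        cluster_total = spec.n_vertices - interior
        base, extra = divmod(cluster_total, spec.n_clusters)
        sizes = [base + (c < extra) for c in range(spec.n_clusters)]
        lbase, lextra = divmod(spec.n_haplotypes, spec.n_clusters)
        lab_counts = [lbase + (c < lextra) for c in range(spec.n_clusters)]
        edges = []
        labeling = {}
        lab_iter = iter(labels)
        cluster_labels: list[list[str]] = []
        roots = []
        for c, (size, n_lab) in enumerate(zip(sizes, lab_counts)):
            names = [f"c{c}v{i}" for i in range(size)]
            roots.append(names[0])
            edges += _grow_tree(rng, names)
            chosen = rng.choice(size, n_lab, replace=False)
            mine = []
            for v in chosen:
                lab = next(lab_iter)
                labeling[lab] = names[int(v)]
                mine.append(lab)
            cluster_labels.append(mine)
        # unlabeled bridge paths between consecutive cluster roots
        for c in range(spec.n_clusters - 1):
            prev = roots[c]
            for s in range(spec.separation - 1):
                mid = f"bridge{c}s{s}"
                edges.append((prev, mid, 1.0))
                prev = mid
            edges.append((prev, roots[c + 1], 1.0))

    phylogeny = HaplotypePhylogeny(edges, labeling)
    D = phyletic_distances(phylogeny)

    n_focal = max(2, round(spec.focal_fraction * spec.n_haplotypes))
    if spec.scenario == "melting_pot":
        # secondary contact: draw focal haplotypes evenly from every cluster
        fbase, fextra = divmod(n_focal, spec.n_clusters)
        focal = []
        for c, mine in enumerate(cluster_labels):
            take = fbase + (c < fextra)
            picked = rng.choice(len(mine), take, replace=False)
            focal += [mine[int(i)] for i in picked]
    else:
        picked = rng.choice(spec.n_haplotypes, n_focal, replace=False)
        focal = [labels[int(i)] for i in picked]
    focal = sorted(focal)
    rest = sorted(set(labels) - set(focal))
    regions = {"focal": tuple(focal)}
    if rest:
        regions["background"] = tuple(rest)
    return phylogeny, D, RegionTable(regions)
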