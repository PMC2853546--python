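"""Genetic distance matrices on a haplotype set.

A haplotype is a distinct sampled sequence / allele-profile variant.  All
downstream machinery (threshold graphs, connectivity, diversity) consumes a
single interchange object, :class:`DistanceMatrix`: a symmetric, non-negative,
zero-diagonal matrix of pairwise genetic distances ``D`` on an ordered label
set ``X``.  Three front-end constructors are provided:

* :func:`hamming_distances` — per-site mismatch counts on aligned sequences;
* :func:`allele_size_distances` — summed absolute allele-size differences
  across microsatellite loci (the "pairwise haplotypic difference");
* :func:`phyletic_distances` — path-length distances on a haplotype
  phylogeny or network with labeled (sampled) and unlabeled (hypothetical
  intermediate) vertices.

No algorithm in this package assumes the triangle inequality; only symmetry
and non-negativity are required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import InputError, ValidationError

__all__ = [
    "HaplotypeSet",
    "DistanceMatrix",
    "HaplotypePhylogeny",
    "AlleleProfile",
    "hamming_distances",
    "allele_size_distances",
    "phyletic_distances",
    "validate_distance_matrix",
]

#: characters treated as gap/ambiguity sites in aligned sequences
DEFAULT_MISSING_CHARS = "-.?Nn"


@dataclass(frozen=True)
class HaplotypeSet:
    """An ordered set of unique haplotype identifiers (the set X).

    The order is stable and defines the row/column order of any
    :class:`DistanceMatrix` built on it.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if not labels:
            raise InputError("haplotype set must be non-empty")
        if any(not isinstance(x, str) or not x for x in labels):
            raise InputError("haplotype labels must be non-empty strings")
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise InputError(f"duplicate haplotype labels: {dupes}")
        object.__setattr__(
            self, "_index", {x: i for i, x in enumerate(labels)}
        )

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self._index  # type: ignore[attr-defined]

    def index(self, label: str) -> int:
        try:
            return self._index[label]  # type: ignore[attr-defined]
        except KeyError:
            raise InputError(f"unknown haplotype label: {label!r}") from None

    def indices(self, labels: Iterable[str]) -> np.ndarray:
        return np.asarray([self.index(x) for x in labels], dtype=np.intp)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise genetic distances D on a haplotype label set."""

    haplotypes: HaplotypeSet
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(self.haplotypes)
        if values.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {values.shape} does not match "
                f"{n} haplotype labels"
            )
        _check_matrix(values, self.haplotypes.labels, atol=0.0)
        values.setflags(write=False)

    # -- convenience accessors -------------------------------------------

    @property
    def labels(self) -> tuple[str, ...]:
        return self.haplotypes.labels

    @property
    def n(self) -> int:
        return len(self.haplotypes)

    def value(self, x: str, y: str) -> float:
        return float(
            self.values[self.haplotypes.index(x), self.haplotypes.index(y)]
        )

    def subset_indices(self, subset: Iterable[str] | None) -> np.ndarray:
        """Indices of ``subset`` (all labels if None), validating membership."""
        if subset is None:
            return np.arange(self.n, dtype=np.intp)
        labels = list(subset)
        if not labels:
            raise InputError("subset must be non-empty")
        if len(set(labels)) != len(labels):
            raise InputError("subset contains duplicate labels")
        return self.haplotypes.indices(labels)

    def submatrix(self, subset: Iterable[str]) -> "DistanceMatrix":
        labels = tuple(subset)
        idx = self.subset_indices(labels)
        return DistanceMatrix(
            HaplotypeSet(labels), self.values[np.ix_(idx, idx)].copy()
        )

    def pairwise(self, subset: Iterable[str] | None = None) -> np.ndarray:
        """Condensed upper-triangle vector of distances within ``subset``."""
        idx = self.subset_indices(subset)
        sub = self.values[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        return sub[iu]


def _check_matrix(
    values: np.ndarray, labels: Sequence[str], atol: float
) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError(f"matrix is not square: shape {values.shape}")
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            f"non-finite distance between {labels[i]!r} and {labels[j]!r}"
        )
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative distance D({labels[i]!r}, {labels[j]!r}) = "
            f"{values[i, j]}"
        )
    diag = np.diag(values)
    if np.any(diag != 0):
        i = int(np.argmax(diag != 0))
        raise ValidationError(
            f"nonzero diagonal entry for {labels[i]!r}: {diag[i]}"
        )
    asym = np.abs(values - values.T)
    if np.any(asym > atol):
        i, j = np.argwhere(asym > atol)[0]
        raise ValidationError(
            f"asymmetric distances: D({labels[i]!r}, {labels[j]!r}) = "
            f"{values[i, j]} but D({labels[j]!r}, {labels[i]!r}) = "
            f"{values[j, i]}"
        )


def validate_distance_matrix(
    values,
    labels: Sequence[str],
    *,
    atol: float = 0.0,
    symmetrize: bool = False,
) -> DistanceMatrix:
    """Validate a square array as a :class:`DistanceMatrix`.

    Parameters
    ----------
    values
        Square numeric array of pairwise distances.
    labels
        Haplotype identifiers, one per row, in row order.
    atol
        Tolerance for asymmetry (default 0: exact symmetry required).
        Useful for matrices that round-tripped through limited-precision
        text formats.
    symmetrize
        If True, replace the matrix by ``(D + D.T) / 2`` after the
        asymmetry check against ``atol`` passes.

    Raises
    ------
    ValidationError
        On asymmetry beyond ``atol``, negative entries, a nonzero diagonal
        or non-finite values; the message names the offending pair.
    """
    arr = np.array(values, dtype=float)
    haps = HaplotypeSet(tuple(labels))
    if arr.shape != (len(haps), len(haps)):
        raise ValidationError(
            f"matrix shape {arr.shape} does not match {len(haps)} labels"
        )
    _check_matrix(arr, haps.labels, atol=atol)
    if symmetrize:
        arr = (arr + arr.T) / 2.0
    np.fill_diagonal(arr, 0.0)
    return DistanceMatrix(haps, arr)


# ---------------------------------------------------------------------------
# Hamming distance on aligned sequences
# ---------------------------------------------------------------------------

def hamming_distances(
    alignment: Mapping[str, str] | Sequence[tuple[str, str]],
    *,
    missing_as_mismatch: bool = False,
    missing_chars: str = DEFAULT_MISSING_CHARS,
) -> DistanceMatrix:
    """Pairwise Hamming distances on a labeled multiple alignment.

    ``D(x, y)`` is the number of alignment columns at which the two
    sequences differ.  Gap and ambiguity characters (``missing_chars``)
    are by default excluded pairwise — a column with a missing state in
    either sequence of a pair does not contribute to that pair's distance.
    Set ``missing_as_mismatch=True`` to count them as ordinary states.
    """
    items = (
        list(alignment.items())
        if isinstance(alignment, Mapping)
        else [(str(a), str(b)) for a, b in alignment]
    )
    if not items:
        raise InputError("alignment is empty")
    labels = tuple(label for label, _ in items)
    haps = HaplotypeSet(labels)  # rejects duplicates
    length = len(items[0][1])
    if length < 1:
        raise InputError("sequences must have length >= 1")
    for label, seq in items:
        if len(seq) != length:
            raise InputError(
                f"sequence length mismatch: {label!r} has length "
                f"{len(seq)}, expected {length}"
            )
    seqs = np.array([list(seq) for _, seq in items])
    n = len(items)
    D = np.zeros((n, n), dtype=float)
    if missing_as_mismatch:
        present = np.ones_like(seqs, dtype=bool)
    else:
        present = ~np.isin(seqs, list(missing_chars))
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            D[i, j] = D[j, i] = np.count_nonzero(
                (seqs[i] != seqs[j]) & both
            )
    return DistanceMatrix(haps, D)


# ---------------------------------------------------------------------------
# Microsatellite allele-size distance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleProfile:
    """Allele sizes of one haplotype, one integer per microsatellite locus."""

    label: str
    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sizes", tuple(int(s) for s in self.sizes))
        if not self.sizes:
            raise InputError(f"profile {self.label!r} has no loci")


def allele_size_distances(
    profiles: Sequence[AlleleProfile | tuple[str, Sequence[int]]],
) -> DistanceMatrix:
    """Pairwise haplotypic difference on allele-size profiles.

    ``D(x, y)`` is the sum over loci of the absolute difference in allele
    size — the standard distance for chloroplast SSR haplotypes.
    """
    profs = [
        p if isinstance(p, AlleleProfile) else AlleleProfile(p[0], tuple(p[1]))
        for p in profiles
    ]
    if len(profs) < 2:
        raise InputError("need at least 2 allele profiles")
    n_loci = len(profs[0].sizes)
    for p in profs:
        if len(p.sizes) != n_loci:
            raise InputError(
                f"profile {p.label!r} has {len(p.sizes)} loci, "
                f"expected {n_loci}"
            )
    haps = HaplotypeSet(tuple(p.label for p in profs))
    sizes = np.asarray([p.sizes for p in profs], dtype=float)
    D = np.abs(sizes[:, None, :] - sizes[None, :, :]).sum(axis=2)
    return DistanceMatrix(haps, D)


# ---------------------------------------------------------------------------
# Phyletic distance on a haplotype phylogeny / network
# ---------------------------------------------------------------------------

class HaplotypePhylogeny:
    """A haplotype phylogeny or network with partially labeled vertices.

    Vertices are either *sampled* (they carry a haplotype label) or
    *hypothetical intermediates* (unlabeled) — the white dots of a
    parsimony haplotype network.  Edges carry positive lengths in
    mutational steps; the unit-edge case corresponds to single-mutation
    networks.

    Parameters
    ----------
    edges
        Iterable of ``(u, v)`` or ``(u, v, length)`` tuples; missing
        lengths default to 1.0.
    labeling
        Map from haplotype label to vertex identifier.  Must be injective
        into the vertex set; a vertex carries at most one label.
    """

    def __init__(
        self,
        edges: Iterable[tuple],
        labeling: Mapping[str, object],
    ) -> None:
        g = nx.Graph()
        for edge in edges:
            if len(edge) == 2:
                u, v = edge
                length = 1.0
            else:
                u, v, length = edge
            length = float(length)
            if length <= 0 or not math.isfinite(length):
                raise ValidationError(
                    f"edge ({u!r}, {v!r}) has non-positive length {length}"
                )
            if u == v:
                raise ValidationError(f"self-loop at vertex {u!r}")
            g.add_edge(u, v, length=length)
        if g.number_of_nodes() == 0:
            raise InputError("phylogeny has no edges")
        if not nx.is_connected(g):
            raise ValidationError("phylogeny graph is not connected")
        labeling = dict(labeling)
        if not labeling:
            raise InputError("phylogeny has no labeled vertices")
        seen_vertices: dict[object, str] = {}
        for label, vertex in labeling.items():
            if vertex not in g:
                raise InputError(
                    f"label {label!r} maps to unknown vertex {vertex!r}"
                )
            if vertex in seen_vertices:
                raise ValidationError(
                    f"vertex {vertex!r} carries two labels: "
                    f"{seen_vertices[vertex]!r} and {label!r}"
                )
            seen_vertices[vertex] = label
        self.graph = g
        self.labeling = labeling

    # -- structure -------------------------------------------------------

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.labeling)

    @property
    def is_tree(self) -> bool:
        return self.graph.number_of_edges() == self.graph.number_of_nodes() - 1

    @property
    def total_length(self) -> float:
        return float(
            sum(d["length"] for _, _, d in self.graph.edges(data=True))
        )

    def vertex_of(self, label: str) -> object:
        try:
            return self.labeling[label]
        except KeyError:
            raise InputError(f"unknown haplotype label: {label!r}") from None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"HaplotypePhylogeny({self.graph.number_of_nodes()} vertices, "
            f"{self.graph.number_of_edges()} edges, "
            f"{len(self.labeling)} labeled)"
        )


def phyletic_distances(phylogeny: HaplotypePhylogeny) -> DistanceMatrix:
    """Path-length distances between sampled haplotypes on a phylogeny.

    ``D(x, y)`` is the length of the shortest path (sum of edge lengths)
    between the vertices labeled ``x`` and ``y``.  On a tree this is the
    unique path; on a haplotype network it is the shortest one.  The
    matrix is restricted to labeled vertices.
    """
    labels = phylogeny.labels
    haps = HaplotypeSet(labels)
    n = len(labels)
    D = np.zeros((n, n), dtype=float)
    for i, x in enumerate(labels):
        lengths = nx.single_source_dijkstra_path_length(
            phylogeny.graph, phylogeny.vertex_of(x), weight="length"
        )
        for j, y in enumerate(labels):
            D[i, j] = lengths[phylogeny.vertex_of(y)]
    D = (D + D.T) / 2.0  # guard against float drift in Dijkstra order
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(haps, D)
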