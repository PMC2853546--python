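"""Readers and writers for the supported file formats.

Formats: FASTA alignments (Biopython), Newick trees (dendropy), PHYLIP
distance matrices (square and lower-triangular dialects, auto-detected,
relaxed name parsing on read / strict 10-character names on write),
plain TSV matrices, and TSV tables for edge lists, vertex label maps,
region assignments, allele profiles, score tables and GDS histograms.
Labels follow the first-token convention throughout.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .distances import (
    AlleleProfile,
    DistanceMatrix,
    HaplotypePhylogeny,
    validate_distance_matrix,
)
from .diversity import DiversitySpectrum
from .errors import FormatError, InputError
from .scoring import RegionTable, ScoreRow

logger = logging.getLogger(__name__)

__all__ = [
    "read_distance_file",
    "write_distance_tsv",
    "write_distance_phylip",
    "read_fasta_alignment",
    "read_allele_profiles",
    "read_newick",
    "read_edge_list",
    "read_regions",
    "write_regions",
    "scores_to_frame",
    "write_scores_tsv",
    "write_scores_json",
    "write_gds_tsv",
    "write_spanning_tree_tsv",
]


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

def read_distance_file(
    path: str | Path,
    dialect: str = "auto",
    *,
    atol: float = 0.0,
    symmetrize: bool = False,
) -> DistanceMatrix:
    """Read a distance matrix in PHYLIP (square or lower-triangular) or TSV.

    Auto-detection: a first line consisting of a single integer selects
    PHYLIP, with the dialect decided by the value count; otherwise the
    file is parsed as a TSV matrix with a header row and a label column.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    if dialect == "auto":
        first = lines[0].split()
        dialect = "phylip" if len(first) == 1 and first[0].isdigit() else "tsv"
    if dialect in ("phylip", "phylip-square", "phylip-lower"):
        return _read_phylip(lines, dialect, path, atol=atol, symmetrize=symmetrize)
    if dialect == "tsv":
        return _read_tsv_matrix(path, atol=atol, symmetrize=symmetrize)
    raise InputError(f"unknown distance dialect {dialect!r}")


def _read_phylip(
    lines: list[str],
    dialect: str,
    path: Path,
    *,
    atol: float,
    symmetrize: bool,
) -> DistanceMatrix:
    try:
        n = int(lines[0].split()[0])
    except ValueError:
        raise FormatError(f"{path}:1: expected taxon count") from None
    if len(lines) - 1 != n:
        raise FormatError(
            f"{path}: expected {n} matrix rows, found {len(lines) - 1}"
        )
    labels, rows = [], []
    for i, line in enumerate(lines[1:], start=2):
        tokens = line.split()
        labels.append(tokens[0])
        try:
            rows.append([float(t) for t in tokens[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{i}: non-numeric entry ({exc})") from None
    counts = [len(r) for r in rows]
    if dialect == "phylip":  # auto-detect sub-dialect from value counts
        if counts == [n] * n:
            dialect = "phylip-square"
        elif counts == list(range(n)):
            dialect = "phylip-lower"
        else:
            raise FormatError(
                f"{path}: row value counts {counts} match neither the "
                "square nor the lower-triangular PHYLIP dialect"
            )
    arr = np.zeros((n, n))
    if dialect == "phylip-square":
        if counts != [n] * n:
            bad = next(i for i, c in enumerate(counts) if c != n)
            raise FormatError(
                f"{path}:{bad + 2}: expected {n} values, found {counts[bad]}"
            )
        arr = np.asarray(rows)
    else:
        if counts != list(range(n)):
            bad = next(i for i, c in enumerate(counts) if c != i)
            raise FormatError(
                f"{path}:{bad + 2}: expected {bad} values, found {counts[bad]}"
            )
        for i, row in enumerate(rows):
            arr[i, : len(row)] = row
        arr = arr + arr.T
    return validate_distance_matrix(
        arr, labels, atol=atol, symmetrize=symmetrize
    )


def _read_tsv_matrix(
    path: Path, *, atol: float, symmetrize: bool
) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(x) for x in df.index]
    if [str(c) for c in df.columns] != labels:
        raise FormatError(
            f"{path}: row and column labels differ or are misordered"
        )
    return validate_distance_matrix(
        df.to_numpy(dtype=float), labels, atol=atol, symmetrize=symmetrize
    )


def write_distance_tsv(D: DistanceMatrix, path: str | Path) -> None:
    """TSV matrix with labels as both header and first column.

    Uses ``repr`` float formatting, so write-then-read round-trips
    bit-identically.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(("", *D.labels)) + "\n")
        for i, label in enumerate(D.labels):
            row = "\t".join(repr(float(v)) for v in D.values[i])
            fh.write(f"{label}\t{row}\n")


def write_distance_phylip(D: DistanceMatrix, path: str | Path) -> None:
    """Strict square PHYLIP: 10-character padded names, count header."""
    for label in D.labels:
        if len(label) > 10:
            raise InputError(
                f"label {label!r} exceeds the 10-character PHYLIP limit"
            )
    with open(path, "w") as fh:
        fh.write(f"{D.n}\n")
        for i, label in enumerate(D.labels):
            row = " ".join(f"{v:.6f}" for v in D.values[i])
            fh.write(f"{label:<10s} {row}\n")


# ---------------------------------------------------------------------------
# Sequences, profiles, trees
# ---------------------------------------------------------------------------

def read_fasta_alignment(path: str | Path) -> list[tuple[str, str]]:
    """Aligned haplotype sequences; labels are record IDs (first token)."""
    records = [
        (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def read_allele_profiles(path: str | Path) -> list[AlleleProfile]:
    """TSV of allele sizes: first column haplotype ID, rest integer sizes.

    A header row is optional and detected by non-numeric size columns.
    """
    profiles = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                sizes = tuple(int(t) for t in tokens[1:])
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise FormatError(
                    f"{path}:{lineno}: non-integer allele size"
                ) from None
            profiles.append(AlleleProfile(tokens[0], sizes))
    if not profiles:
        raise FormatError(f"{path}: no allele profiles found")
    return profiles


def read_newick(path: str | Path) -> HaplotypePhylogeny:
    """Newick tree as a haplotype phylogeny.

    Leaf taxon labels and interior node labels are treated as sampled
    haplotypes; unlabeled interior nodes are hypothetical intermediates.
    Missing edge lengths default to 1.0 with a logged warning (the
    unit-edge convention of single-mutation haplotype networks).
    """
    import dendropy

    tree = dendropy.Tree.get(path=str(path), schema="newick")
    edges = []
    labeling: dict[str, object] = {}
    missing_lengths = 0
    ids = {}

    def vid(node) -> int:
        if id(node) not in ids:
            ids[id(node)] = len(ids)
        return ids[id(node)]

    for node in tree.preorder_node_iter():
        name = None
        if node.taxon is not None:
            name = node.taxon.label
        elif node.label:
            name = node.label
        if name:
            name = str(name).split()[0]
            if name in labeling:
                raise InputError(f"duplicate haplotype label {name!r}")
            labeling[name] = vid(node)
        if node.parent_node is not None:
            length = node.edge.length
            if length is None:
                missing_lengths += 1
                length = 1.0
            edges.append((vid(node.parent_node), vid(node), float(length)))
    if missing_lengths:
        logger.warning(
            "%d edges had no length; defaulting to 1.0", missing_lengths
        )
        warnings.warn(
            f"{missing_lengths} Newick edges had no length; using 1.0",
            stacklevel=2,
        )
    return HaplotypePhylogeny(edges, labeling)


def read_edge_list(
    path: str | Path, label_map: str | Path | None = None
) -> HaplotypePhylogeny:
    """Haplotype network from an edge-list TSV (vertex1, vertex2, length).

    The length column is optional (default 1).  Without a separate
    vertex-to-haplotype ``label_map`` TSV, every vertex is treated as a
    sampled haplotype labeled by its own name.
    """
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) not in (2, 3):
                raise FormatError(
                    f"{path}:{lineno}: expected 2 or 3 columns"
                )
            try:
                length = float(tokens[2]) if len(tokens) == 3 else 1.0
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise FormatError(
                    f"{path}:{lineno}: non-numeric edge length"
                ) from None
            if lineno == 1 and tokens[:2] == ["vertex1", "vertex2"]:
                continue
            edges.append((tokens[0], tokens[1], length))
    if not edges:
        raise FormatError(f"{path}: no edges found")
    if label_map is not None:
        labeling = {}
        with open(label_map) as fh:
            for lineno, line in enumerate(fh, start=1):
                tokens = line.split()
                if not tokens:
                    continue
                if len(tokens) != 2:
                    raise FormatError(
                        f"{label_map}:{lineno}: expected 2 columns"
                    )
                vertex, label = tokens
                if (vertex, label) == ("vertex", "haplotype"):
                    continue
                labeling[label] = vertex
    else:
        vertices = {v for u, w, _ in edges for v in (u, w)}
        labeling = {v: v for v in vertices}
    return HaplotypePhylogeny(edges, labeling)


# ---------------------------------------------------------------------------
# Regions and result tables
# ---------------------------------------------------------------------------

def read_regions(path: str | Path) -> RegionTable:
    """Region assignment TSV: haplotype_id, region (one row per occurrence)."""
    regions: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            hap, region = tokens
            if lineno == 1 and (hap, region) == ("haplotype_id", "region"):
                continue
            regions.setdefault(region, []).append(hap)
    if not regions:
        raise FormatError(f"{path}: no region assignments found")
    return RegionTable({r: tuple(labs) for r, labs in regions.items()})


def write_regions(regions: RegionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("haplotype_id\tregion\n")
        for name, labels in regions:
            for hap in labels:
                fh.write(f"{hap}\t{name}\n")


def scores_to_frame(rows: Sequence[ScoreRow], digits: int = 2) -> pd.DataFrame:
    """Score rows as a DataFrame, normalized columns rounded for display."""
    if not rows:
        raise InputError("no score rows")
    return pd.DataFrame([r.rounded(digits) for r in rows])


def write_scores_tsv(
    rows: Sequence[ScoreRow], path: str | Path, digits: int = 2
) -> None:
    scores_to_frame(rows, digits).to_csv(path, sep="\t", index=False)


def write_scores_json(rows: Sequence[ScoreRow], path: str | Path) -> None:
    """Full-precision machine-readable score table."""
    payload = [
        {
            "region": r.region,
            "n": r.n,
            "diversity_measure": r.diversity_measure,
            "diversity": r.diversity,
            "diversity_min": r.diversity_min,
            "diversity_max": r.diversity_max,
            "diversity_norm": r.diversity_norm,
            "hc": r.hc,
            "hc_min": r.hc_min,
            "hc_max": r.hc_max,
            "hc_norm": r.hc_norm,
            "annotation": r.annotation,
        }
        for r in rows
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_gds_tsv(spectrum: DiversitySpectrum, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("distance\tpair_count\n")
        for d, c in zip(spectrum.distances, spectrum.counts):
            fh.write(f"{d:g}\t{c}\n")


def write_spanning_tree_tsv(
    edges: Iterable[tuple[str, str, float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("vertex1\tvertex2\tweight\n")
        for u, v, w in edges:
            fh.write(f"{u}\t{v}\t{w:g}\n")
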