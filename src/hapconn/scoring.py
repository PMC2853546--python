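"""Normalized scores and per-region ranking tables.

Raw HC and diversity values are not comparable across regions of
different sample sizes, so every raw score for a region of k haplotypes
is normalized against the minimum and maximum achievable over *all*
k-subsets of the full haplotype set X:

    score* = (raw - min_k) / (max_k - min_k)        in [0, 1]

``score_regions`` assembles one row per geographic region — size, the
diversity triple (PD or AD) and normalized diversity, the connectivity
triple and normalized HC — sorted by normalized diversity, and
``interpret`` adds the advisory hot-spot / melting-pot annotation:
among regions of high normalized diversity, high HC* (haplotypes clumped
into divergent groups) suggests a melting-pot of secondary contact, and
low HC* (haplotypes dispersed over the phylogeny) a hot-spot of in-situ
diversification.  Low-diversity regions are not assessed — the method is
only informative where diversity is high.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np

from .connectivity import ConnectivityProfile, haplotype_connectivity
from .distances import DistanceMatrix, HaplotypePhylogeny
from .diversity import DEFAULT_EXACT_CAP, ad, ad_extrema, pd, pd_max, pd_min
from .errors import InputError, ValidationError

__all__ = ["RegionTable", "ScoreRow", "normalize", "score_regions", "interpret"]

logger = logging.getLogger(__name__)

NOT_ASSESSED = "low-diversity (not assessed)"
HOT_SPOT = "hot-spot-like"
MELTING_POT = "melting-pot-like"


@dataclass(frozen=True)
class RegionTable:
    """Map from region name to the haplotype labels found there.

    A haplotype may occur in several regions; multiplicities are ignored
    throughout — what matters is *which* haplotypes were found, not how
    often.
    """

    regions: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        cleaned = {}
        for name, labels in dict(self.regions).items():
            labels = tuple(dict.fromkeys(labels))  # dedupe, keep order
            if not labels:
                raise InputError(f"region {name!r} has no haplotypes")
            cleaned[str(name)] = labels
        if not cleaned:
            raise InputError("region table is empty")
        object.__setattr__(self, "regions", cleaned)

    def __iter__(self):
        return iter(self.regions.items())

    def __len__(self) -> int:
        return len(self.regions)


@dataclass(frozen=True)
class ScoreRow:
    """One region's row of the score table (Tables 1-2 column structure)."""

    region: str
    n: int
    diversity_measure: str  # "PD" | "AD"
    diversity: float
    diversity_min: float
    diversity_max: float
    diversity_norm: float
    hc: float
    hc_min: float
    hc_max: float
    hc_norm: float
    annotation: str | None = field(default=None)

    def rounded(self, digits: int = 2) -> dict:
        """Row as a dict with normalized scores rounded half-up for display."""
        q = Decimal(1).scaleb(-digits)

        def r(x: float) -> float:
            return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))

        return {
            "region": self.region,
            "n": self.n,
            self.diversity_measure: self.diversity,
            f"{self.diversity_measure}_min": self.diversity_min,
            f"{self.diversity_measure}_max": self.diversity_max,
            f"{self.diversity_measure}*": r(self.diversity_norm),
            "HC": self.hc,
            "HC_min": self.hc_min,
            "HC_max": self.hc_max,
            "HC*": r(self.hc_norm),
            "annotation": self.annotation,
        }


def normalize(raw: float, lo: float, hi: float) -> float:
    """(raw - lo) / (hi - lo); 0 when hi == lo (degenerate range).

    Requires lo <= raw <= hi; the result always lies in [0, 1].
    """
    if not lo <= raw <= hi:
        raise ValidationError(
            f"raw score {raw} outside its extremal range [{lo}, {hi}]"
        )
    if hi == lo:
        return 0.0
    return (raw - lo) / (hi - lo)


def score_regions(
    D: DistanceMatrix,
    regions: RegionTable,
    diversity: str = "PD",
    phylogeny: HaplotypePhylogeny | None = None,
    *,
    ad_exponent: int = 2,
    ad_cap: int = DEFAULT_EXACT_CAP,
) -> list[ScoreRow]:
    """Score every region against the full haplotype set X.

    Extremal scores are computed at k = (number of haplotypes in the
    region) over all k-subsets of X, cached per distinct k.  Rows are
    sorted by normalized diversity descending, ties broken by region
    name.

    ``diversity="PD"`` requires a tree ``phylogeny`` whose label set
    matches X (typically D is its phyletic distance matrix);
    ``diversity="AD"`` works from D alone but is exact-only and subject
    to the ``ad_cap`` size cap.
    """
    if diversity not in ("PD", "AD"):
        raise InputError(f"diversity must be 'PD' or 'AD', got {diversity!r}")
    if diversity == "PD":
        if phylogeny is None:
            raise InputError("diversity='PD' requires a phylogeny")
        missing = set(D.labels) - set(phylogeny.labels)
        if missing:
            raise InputError(
                f"phylogeny lacks labels present in D: {sorted(missing)}"
            )
    for name, labels in regions:
        D.subset_indices(labels)  # raises on unknown labels

    profile = ConnectivityProfile(D)
    div_cache: dict[int, tuple[float, float]] = {}
    hc_cache: dict[int, tuple[float, float]] = {}

    def div_bounds(k: int) -> tuple[float, float]:
        if k not in div_cache:
            logger.info("computing %s extrema at k=%d", diversity, k)
            if diversity == "PD":
                div_cache[k] = (pd_min(phylogeny, k), pd_max(phylogeny, k))
            elif k == 1:
                div_cache[k] = (0.0, 0.0)
            else:
                div_cache[k] = (
                    ad_extrema(D, k, "min", exponent=ad_exponent, cap=ad_cap),
                    ad_extrema(D, k, "max", exponent=ad_exponent, cap=ad_cap),
                )
        return div_cache[k]

    def hc_bounds(k: int) -> tuple[float, float]:
        if k not in hc_cache:
            logger.info("computing HC extrema at k=%d", k)
            b = profile.bounds(k)
            hc_cache[k] = (b.hc_min, b.hc_max)
        return hc_cache[k]

    rows = []
    for name, labels in regions:
        k = len(labels)
        if diversity == "PD":
            raw_div = pd(phylogeny, labels)
        else:
            raw_div = ad(D, labels, exponent=ad_exponent)
        dlo, dhi = div_bounds(k)
        raw_hc = haplotype_connectivity(D, labels)
        hlo, hhi = hc_bounds(k)
        rows.append(
            ScoreRow(
                region=name,
                n=k,
                diversity_measure=diversity,
                diversity=raw_div,
                diversity_min=dlo,
                diversity_max=dhi,
                diversity_norm=normalize(raw_div, dlo, dhi),
                hc=raw_hc,
                hc_min=hlo,
                hc_max=hhi,
                hc_norm=normalize(raw_hc, hlo, hhi),
            )
        )
    rows.sort(key=lambda r: (-r.diversity_norm, r.region))
    return rows


def interpret(
    rows: Iterable[ScoreRow],
    diversity_quantile: float = 0.5,
    hc_cut: float = 0.5,
) -> list[ScoreRow]:
    """Attach advisory hot-spot / melting-pot annotations.

    Regions whose normalized diversity reaches the ``diversity_quantile``
    of the table are assessed: HC* at or above ``hc_cut`` is annotated
    melting-pot-like, below it hot-spot-like.  All other regions get
    "low-diversity (not assessed)".  The annotation is qualitative: the
    underlying inference is comparative, and no universal numeric
    threshold exists.
    """
    rows = list(rows)
    if not rows:
        raise InputError("no score rows to interpret")
    cut = float(np.quantile([r.diversity_norm for r in rows], diversity_quantile))
    out = []
    for r in rows:
        if r.diversity_norm >= cut:
            label = MELTING_POT if r.hc_norm >= hc_cut else HOT_SPOT
        else:
            label = NOT_ASSESSED
        out.append(replace(r, annotation=label))
    return out
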