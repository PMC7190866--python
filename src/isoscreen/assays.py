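"""Small formula-defined assay quantifications.

Comet-assay Olive Tail Moment, RNA in situ hybridization score binning,
DAB-positivity percentage, Western-blot densitometry fold-ratio, caliper
tumor volume and cohort mutation frequency. Each is a direct transcription
of the formula or rubric used to quantify the corresponding assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "CometCell",
    "DensitometryPair",
    "olive_tail_moment",
    "ish_score",
    "dab_percent",
    "densitometry_fold",
    "tumor_volume",
    "cohort_frequency",
]


@dataclass(frozen=True)
class CometCell:
    """Per-cell comet-assay intensities (arbitrary units) and tail %DNA."""

    head_mean_intensity: float
    tail_mean_intensity: float
    tail_pct_dna: float

    def __post_init__(self) -> None:
        if self.head_mean_intensity < 0 or self.tail_mean_intensity < 0:
            raise ValueError("intensities must be non-negative")
        if not 0.0 <= self.tail_pct_dna <= 100.0:
            raise ValueError("tail_pct_dna must be in [0, 100]")


def olive_tail_moment(cell: CometCell, tail_centroid_distance: float | None = None) -> float:
    """Olive Tail Moment: (mean tail - mean head intensity) x tail%DNA / 100.

    Implemented as the intensity-difference form; may be negative when the
    head outshines the tail. Pass ``tail_centroid_distance`` to compute the
    canonical centroid-based variant (centroid separation x tail%DNA / 100)
    for comparison instead.
    """
    if tail_centroid_distance is not None:
        return tail_centroid_distance * cell.tail_pct_dna / 100.0
    return (cell.tail_mean_intensity - cell.head_mean_intensity) * cell.tail_pct_dna / 100.0


#: ISH rubric bin edges on mean dots/cell: [0,1) -> 0, [1,4) -> 1, [4,10) -> 2,
#: [10,16) -> 3, [16,inf) -> 4. The printed rubric is integer-valued
#: ("1-3 dots/cell", "4-9", "10-15", ">15"); half-open bins on the mean are
#: the documented interpretation for non-integer values.
_ISH_EDGES = (1.0, 4.0, 10.0, 16.0)


def ish_score(mean_dots_per_cell: float) -> int:
    """Semi-quantitative 0-4 RNA-ISH score from mean signal dots per cell."""
    x = float(mean_dots_per_cell)
    if x < 0:
        raise ValueError("mean dots per cell must be >= 0")
    score = 0
    for edge in _ISH_EDGES:
        if x >= edge:
            score += 1
    return score


def dab_percent(n_positive: int, n_total: int) -> float:
    """Percentage of DAB-positive cells among counted cells."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_positive <= n_total:
        raise ValueError("need 0 <= n_positive <= n_total")
    return 100.0 * n_positive / n_total


@dataclass(frozen=True)
class DensitometryPair:
    """Band intensities for a combination-treated vs comparator-treated lane,
    each with its loading-control band."""

    target_combo: float
    loading_combo: float
    target_comparator: float
    loading_comparator: float

    def __post_init__(self) -> None:
        if self.loading_combo <= 0 or self.loading_comparator <= 0:
            raise ValueError("loading-control intensities must be positive")


def densitometry_fold(pair: DensitometryPair) -> float:
    """Loading-normalized fold ratio of the combination lane over the
    comparator lane: (target_c/loading_c) / (target_ref/loading_ref)."""
    if pair.target_comparator == 0:
        raise ValueError("comparator target band is zero; fold undefined")
    return (pair.target_combo / pair.loading_combo) / (
        pair.target_comparator / pair.loading_comparator
    )


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumor volume in mm^3: length x width^2 x 3.14159 / 6.

    By caliper convention length >= width; a wider-than-long measurement is
    computed anyway with a warning. Equals the sphere volume pi*d^3/6 when
    length = width = d.
    """
    if width_mm <= 0:
        raise ValueError("width must be positive")
    if length_mm <= 0:
        raise ValueError("length must be positive")
    if width_mm > length_mm:
        warnings.warn("width exceeds length; check caliper axis convention")
    return length_mm * width_mm**2 * 3.14159 / 6.0


def cohort_frequency(n_mutant: int, n_cohort: int) -> float:
    """Mutation frequency as a percentage rounded to 1 decimal.

    Rounding is half-away-from-zero (so 4.45 -> 4.5), not banker's.
    """
    if n_cohort <= 0:
        raise ValueError("empty cohort")
    if not 0 <= n_mutant <= n_cohort:
        raise ValueError("need 0 <= n_mutant <= n_cohort")
    pct = Decimal(100 * n_mutant) / Decimal(n_cohort)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
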