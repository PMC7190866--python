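"""Bliss Independence synergy scoring over drug-pair dose matrices.

The Bliss null model treats two drugs as independent "kill" events: for
single-agent fractional inhibitions fA and fB the expected combination
inhibition is ``fA + fB - fA*fB``. The per-cell combination index is

    CI = expected - observed

so observed inhibition above the expectation gives CI < 0 (synergy) and
below gives CI > 0 (antagonism).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "DoseMatrix",
    "BlissSurface",
    "fractional_inhibition",
    "bliss_expected",
    "bliss_score",
    "bliss_surface",
    "read_dose_matrix",
    "write_dose_matrix",
]

#: single-agent inhibition at or above this is flagged saturated: the Bliss
#: expectation is pinned near 1 there and the score carries no information
SATURATION_LIMIT = 0.99


def fractional_inhibition(viability_percent):
    """Convert % viability to fractional inhibition, clipped to [0, 1].

    Growth stimulation (viability > 100%) clips to 0 rather than going
    negative, keeping the Bliss formula inside its probabilistic domain.
    """
    v = np.asarray(viability_percent, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("viability must be finite")
    f = np.clip(1.0 - v / 100.0, 0.0, 1.0)
    return float(f) if f.ndim == 0 else f


def _check_unit(x, name: str):
    a = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(a)) or np.any(a < 0) or np.any(a > 1):
        raise ValueError(f"{name} must be in [0, 1]")
    return a


def bliss_expected(f_a, f_b):
    """Expected inhibition under independence: fA + fB - fA*fB."""
    a = _check_unit(f_a, "f_a")
    b = _check_unit(f_b, "f_b")
    out = a + b - a * b
    return float(out) if out.ndim == 0 else out


def bliss_score(observed_f, expected_f):
    """Combination index CI = expected - observed (CI < 0 means synergy)."""
    o = _check_unit(observed_f, "observed_f")
    e = _check_unit(expected_f, "expected_f")
    out = e - o
    return float(out) if out.ndim == 0 else out


@dataclass
class DoseMatrix:
    """Replicate-averaged fractional-inhibition matrix with dose-0 margins.

    ``inhibition[i, j]`` is the observed mean fractional inhibition at
    ``doses_a[i]`` x ``doses_b[j]``; the first row/column (dose 0 for the
    partner) are the single-agent margins.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    inhibition: np.ndarray
    n_replicates: int = 1
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.inhibition = np.asarray(self.inhibition, dtype=float)
        if self.inhibition.shape != (self.doses_a.size, self.doses_b.size):
            raise ValueError("inhibition shape does not match dose grids")
        if 0.0 not in self.doses_a or 0.0 not in self.doses_b:
            raise ValueError("missing single-agent margin (dose 0 row/column)")
        if not np.all(np.isfinite(self.inhibition)):
            raise ValueError("inhibition must be finite")
        _check_unit(self.inhibition, "inhibition")

    @classmethod
    def from_viability(cls, doses_a, doses_b, viability_percent, **kw) -> "DoseMatrix":
        return cls(doses_a, doses_b, fractional_inhibition(viability_percent), **kw)


@dataclass
class BlissSurface:
    """Per-cell Bliss expectation and combination index over a dose matrix.

    ``scores`` is NaN on the single-agent margins (the model is defined for
    combinations only); ``saturated`` marks interior cells where either
    single agent already inhibits >= 99%, which are excluded from the
    summary statistics.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    scores: np.ndarray
    saturated: np.ndarray

    @property
    def interior(self) -> np.ndarray:
        return (self.doses_a[:, None] > 0) & (self.doses_b[None, :] > 0)

    def _summary_cells(self) -> np.ndarray:
        return self.interior & ~self.saturated

    @property
    def mean_score(self) -> float:
        cells = self._summary_cells()
        return float(np.mean(self.scores[cells])) if cells.any() else float("nan")

    @property
    def min_score(self) -> float:
        cells = self._summary_cells()
        return float(np.min(self.scores[cells])) if cells.any() else float("nan")

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-cell table (interior cells only)."""
        ia, ib = np.nonzero(self.interior)
        return pd.DataFrame(
            {
                "dose_a_um": self.doses_a[ia],
                "dose_b_um": self.doses_b[ib],
                "observed_inhibition": self.observed[ia, ib],
                "expected_inhibition": self.expected[ia, ib],
                "bliss_score": self.scores[ia, ib],
                "saturated": self.saturated[ia, ib],
            }
        )


def bliss_surface(matrix: DoseMatrix) -> BlissSurface:
    """Score every combination cell of a dose matrix against the Bliss model.

    Single-agent effects are read off the dose-0 margins of the same
    replicate-averaged matrix; ``expected[i, j] = fA_i + fB_j - fA_i*fB_j``
    and ``score = expected - observed`` for all interior cells.
    """
    ia0 = int(np.flatnonzero(matrix.doses_a == 0)[0])
    ib0 = int(np.flatnonzero(matrix.doses_b == 0)[0])
    f_a = matrix.inhibition[:, ib0]
    f_b = matrix.inhibition[ia0, :]
    expected = bliss_expected(f_a[:, None], f_b[None, :])
    interior = (matrix.doses_a[:, None] > 0) & (matrix.doses_b[None, :] > 0)
    scores = np.where(interior, expected - matrix.inhibition, np.nan)
    saturated = interior & (
        (f_a[:, None] >= SATURATION_LIMIT) | (f_b[None, :] >= SATURATION_LIMIT)
    )
    return BlissSurface(
        doses_a=matrix.doses_a,
        doses_b=matrix.doses_b,
        observed=matrix.inhibition,
        expected=expected,
        scores=scores,
        saturated=saturated,
    )


# ---------------------------------------------------------------------------
# wide-format CSV (first row/column = doses, cells = % viability)
# ---------------------------------------------------------------------------

def read_dose_matrix(path: str | Path, n_replicates: int = 1) -> DoseMatrix:
    """Read a wide dose-matrix CSV (rows = drug A doses, cols = drug B doses,
    cells = % viability) into a :class:`DoseMatrix`."""
    df = pd.read_csv(path, index_col=0)
    doses_a = df.index.to_numpy(dtype=float)
    doses_b = df.columns.to_numpy(dtype=float)
    return DoseMatrix.from_viability(doses_a, doses_b, df.to_numpy(dtype=float), n_replicates=n_replicates)


def write_dose_matrix(matrix: DoseMatrix, path: str | Path) -> None:
    """Write the matrix in the same wide layout, cells as % viability."""
    viability = 100.0 * (1.0 - matrix.inhibition)
    df = pd.DataFrame(viability, index=matrix.doses_a, columns=matrix.doses_b)
    df.index.name = "dose_a_um"
    df.to_csv(path, encoding="utf-8", lineterminator="\n")


def write_surface(surface: BlissSurface, path: str | Path) -> None:
    """Write per-cell Bliss scores mirroring the wide matrix layout."""
    df = pd.DataFrame(surface.scores, index=surface.doses_a, columns=surface.doses_b)
    df.index.name = "dose_a_um"
    df.to_csv(path, encoding="utf-8", lineterminator="\n")
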