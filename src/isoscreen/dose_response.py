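"""Four-parameter logistic (4PL) dose-response fitting and potency comparison.

The model for % viability v as a function of dose d is

    v(d) = bottom + (top - bottom) / (1 + (d / ec50)^hill)

with hill > 0 and top >= bottom, so the curve falls from ``top`` toward
``bottom`` with increasing dose. Two potency readouts are distinguished:
``ec50`` (the relative midpoint, reported as ED50) and the absolute IC50,
the dose where the fitted curve crosses 50% viability — these coincide only
when (bottom, top) = (0, 100).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseFit",
    "four_pl",
    "fit_4pl",
    "ic50_absolute",
    "potency_fold_change",
    "ic50_shift",
]


def four_pl(dose, bottom: float, top: float, hill: float, ec50: float):
    """Evaluate the 4PL viability curve at the given dose(s)."""
    d = np.asarray(dose, dtype=float)
    out = bottom + (top - bottom) / (1.0 + (d / ec50) ** hill)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DoseResponseFit:
    bottom: float
    top: float
    hill: float
    ec50: float
    residual_sum_squares: float
    converged: bool
    n_points: int
    degenerate: bool = False

    @property
    def ed50(self) -> float:
        """The curve midpoint; the screen's ED50 readout."""
        return self.ec50

    def predict(self, dose):
        return four_pl(dose, self.bottom, self.top, self.hill, self.ec50)


def _failed(n: int) -> DoseResponseFit:
    return DoseResponseFit(
        bottom=float("nan"), top=float("nan"), hill=float("nan"), ec50=float("nan"),
        residual_sum_squares=float("nan"), converged=False, n_points=n, degenerate=True,
    )


def fit_4pl(
    doses: Sequence[float],
    viability: Sequence[float],
    bottom: float | None = None,
    top: float | None = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit of % viability against dose.

    Requires >= 4 distinct positive doses. ``bottom``/``top`` may be pinned
    (e.g. 0/100 for a constrained fit); both are free by default. The
    optimizer works in (bottom, log span, log hill, log ec50) space, which
    enforces top >= bottom and hill, ec50 > 0. Initialization: top = max
    response, bottom = min response, ec50 = geometric-mean dose, hill = 1,
    with one restart from a perturbed start on failure. Constant responses
    yield a degenerate, unconverged fit rather than an error.
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(viability, dtype=float)
    if d.shape != v.shape:
        raise ValueError("doses and viability must have equal length")
    if np.unique(d).size < 4:
        raise ValueError("need at least 4 distinct doses")
    if np.any(d <= 0):
        raise ValueError("doses must be strictly positive")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite responses")

    if np.ptp(v) < 1e-9:
        return _failed(d.size)

    fix_b, fix_t = bottom, top
    b0 = float(np.min(v)) if fix_b is None else fix_b
    t0 = float(np.max(v)) if fix_t is None else fix_t
    span0 = max(t0 - b0, 1e-3)
    ec0 = float(np.exp(np.mean(np.log(d))))

    def unpack(p):
        k = 0
        if fix_b is None:
            b = p[k]; k += 1
        else:
            b = fix_b
        if fix_t is None:
            span = np.exp(p[k]); k += 1
            t = b + span
        else:
            t = fix_t
        hill = np.exp(p[k]); k += 1
        ec50 = np.exp(p[k])
        return b, t, hill, ec50

    def resid(p):
        b, t, hill, ec50 = unpack(p)
        return four_pl(d, b, t, hill, ec50) - v

    def start(b, span, hill, ec50):
        p = []
        if fix_b is None:
            p.append(b)
        if fix_t is None:
            p.append(np.log(max(span, 1e-6)))
        p.extend([np.log(hill), np.log(ec50)])
        return np.asarray(p)

    attempts = [start(b0, span0, 1.0, ec0), start(b0, span0, 1.5, ec0 * 3.0)]
    best = None
    for p0 in attempts:
        try:
            res = least_squares(resid, p0, method="lm", max_nfev=5000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if res.success and res.cost < 1e-12:
            break
    if best is None or not np.all(np.isfinite(best.x)):
        return _failed(d.size)

    b, t, hill, ec50 = unpack(best.x)
    rss = float(2.0 * best.cost)
    # degenerate: vanished span or midpoint absurdly far outside the dose range
    degenerate = (t - b) < 1e-3 or not (d.min() / 1e4 < ec50 < d.max() * 1e4)
    return DoseResponseFit(
        bottom=float(b), top=float(t), hill=float(hill), ec50=float(ec50),
        residual_sum_squares=rss, converged=bool(best.success) and not degenerate,
        n_points=int(d.size), degenerate=degenerate,
    )


def ic50_absolute(fit: DoseResponseFit) -> float:
    """Dose where the fitted curve crosses 50% viability (absolute IC50).

    Defined only when bottom < 50 < top; otherwise the curve never reaches
    50% and a ValueError flags it.
    """
    if not fit.converged:
        raise ValueError("ic50_absolute requires a converged fit")
    if not (fit.bottom < 50.0 < fit.top):
        raise ValueError(
            f"curve does not cross 50% viability (bottom={fit.bottom:.3g}, top={fit.top:.3g})"
        )
    return float(fit.ec50 * ((fit.top - 50.0) / (50.0 - fit.bottom)) ** (1.0 / fit.hill))


def potency_fold_change(
    fit_target_line: DoseResponseFit,
    fit_reference_line: DoseResponseFit,
    threshold: float = 10.0,
) -> tuple[float, bool]:
    """ED50 fold difference between lines: fold = ed50_ref / ed50_target.

    The selectivity flag is inclusive at the threshold (a 10-fold
    difference counts as selective).
    """
    if not (fit_target_line.converged and fit_reference_line.converged):
        raise ValueError("potency_fold_change requires converged fits")
    fold = fit_reference_line.ed50 / fit_target_line.ed50
    return float(fold), bool(fold >= threshold)


def ic50_shift(fit_drug_alone: DoseResponseFit, fit_drug_plus_modulator: DoseResponseFit) -> float:
    """IC50(alone) / IC50(+modulator); ratio > 1 indicates sensitization."""
    return ic50_absolute(fit_drug_alone) / ic50_absolute(fit_drug_plus_modulator)
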