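"""Evaluation measures: MRE/MMRE, Pearson, Spearman, and the cubic-fit R².

MMRE — the mean magnitude of relative error, reported in percent — is both
the search objective and the headline accuracy measure.  It is computed on
the decoded percent scale, never on coded values, and is deliberately
asymmetric in its arguments: the denominator is always the *actual* value.

The "cubic R²" is the determination coefficient of an ordinary
least-squares fit of the estimates on ``{1, a, a², a³}`` of the actuals —
the standard curve-estimation statistic.  It is always at least the square
of the Pearson correlation on the same data, since the cubic span contains
the linear one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["mre", "mmre", "pearson", "spearman", "r2_cubic", "EvaluationReport"]


def _pair(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("actual and predicted must be 1-d vectors of equal length >= 1")
    return a, p


def mre(actual, predicted) -> np.ndarray:
    """Per-observation magnitude of relative error, in percent."""
    a, p = _pair(actual, predicted)
    if np.any(a <= 0):
        raise ValueError("MRE undefined for non-positive actual values")
    return 100.0 * np.abs(a - p) / a


def mmre(actual, predicted) -> float:
    """Mean magnitude of relative error, percent: ``100·mean(|a−p|/a)``."""
    return float(np.mean(mre(actual, predicted)))


def pearson(x, y) -> float:
    """Product-moment correlation; raises on constant input."""
    xv, yv = _pair(x, y)
    if xv.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(xv, yv).statistic)


def spearman(x, y) -> float:
    """Rank correlation with average ranks for ties; raises on constant input."""
    xv, yv = _pair(x, y)
    if xv.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.spearmanr(xv, yv).statistic)


def r2_cubic(actual, predicted) -> float:
    """R² of the OLS cubic fit of ``predicted`` on ``actual``.

    Requires at least 5 observations and at least 4 distinct actual values
    (otherwise the cubic design matrix is rank deficient).
    """
    a, p = _pair(actual, predicted)
    if a.size < 5:
        raise ValueError("need at least 5 observations for a cubic fit")
    if len(np.unique(a)) < 4:
        raise ValueError("need at least 4 distinct actual values for a cubic fit")
    design = np.vander(a, 4, increasing=True)  # 1, a, a^2, a^3
    coef, *_ = np.linalg.lstsq(design, p, rcond=None)
    resid = p - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((p - p.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0  # constant predictions: no variance to explain
    return 1.0 - ss_res / ss_tot


@dataclass
class EvaluationReport:
    """One evaluation row: a model, a phase, a year panel, and its measures."""

    model: str
    phase: str          # "training" | "testing"
    year: str           # "2013" | "2019" | "2013-2019"
    mmre_pct: float
    pearson_r: float | None = None
    spearman_rho: float | None = None
    r2_cubic: float | None = None

    def as_row(self) -> dict:
        return {
            "model": self.model,
            "phase": self.phase,
            "year": self.year,
            "mmre_pct": self.mmre_pct,
            "pearson": self.pearson_r,
            "spearman_rho": self.spearman_rho,
            "r2_cubic": self.r2_cubic,
        }
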