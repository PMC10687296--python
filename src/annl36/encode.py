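"""Coding functions applied to features and targets before network training.

Four families are provided, mirroring the model variants of the experiment:

* **fuzzy** — triangular fuzzification over three linguistic terms
  (low / medium / high) followed by centroid defuzzification.  The term
  peaks sit at the minimum, midpoint and maximum of the fitted support, so
  adjacent memberships form a partition of unity and the fuzzify→defuzzify
  round trip is the exact identity on the support.
* **log** — ``ln(1+x) / ln(1+x_max)``, compressing large prevalences.
* **minmax** — affine map of ``[min, max]`` onto ``[0, 1]``.
* **zscore** — standardization ``(x - mean) / sd``.

All coders expose the same ``encode``/``decode`` pair and are fitted on the
training split only; encoding a value outside the fitted support raises
unless clamping is requested explicitly (clamps are logged, never silent).

Targets may additionally be mapped into an interior *output band* of the
unit interval (default ``[0.2, 0.8]`` in the experiment).  Keeping coded
targets away from 0 and 1 is standard practice for sigmoid-output networks:
the weight search then operates where the sigmoid has usable slope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "FuzzyScheme",
    "CodingConfig",
    "fuzzify",
    "defuzzify",
    "log_encode",
    "log_decode",
    "minmax_normalize",
    "minmax_denormalize",
    "z_standardize",
    "z_destandardize",
    "OutOfSupportError",
]

logger = logging.getLogger(__name__)

CodingKind = Literal["fuzzy", "log", "minmax", "zscore", "identity"]


class OutOfSupportError(ValueError):
    """A value fell outside the fitted coding support and clamping was off."""


@dataclass(frozen=True)
class FuzzyScheme:
    """Triangular membership partition over ``[support_min, support_max]``.

    ``peaks`` are the term centers; the first and last peak coincide with the
    support ends so that the triangular memberships over adjacent peaks sum
    to one everywhere on the support.
    """

    support: tuple[float, float]
    peaks: tuple[float, ...]

    def __post_init__(self) -> None:
        lo, hi = self.support
        if not (hi > lo):
            raise ValueError(f"degenerate support [{lo}, {hi}]")
        if len(self.peaks) < 2:
            raise ValueError("need at least two term peaks")
        if any(b <= a for a, b in zip(self.peaks, self.peaks[1:])):
            raise ValueError(f"peaks must be strictly increasing: {self.peaks}")
        if not math.isclose(self.peaks[0], lo) or not math.isclose(self.peaks[-1], hi):
            raise ValueError("first/last peak must coincide with the support ends")

    @property
    def n_terms(self) -> int:
        return len(self.peaks)

    @classmethod
    def from_support(cls, lo: float, hi: float, n_terms: int = 3) -> "FuzzyScheme":
        """Equally spaced peaks between ``lo`` and ``hi`` (default low/medium/high)."""
        peaks = tuple(lo + (hi - lo) * i / (n_terms - 1) for i in range(n_terms))
        return cls(support=(float(lo), float(hi)), peaks=peaks)


def fuzzify(x: float | np.ndarray, scheme: FuzzyScheme) -> np.ndarray:
    """Membership degrees of ``x`` in each linguistic term.

    Triangular memberships over adjacent peaks; the result is non-negative
    and sums to exactly one (partition of unity).  For array input the term
    axis is the last axis.
    """
    xv = np.asarray(x, dtype=float)
    lo, hi = scheme.support
    if np.any(xv < lo) or np.any(xv > hi):
        raise OutOfSupportError(
            f"value outside support [{lo}, {hi}]; clamp explicitly before fuzzifying"
        )
    peaks = np.asarray(scheme.peaks)
    out = np.zeros(xv.shape + (scheme.n_terms,))
    # locate the surrounding peak pair and interpolate linearly
    idx = np.clip(np.searchsorted(peaks, xv, side="right") - 1, 0, scheme.n_terms - 2)
    left, right = peaks[idx], peaks[idx + 1]
    t = (xv - left) / (right - left)
    np.put_along_axis(out, idx[..., None], (1.0 - t)[..., None], axis=-1)
    np.put_along_axis(out, (idx + 1)[..., None], t[..., None], axis=-1)
    return out


def defuzzify(memberships: np.ndarray, scheme: FuzzyScheme) -> float | np.ndarray:
    """Centroid of the term peaks weighted by membership degree."""
    m = np.asarray(memberships, dtype=float)
    if np.any(m < 0):
        raise ValueError("memberships must be non-negative")
    total = m.sum(axis=-1)
    if np.any(total <= 0):
        raise ValueError("degenerate membership vector: all terms zero")
    val = (m * np.asarray(scheme.peaks)).sum(axis=-1) / total
    return float(val) if m.ndim == 1 else val


def log_encode(x: float | np.ndarray, x_max: float) -> float | np.ndarray:
    """``ln(1+x)/ln(1+x_max)`` — maps ``[0, x_max]`` onto ``[0, 1]``."""
    if x_max <= 0:
        raise ValueError("x_max must be positive")
    xv = np.asarray(x, dtype=float)
    if np.any(xv < 0):
        raise ValueError("log coding requires non-negative values")
    out = np.log1p(xv) / np.log1p(x_max)
    return float(out) if np.isscalar(x) else out


def log_decode(y: float | np.ndarray, x_max: float) -> float | np.ndarray:
    """Inverse of :func:`log_encode` (exact to floating point)."""
    if x_max <= 0:
        raise ValueError("x_max must be positive")
    out = np.expm1(np.asarray(y, dtype=float) * np.log1p(x_max))
    return float(out) if np.isscalar(y) else out


def minmax_normalize(x, lo: float, hi: float):
    if not hi > lo:
        raise ValueError(f"degenerate range [{lo}, {hi}]")
    out = (np.asarray(x, dtype=float) - lo) / (hi - lo)
    return float(out) if np.isscalar(x) else out


def minmax_denormalize(y, lo: float, hi: float):
    if not hi > lo:
        raise ValueError(f"degenerate range [{lo}, {hi}]")
    out = lo + np.asarray(y, dtype=float) * (hi - lo)
    return float(out) if np.isscalar(y) else out


def z_standardize(x, mean: float, sd: float):
    if sd <= 0:
        raise ValueError("sd must be positive")
    out = (np.asarray(x, dtype=float) - mean) / sd
    return float(out) if np.isscalar(x) else out


def z_destandardize(y, mean: float, sd: float):
    if sd <= 0:
        raise ValueError("sd must be positive")
    out = mean + np.asarray(y, dtype=float) * sd
    return float(out) if np.isscalar(y) else out


@dataclass
class CodingConfig:
    """A fitted, invertible scalar coder.

    ``kind`` selects the family; the fitted parameters (support, peaks,
    moments) are stored so a configuration can be serialized and re-applied
    bit-identically.  ``band`` optionally maps the coded unit value into an
    interior interval ``[band[0], band[1]]`` — used for targets.
    """

    kind: CodingKind = "fuzzy"
    support: tuple[float, float] | None = None
    mean: float | None = None
    sd: float | None = None
    band: tuple[float, float] | None = None
    n_terms: int = 3
    scheme: FuzzyScheme | None = field(default=None, repr=False)

    @classmethod
    def fit(
        cls,
        values,
        kind: CodingKind = "fuzzy",
        band: tuple[float, float] | None = None,
        n_terms: int = 3,
    ) -> "CodingConfig":
        """Fit coder parameters to observed (training) values."""
        v = np.asarray(values, dtype=float)
        if v.size == 0 or not np.all(np.isfinite(v)):
            raise ValueError("cannot fit a coder to empty or non-finite values")
        cfg = cls(kind=kind, band=band, n_terms=n_terms)
        if kind in ("fuzzy", "minmax", "log"):
            lo, hi = float(v.min()), float(v.max())
            if not hi > lo:
                raise ValueError("cannot fit coder support to constant values")
            cfg.support = (lo, hi)
            if kind == "fuzzy":
                cfg.scheme = FuzzyScheme.from_support(lo, hi, n_terms)
        elif kind == "zscore":
            sd = float(v.std(ddof=0))
            if sd <= 0:
                raise ValueError("cannot standardize constant values")
            cfg.mean, cfg.sd = float(v.mean()), sd
        elif kind != "identity":
            raise ValueError(f"unknown coding kind {kind!r}")
        return cfg

    def __post_init__(self) -> None:
        if self.kind == "fuzzy" and self.support is not None and self.scheme is None:
            self.scheme = FuzzyScheme.from_support(*self.support, self.n_terms)
        if self.band is not None and not self.band[1] > self.band[0]:
            raise ValueError(f"degenerate band {self.band}")

    # -- unit-scale maps -------------------------------------------------
    def _to_unit(self, x):
        if self.kind == "identity":
            return np.asarray(x, dtype=float)
        if self.kind == "zscore":
            return z_standardize(x, self.mean, self.sd)
        lo, hi = self.support
        if self.kind == "minmax":
            return minmax_normalize(x, lo, hi)
        if self.kind == "log":
            if lo < 0:
                raise ValueError("log coding requires a non-negative support")
            return (np.log1p(np.asarray(x, dtype=float)) - np.log1p(lo)) / (
                np.log1p(hi) - np.log1p(lo)
            )
        # fuzzy: memberships -> centroid over unit-normalized peak positions
        m = fuzzify(x, self.scheme)
        unit_peaks = minmax_normalize(np.asarray(self.scheme.peaks), lo, hi)
        return (m * unit_peaks).sum(axis=-1)

    def _from_unit(self, u):
        if self.kind == "identity":
            return np.asarray(u, dtype=float)
        if self.kind == "zscore":
            return z_destandardize(u, self.mean, self.sd)
        lo, hi = self.support
        if self.kind == "minmax":
            return minmax_denormalize(u, lo, hi)
        if self.kind == "log":
            return np.expm1(
                np.asarray(u, dtype=float) * (np.log1p(hi) - np.log1p(lo)) + np.log1p(lo)
            )
        # fuzzy: the unit centroid map is piecewise linear and strictly
        # increasing with knots at the unit peak positions — invert per piece
        unit_peaks = minmax_normalize(np.asarray(self.scheme.peaks), lo, hi)
        uv = np.asarray(u, dtype=float)
        idx = np.clip(np.searchsorted(unit_peaks, uv, side="right") - 1, 0, len(unit_peaks) - 2)
        left, right = unit_peaks[idx], unit_peaks[idx + 1]
        t = (uv - left) / (right - left)
        peaks = np.asarray(self.scheme.peaks)
        return peaks[idx] + t * (peaks[idx + 1] - peaks[idx])

    # -- public API ------------------------------------------------------
    def encode(self, x, clamp: bool = False):
        """Code ``x``; out-of-support values raise unless ``clamp=True``."""
        xv = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(xv)):
            raise ValueError("cannot encode non-finite values")
        if self.support is not None:
            lo, hi = self.support
            if clamp:
                n_out = int(np.sum((xv < lo) | (xv > hi)))
                if n_out:
                    logger.warning(
                        "clamping %d value(s) outside fitted support [%g, %g]", n_out, lo, hi
                    )
                xv = np.clip(xv, lo, hi)
            elif np.any(xv < lo) or np.any(xv > hi):
                raise OutOfSupportError(
                    f"value outside fitted support [{lo}, {hi}]; pass clamp=True to clamp"
                )
        u = self._to_unit(xv)
        if self.band is not None:
            a, b = self.band
            u = a + (b - a) * u
        return float(u) if np.isscalar(x) else u

    def decode(self, y):
        """Invert :meth:`encode`.  Total on all of R for every kind."""
        u = np.asarray(y, dtype=float)
        if self.band is not None:
            a, b = self.band
            u = (u - a) / (b - a)
        if self.kind == "fuzzy":
            # the piecewise inverse needs u within [0,1]; extend linearly
            # outside so decode stays total (network outputs can overshoot)
            uc = np.clip(u, 0.0, 1.0)
            base = self._from_unit(uc)
            lo, hi = self.support
            out = base + (u - uc) * (hi - lo)
        else:
            out = self._from_unit(u)
        return float(out) if np.isscalar(y) else out

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind, "n_terms": self.n_terms}
        if self.support is not None:
            d["support"] = list(self.support)
        if self.mean is not None:
            d["mean"], d["sd"] = self.mean, self.sd
        if self.band is not None:
            d["band"] = list(self.band)
        if self.scheme is not None:
            d["peaks"] = list(self.scheme.peaks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CodingConfig":
        cfg = cls(
            kind=d["kind"],
            support=tuple(d["support"]) if "support" in d else None,
            mean=d.get("mean"),
            sd=d.get("sd"),
            band=tuple(d["band"]) if "band" in d else None,
            n_terms=d.get("n_terms", 3),
        )
        if "peaks" in d and cfg.support is not None:
            cfg.scheme = FuzzyScheme(support=cfg.support, peaks=tuple(d["peaks"]))
        return cfg
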