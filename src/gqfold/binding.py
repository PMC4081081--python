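"""Ligand-quenching analysis: percent quenching, T25 background
subtraction, Hill fits for Kd, double-exponential saturation levels, EMSA
bound fractions and the correlation of binding with the parallel-conformer
fraction.

Note on the quenching transform: "% quenching" is computed as the
complement 100*(1 - F/F0), i.e. the fractional loss of fluorescence on a
0-100 scale — not the reciprocal of the reading.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .simulate import hill

__all__ = [
    "QuenchCurve",
    "HillFit",
    "SaturationFit",
    "BindingSummary",
    "percent_quenching",
    "subtract_background",
    "fit_hill",
    "fit_saturation",
    "emsa_bound_fraction",
    "correlate_with_parallel",
]


@dataclass
class QuenchCurve:
    construct: str
    ligand: str
    concentrations_uM: np.ndarray
    percent_quench: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations_uM = np.asarray(self.concentrations_uM, dtype=float)
        self.percent_quench = np.asarray(self.percent_quench, dtype=float)
        if (self.concentrations_uM < 0).any():
            raise ValueError("concentrations must be non-negative")
        if not np.all(np.diff(self.concentrations_uM) > 0):
            raise ValueError("concentrations must be strictly increasing")


@dataclass
class HillFit:
    vmax: float
    k: float  # apparent Kd, uM
    n: float  # Hill coefficient
    residual_norm: float
    converged: bool


@dataclass
class SaturationFit:
    saturation: float  # % quench at saturation (A1 + A2)
    fallback: bool  # True when the double-exponential fit failed


@dataclass
class BindingSummary:
    constructs: list[str]
    percent_parallel: np.ndarray
    quantities: dict[str, np.ndarray] = field(default_factory=dict)


def percent_quenching(fluorescence: np.ndarray, f0: float) -> np.ndarray:
    """q(x) = 100 * (1 - F(x)/F0), clipped to [0, 100] with a warning."""
    if f0 <= 0:
        raise ValueError("F0 must be positive")
    q = 100.0 * (1.0 - np.asarray(fluorescence, dtype=float) / f0)
    if (q < 0).any() or (q > 100).any():
        _warnings.warn("percent quenching outside [0, 100]; clipping")
        q = np.clip(q, 0.0, 100.0)
    return q


def subtract_background(
    quench: np.ndarray,
    t25_quench: np.ndarray,
    concentrations: np.ndarray | None = None,
    t25_concentrations: np.ndarray | None = None,
) -> np.ndarray:
    """Pointwise background subtraction, floored at 0.

    When the two concentration grids differ, the background is linearly
    interpolated onto the signal grid (with a warning); disjoint grids are
    an error.
    """
    quench = np.asarray(quench, dtype=float)
    t25_quench = np.asarray(t25_quench, dtype=float)
    if concentrations is not None and t25_concentrations is not None:
        concentrations = np.asarray(concentrations, dtype=float)
        t25_concentrations = np.asarray(t25_concentrations, dtype=float)
        if not np.array_equal(concentrations, t25_concentrations):
            lo = max(concentrations.min(), t25_concentrations.min())
            hi = min(concentrations.max(), t25_concentrations.max())
            if lo > hi:
                raise ValueError("signal and background grids are disjoint")
            _warnings.warn("concentration grids differ; interpolating background")
            t25_quench = np.interp(
                concentrations, t25_concentrations, t25_quench
            )
    elif quench.shape != t25_quench.shape:
        raise ValueError("grids differ in length and no concentrations given")
    return np.clip(quench - t25_quench, 0.0, None)


def fit_hill(curve: QuenchCurve) -> HillFit:
    """Multi-start nonlinear least squares of the Hill saturation model.

    Starting k values span the measured concentration range (log-spaced)
    crossed with Hill coefficients {0.5, 1, 2}; bounds keep k positive,
    n in [0.2, 6] and Vmax in (0, 120].
    """
    x, y = curve.concentrations_uM, curve.percent_quench
    positive = x[x > 0]
    if x.size < 5:
        raise ValueError("need at least 5 concentration points")
    if positive.size and positive.max() / positive.min() < 10:
        raise ValueError("concentrations must span at least one decade")
    k_starts = np.geomspace(positive.min(), positive.max(), 5)
    vmax0 = max(float(y.max()), 1.0)
    best = None
    for k0 in k_starts:
        for n0 in (0.5, 1.0, 2.0):
            try:
                popt, _ = optimize.curve_fit(
                    hill,
                    x,
                    y,
                    p0=[vmax0, k0, n0],
                    bounds=([1e-6, 1e-9, 0.2], [120.0, np.inf, 6.0]),
                    maxfev=5000,
                )
            except RuntimeError:
                continue
            resid = float(np.linalg.norm(hill(x, *popt) - y))
            if best is None or resid < best[0]:
                best = (resid, popt)
    if best is None:
        return HillFit(np.nan, np.nan, np.nan, np.inf, converged=False)
    resid, (vmax, k, n) = best
    return HillFit(float(vmax), float(k), float(n), resid, converged=True)


def _double_exp(x, a1, c1, a2, c2):
    return a1 * (1.0 - np.exp(-x / c1)) + a2 * (1.0 - np.exp(-x / c2))


def fit_saturation(curve: QuenchCurve) -> SaturationFit:
    """Saturation level from a double-exponential fit, q = A1(1-e^-x/c1) +
    A2(1-e^-x/c2); falls back to the maximum observed quench on failure."""
    x, y = curve.concentrations_uM, curve.percent_quench
    if x.size < 6:
        raise ValueError("need at least 6 concentration points")
    span = max(x.max(), 1e-6)
    try:
        popt, _ = optimize.curve_fit(
            _double_exp,
            x,
            y,
            p0=[0.7 * max(y.max(), 1.0), span / 10, 0.3 * max(y.max(), 1.0), span],
            bounds=([0, 1e-9, 0, 1e-9], [120, np.inf, 120, np.inf]),
            maxfev=5000,
        )
    except RuntimeError:
        return SaturationFit(saturation=float(y.max()), fallback=True)
    return SaturationFit(saturation=float(popt[0] + popt[2]), fallback=False)


def emsa_bound_fraction(shifted_area: float, unshifted_area: float) -> float:
    """% bound = 100 * shifted / (shifted + unshifted)."""
    if shifted_area < 0 or unshifted_area < 0:
        raise ValueError("band areas must be non-negative")
    total = shifted_area + unshifted_area
    if total == 0:
        raise ValueError("both band areas are zero")
    return 100.0 * shifted_area / total


def correlate_with_parallel(
    percent_parallel: np.ndarray, quantity: np.ndarray
) -> dict:
    """Pearson and Spearman correlation of a binding quantity against the
    parallel-conformer percentage across constructs."""
    x = np.asarray(percent_parallel, dtype=float)
    y = np.asarray(quantity, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 constructs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"pearson": None, "spearman": None, "n": int(x.size),
                "note": "undefined for a constant vector"}
    pearson = stats.pearsonr(x, y).statistic
    spearman = stats.spearmanr(x, y).statistic
    return {"pearson": float(pearson), "spearman": float(spearman), "n": int(x.size)}
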