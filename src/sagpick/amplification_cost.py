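"""Selection costs from whole-genome-amplification kinetics.

Each sorted cell's real-time amplification curve is fit with a 4-parameter
logistic F(t) = F0 + A / (1 + exp(-r (t - tinf))); the fitted inflection time
tinf is the cell's selection cost (minutes). Wells whose curves never rise —
amplitude indistinguishable from noise — are marked as failed amplification
and get infinite cost, which excludes them from selection downstream.

The module also houses the forward-scatter calibration: cell diameter D is
predicted from flow-cytometry forward scatter (FSC) by the log-linear model
D = 10^(a*log10(FSC) - b), with a and b fit by ordinary least squares on
log10-transformed reference-culture data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "AmplificationCurve",
    "SigmoidFit",
    "CalibrationModel",
    "fit_sigmoid",
    "cost_of",
    "fit_calibration",
    "predict_diameter",
    "costs_from_curves",
]

MIN_POINTS = 8


@dataclass(frozen=True)
class AmplificationCurve:
    cell_id: str
    times: np.ndarray  # minutes, strictly increasing
    fluorescence: np.ndarray  # arbitrary units

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.fluorescence, dtype=float)
        if t.size < MIN_POINTS:
            raise ValueError(f"need >= {MIN_POINTS} time points, got {t.size}")
        if t.size != y.size:
            raise ValueError("times and fluorescence must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(y)):
            raise ValueError("curve contains NaN/inf values")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fluorescence", y)


@dataclass(frozen=True)
class SigmoidFit:
    cell_id: str
    baseline: float  # F0
    amplitude: float  # A
    rate: float  # r, 1/min
    inflection: float  # tinf, min
    rss: float
    converged: bool
    failed_amplification: bool


@dataclass(frozen=True)
class CalibrationModel:
    a: float
    b: float
    r_squared: float


def _logistic(t, f0, a, r, tinf):
    return f0 + a / (1.0 + np.exp(-np.clip(r * (t - tinf), -500, 500)))


def _initial_guess(t: np.ndarray, y: np.ndarray) -> Tuple[float, float, float, float]:
    f0 = float(np.percentile(y, 5))
    a = max(float(np.percentile(y, 95) - f0), 1e-9)
    half = f0 + a / 2.0
    above = np.nonzero(y >= half)[0]
    i = int(above[0]) if above.size else len(t) // 2
    tinf = float(t[i])
    # slope of the logistic at tinf is a*r/4
    j0, j1 = max(i - 1, 0), min(i + 1, len(t) - 1)
    slope = (y[j1] - y[j0]) / (t[j1] - t[j0]) if t[j1] > t[j0] else 0.0
    r = float(np.clip(4.0 * slope / a, 1e-3, 5.0))
    return f0, a, r, tinf


def fit_sigmoid(curve: AmplificationCurve) -> SigmoidFit:
    """Least-squares 4-parameter logistic fit with a deterministic retry.

    The amplification is called failed when the fitted rise realized inside
    the observed time window does not exceed 3x the residual standard
    deviation of the fit (a scale-free signal-to-noise rule), when the
    fitted inflection falls outside the observed window — the
    time-to-inflection is then not a measured quantity — or when the
    optimizer does not converge.
    """
    t, y = curve.times, curve.fluorescence
    t_range = float(t[-1] - t[0])
    p0 = _initial_guess(t, y)
    bounds = (
        [-np.inf, 0.0, 1e-6, t[0] - t_range],
        [np.inf, np.inf, np.inf, t[-1] + t_range],
    )
    popt, converged = None, False
    for attempt, guess in enumerate(
        (p0, (p0[0], p0[1] * 1.3 + 1.0, min(p0[2] * 2.0, 5.0), p0[3] * 0.7 + 1.0))
    ):
        guess = np.clip(guess, bounds[0], bounds[1])
        try:
            popt, _ = curve_fit(
                _logistic,
                t,
                y,
                p0=guess,
                bounds=bounds,
                maxfev=500,
                xtol=1e-8,
                ftol=1e-8,
                method="trf",
            )
            converged = True
            break
        except (RuntimeError, ValueError):
            continue
    if not converged:
        f0, a, r, tinf = p0
        rss = float(np.sum((y - y.mean()) ** 2))
        return SigmoidFit(curve.cell_id, f0, 0.0, r, tinf, rss, False, True)
    f0, a, r, tinf = (float(v) for v in popt)
    rss = float(np.sum((y - _logistic(t, *popt)) ** 2))
    resid_sd = math.sqrt(rss / max(t.size - 4, 1))
    a_observed = float(_logistic(t[-1], *popt) - _logistic(t[0], *popt))
    # noise floor keeps exactly-constant curves (resid_sd == 0 up to float
    # dust) classified as failed
    noise_floor = 1e-9 * max(1.0, float(np.max(np.abs(y))))
    failed = (
        a_observed <= 3.0 * resid_sd + noise_floor
        or not t[0] <= tinf <= t[-1]
    )
    return SigmoidFit(curve.cell_id, f0, a, r, tinf, rss, True, failed)


def cost_of(fit: SigmoidFit) -> float:
    """Time-to-inflection as the selection cost; +inf for failed wells."""
    if fit.failed_amplification or not fit.converged:
        return math.inf
    return fit.inflection


def costs_from_curves(curves_df: pd.DataFrame) -> pd.DataFrame:
    """Fit every cell in a long-form (cell_id, time_min, fluorescence) table.

    Returns one row per cell: cell_id, tinf, cost, failed, converged, rss.
    """
    required = {"cell_id", "time_min", "fluorescence"}
    if not required.issubset(curves_df.columns):
        raise ValueError(f"curves table must have columns {sorted(required)}")
    rows = []
    for cell_id, grp in curves_df.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_min")
        curve = AmplificationCurve(
            str(cell_id),
            grp["time_min"].to_numpy(float),
            grp["fluorescence"].to_numpy(float),
        )
        fit = fit_sigmoid(curve)
        rows.append(
            {
                "cell_id": curve.cell_id,
                "tinf": fit.inflection,
                "cost": cost_of(fit),
                "failed": fit.failed_amplification,
                "converged": fit.converged,
                "rss": fit.rss,
            }
        )
    return pd.DataFrame(rows)


def fit_calibration(
    fsc_values: Sequence[float], diameters: Sequence[float]
) -> CalibrationModel:
    """OLS of log10(D) on log10(FSC): log10(D) = a*log10(FSC) - b."""
    fsc = np.asarray(list(fsc_values), dtype=float)
    d = np.asarray(list(diameters), dtype=float)
    if fsc.size != d.size:
        raise ValueError("fsc_values and diameters must have equal length")
    if fsc.size < 2 or np.unique(fsc).size < 2:
        raise ValueError("need >= 2 distinct FSC values")
    if np.any(fsc <= 0) or np.any(d <= 0):
        raise ValueError("FSC and diameter values must be positive")
    x, y = np.log10(fsc), np.log10(d)
    a, c = np.polyfit(x, y, 1)
    resid = y - (a * x + c)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return CalibrationModel(a=float(a), b=float(-c), r_squared=r2)


def predict_diameter(model: CalibrationModel, fsc: float) -> float:
    """D = 10^(a*log10(FSC) - b)."""
    if fsc <= 0:
        raise ValueError("FSC must be positive")
    return float(10.0 ** (model.a * math.log10(fsc) - model.b))
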