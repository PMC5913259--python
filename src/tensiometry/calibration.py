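"""Calibration of squared wave speed against load, torque, or stress.

The tensioned-beam relation predicts that squared wave speed is affine in the
axial load, so ordinary least squares of c**2 on load (with binned summary
statistics) both validates the physics and provides a per-tendon calibration
that can be inverted into a tension estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .containers import SensorTrace
from .dsp import LOAD_LOWPASS, FilterSpec, zero_lag_filter
from .tensiometer import SpeedSeries

__all__ = [
    "CalibrationFit",
    "fit_speed2_vs_load",
    "torque_from_force",
    "rate_independence_test",
    "calibrate_tension",
]

EXVIVO_BINS = 15
INVIVO_BINS = 8


@dataclass
class CalibrationFit:
    """OLS fit of squared wave speed on load, with binned summaries.

    ``slope`` has units (m/s)**2 per load unit; bins are evenly spaced over
    the observed load range; empty bins carry NaN means/SDs.
    """

    slope: float
    intercept: float
    r2: float
    bin_centers: np.ndarray
    bin_means: np.ndarray
    bin_sds: np.ndarray
    bin_n: np.ndarray
    n_valid: int
    n_excluded: int
    load_quantity: str = ""
    meta: dict = field(default_factory=dict)

    def predict_speed2(self, load):
        return self.slope * np.asarray(load, dtype=float) + self.intercept

    def invert_load(self, speed2):
        """Load implied by a squared wave speed (inverse of the fit)."""
        return (np.asarray(speed2, dtype=float) - self.intercept) / self.slope


def fit_speed2_vs_load(speed: SpeedSeries, load: SensorTrace,
                       n_bins: int = EXVIVO_BINS,
                       lowpass_hz: float | None = LOAD_LOWPASS) -> CalibrationFit:
    """Ordinary least squares of squared wave speed on load.

    Both series are low-pass filtered (default 20 Hz, zero-lag; the speed
    series after linear interpolation across invalid taps) and the load is
    resampled onto the speed timestamps by linear interpolation.  Invalid
    speed samples are excluded from the fit, with the count reported.  Binned
    means and SDs of c**2 are computed over ``n_bins`` evenly spaced load
    bins spanning the observed range.
    """
    if len(speed) < 2:
        raise ValueError("speed series too short")
    rate = 1.0 / np.median(np.diff(speed.t))

    c = speed.speed.copy()
    valid = speed.valid & np.isfinite(c)
    if lowpass_hz is not None and lowpass_hz < rate / 2 and valid.sum() >= 2:
        idx = np.arange(c.size)
        filled = np.interp(idx, idx[valid], c[valid])
        tr = SensorTrace(filled, rate, "speed")
        c = zero_lag_filter(tr, FilterSpec("low", (lowpass_hz,))).data
    c2 = c**2

    load_f = load
    if lowpass_hz is not None and lowpass_hz < load.rate / 2:
        load_f = zero_lag_filter(load, FilterSpec("low", (lowpass_hz,)))
    x = load_f.sample_at(speed.t)

    xv, yv = x[valid], c2[valid]
    if xv.size < 10:
        raise ValueError(f"only {xv.size} valid speed/load pairs (need >= 10)")
    if np.ptp(xv) == 0:
        raise ValueError("constant load: degenerate regressor")

    res = stats.linregress(xv, yv)
    edges = np.linspace(xv.min(), xv.max(), n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.clip(np.digitize(xv, edges) - 1, 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    sds = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = which == b
        counts[b] = sel.sum()
        if counts[b]:
            means[b] = yv[sel].mean()
            sds[b] = yv[sel].std(ddof=1) if counts[b] > 1 else 0.0

    return CalibrationFit(float(res.slope), float(res.intercept),
                          float(res.rvalue**2), centers, means, sds, counts,
                          n_valid=int(xv.size),
                          n_excluded=int((~valid).sum()),
                          load_quantity=load.quantity)


def torque_from_force(force, lever: float):
    """Joint torque from a measured force and a fixed lever distance, N*m."""
    if lever <= 0:
        raise ValueError("lever distance must be positive")
    out = np.asarray(force, dtype=float) * lever
    return float(out) if out.ndim == 0 else out


def rate_independence_test(slopes: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures ANOVA on regression slopes across rates.

    ``slopes`` is a complete (n_specimens, n_rates) matrix of per-specimen
    calibration slopes at each loading rate.  Returns (F, p) for the
    within-subject rate effect; identical slopes across rates give F = 0,
    p = 1.
    """
    x = np.asarray(slopes, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a (>=2 specimens) x (>=2 rates) matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing cells in the slope matrix")
    n, k = x.shape
    grand = x.mean()
    ss_treat = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_treat - ss_subj
    df_treat = k - 1
    df_err = (k - 1) * (n - 1)
    ms_err = ss_err / df_err
    scale = max(ss_total, 1e-300)
    if ss_treat / scale < 1e-12:
        return 0.0, 1.0
    if ms_err <= 0:
        return float("inf"), 0.0
    f_stat = (ss_treat / df_treat) / ms_err
    p = float(stats.f.sf(f_stat, df_treat, df_err))
    return float(f_stat), p


def calibrate_tension(fit: CalibrationFit, moment_arm: float,
                      load_share: float = 1.0) -> Callable:
    """Tension estimator from a torque calibration: c**2 -> tendon tension (N).

    Inverts the c**2-on-torque fit to recover torque, then converts to tendon
    tension with the tendon's moment arm and the fraction of the joint torque
    carried by this tendon:

        T(c**2) = torque(c**2) * load_share / moment_arm

    When the fit was against tension directly, ``1/fit.slope`` recovers
    ``A * rho_eff`` (cross-checkable against physics.tension_from_speed).
    """
    if moment_arm <= 0:
        raise ValueError("moment_arm must be positive")
    if not 0 < load_share <= 1:
        raise ValueError("load_share must lie in (0, 1]")

    def tension(speed2):
        torque = fit.invert_load(speed2)
        return torque * load_share / moment_arm

    return tension
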