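"""Dual-accelerometer shear wave speed estimation (the tensiometer core).

Each tap launches a transient transverse wave that passes a near and a far
skin-mounted accelerometer in succession.  Per tap window the two signals are
shaped (mean-centred, normalized, sign-preserving squared), cross-correlated,
and the positive lag maximising the normalized cross-correlation — refined to
sub-sample precision by cosine interpolation — converts the fixed sensor
spacing into a wave speed: c = distance / lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .containers import SensorTrace
from .dsp import (FilterSpec, INVIVO_BAND, cosine_interp_peak, tap_windows,
                  zero_lag_filter)

__all__ = ["SpeedSeries", "preprocess_window", "intersensor_lag", "speed_series"]

DEFAULT_CORR_FLOOR = 0.6
SPEED_PLAUSIBILITY = (2.0, 200.0)
DEFAULT_DISTANCE = 10e-3  # Achilles spacing; patellar uses 8 mm


@dataclass
class SpeedSeries:
    """Per-tap wave-speed estimates on a common clock.

    Invalid taps (low correlation, boundary peak, implausible speed) are
    carried with ``valid = False`` and NaN speed — never silently dropped.
    ``freq`` is populated by the standing-wave pipeline instead of ``lag``.
    """

    t: np.ndarray
    speed: np.ndarray
    lag: np.ndarray
    corr: np.ndarray
    valid: np.ndarray
    freq: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        self.lag = np.asarray(self.lag, dtype=float)
        self.corr = np.asarray(self.corr, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)

    def __len__(self) -> int:
        return self.t.size

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time_s": self.t, "speed_mps": self.speed, "lag_s": self.lag,
            "corr": self.corr, "valid": self.valid.astype(int),
        })
        if self.freq is not None:
            df["freq_hz"] = self.freq
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpeedSeries":
        df = pd.read_csv(path)
        freq = df["freq_hz"].to_numpy() if "freq_hz" in df else None
        return cls(df["time_s"].to_numpy(), df["speed_mps"].to_numpy(),
                   df["lag_s"].to_numpy(), df["corr"].to_numpy(),
                   df["valid"].to_numpy().astype(bool), freq=freq)


def preprocess_window(window: np.ndarray) -> np.ndarray:
    """Shape a tap window to sharpen the arriving wavefront.

    Mean-centre, normalize to the maximum absolute magnitude, square to
    enhance peak magnitudes, and multiply by the sign of the centred signal to
    preserve the wave shape.  Output lies in [-1, 1] with at least one element
    of magnitude 1.  Raises on a constant window.
    """
    x = np.asarray(window, dtype=float)
    x = x - x.mean()
    peak = np.max(np.abs(x))
    if peak == 0:
        raise ValueError("constant window: nothing to shape")
    x = x / peak
    return np.sign(x) * x**2


class LagEstimate(NamedTuple):
    lag_s: float
    corr: float
    valid: bool
    fallback: bool


def intersensor_lag(w_near: np.ndarray, w_far: np.ndarray, rate: float,
                    corr_floor: float = DEFAULT_CORR_FLOOR,
                    max_lag: int | None = None) -> LagEstimate:
    """Wave travel time between two shaped windows on a shared clock.

    Full normalized cross-correlation over lags, integer argmax restricted to
    positive lags (the wave travels near -> far), cosine sub-sample
    refinement.  The estimate is invalid when the peak correlation falls below
    ``corr_floor`` or the argmax sits on the search boundary.
    """
    a = np.asarray(w_near, dtype=float)
    b = np.asarray(w_far, dtype=float)
    if a.size != b.size:
        raise ValueError("windows must have equal length")
    n = a.size
    norm = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if norm == 0:
        return LagEstimate(np.nan, 0.0, False, False)
    r_full = np.correlate(b, a, mode="full") / norm  # index n-1+k is lag k
    if max_lag is None:
        max_lag = n - 1
    max_lag = min(max_lag, n - 1)
    lags = np.arange(1, max_lag + 1)
    r_pos = r_full[n - 1 + 1:n - 1 + max_lag + 1]
    k = int(np.argmax(r_pos))
    peak = float(r_pos[k])
    lag_int = int(lags[k])
    boundary = k == 0 or k == r_pos.size - 1
    if peak < corr_floor or boundary:
        return LagEstimate(np.nan, peak, False, False)
    ym, y0, yp = (r_full[n - 1 + lag_int - 1], r_full[n - 1 + lag_int],
                  r_full[n - 1 + lag_int + 1])
    delta, fallback = cosine_interp_peak(ym, y0, yp)
    return LagEstimate((lag_int + delta) / rate, peak, True, fallback)


def _half_taper(n: int) -> np.ndarray:
    """Unity over the first half of the window, raised-cosine roll-off after.

    De-emphasises late-window content (e.g. actuator retraction transients)
    while leaving the arriving wavefront untouched.
    """
    w = np.ones(n)
    h = n // 2
    k = np.arange(n - h)
    w[h:] = 0.5 * (1 + np.cos(np.pi * k / max(n - h - 1, 1)))
    return w


def speed_series(near: SensorTrace, far: SensorTrace, trigger: SensorTrace,
                 distance: float = DEFAULT_DISTANCE,
                 band: tuple = INVIVO_BAND,
                 window_len: int | None = None,
                 corr_floor: float = DEFAULT_CORR_FLOOR,
                 speed_band: tuple = SPEED_PLAUSIBILITY,
                 taper: bool = True) -> SpeedSeries:
    """Per-tap wave speeds from a near/far accelerometer pair.

    Both traces are band-pass filtered (default 150-1000 Hz, zero-lag),
    segmented into tap windows off the trigger's leading edges (default 20 ms),
    shaped, and cross-correlated; speed = ``distance`` / lag.  Speeds outside
    ``speed_band`` are flagged invalid but retained.
    """
    if near.rate != far.rate:
        raise ValueError("near and far traces must share a sampling rate")
    if distance <= 0:
        raise ValueError("sensor distance must be positive")
    spec = FilterSpec("band", tuple(band))
    near_f = zero_lag_filter(near, spec)
    far_f = zero_lag_filter(far, spec)
    win_near = tap_windows(near_f, trigger, window_len)
    win_far = tap_windows(far_f, trigger, window_len)
    n_win = min(len(win_near), len(win_far))

    t = np.zeros(n_win)
    speed = np.full(n_win, np.nan)
    lag = np.full(n_win, np.nan)
    corr = np.zeros(n_win)
    valid = np.zeros(n_win, dtype=bool)
    # lag search capped by the slowest plausible wave
    max_lag = int(np.ceil(distance / speed_band[0] * near.rate))

    for i in range(n_win):
        t[i] = win_near[i].start_time
        wn, wf = win_near[i].samples, win_far[i].samples
        if taper:
            tap_w = _half_taper(wn.size)
            wn, wf = wn * tap_w, wf * tap_w
        try:
            wn = preprocess_window(wn)
            wf = preprocess_window(wf)
        except ValueError:
            continue
        est = intersensor_lag(wn, wf, near.rate, corr_floor, max_lag)
        corr[i] = est.corr
        if not est.valid:
            continue
        lag[i] = est.lag_s
        c = distance / est.lag_s
        speed[i] = c
        valid[i] = speed_band[0] <= c <= speed_band[1]

    return SpeedSeries(t, speed, lag, corr, valid,
                       meta={"distance_m": distance, "band_hz": tuple(band)})
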