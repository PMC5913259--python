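"""Signal-processing primitives shared by the wave-speed pipelines.

Zero-phase Butterworth filtering, tap-window segmentation off a trigger
channel, spectral peak estimation, and cosine sub-sample interpolation of
cross-correlation peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import signal

from .containers import SensorTrace

__all__ = [
    "FilterSpec",
    "zero_lag_filter",
    "tap_windows",
    "TapWindow",
    "spectral_peak_frequency",
    "cosine_interp_peak",
    "SubSampleOffset",
]

log = logging.getLogger(__name__)

# Filter presets used by the pipelines (Hz).
EXVIVO_BAND = (50.0, 2000.0)
INVIVO_BAND = (150.0, 1000.0)
LOAD_LOWPASS = 20.0


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth design applied forward-backward (zero phase).

    ``order`` is the order of the one-pass design; the bidirectional
    application doubles the effective magnitude order.  ``corners`` is a
    single corner for ``kind="low"`` or a (low, high) pair for
    ``kind="band"``.
    """

    kind: str
    corners: tuple
    order: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("band", "low"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        corners = np.atleast_1d(self.corners)
        if self.kind == "band" and corners.size != 2:
            raise ValueError("band filter needs (low, high) corners")
        if np.any(corners <= 0):
            raise ValueError("corners must be positive")


def _sos(spec: FilterSpec, rate: float):
    nyq = rate / 2.0
    corners = np.atleast_1d(spec.corners).astype(float)
    if np.any(corners >= nyq):
        raise ValueError(
            f"filter corners {tuple(corners)} Hz must lie below the Nyquist "
            f"frequency {nyq} Hz"
        )
    if spec.kind == "band":
        return signal.butter(spec.order, corners / nyq, btype="bandpass",
                             output="sos")
    return signal.butter(spec.order, corners[0] / nyq, btype="lowpass",
                         output="sos")


def zero_lag_filter(trace: SensorTrace, spec: FilterSpec) -> SensorTrace:
    """Forward-backward (zero-phase) Butterworth filter of a trace.

    Edge transients are controlled with reflective ("even") padding.  A
    band-pass removes DC exactly; output length equals input length.
    """
    sos = _sos(spec, trace.rate)
    # reflective padding: a few characteristic lengths of the slowest corner
    corners = np.atleast_1d(spec.corners).astype(float)
    settle = int(3 * trace.rate / corners.min())
    padlen = min(trace.data.size - 1, max(settle, 3 * (2 * spec.order + 1)))
    if trace.data.size <= 3 * (2 * spec.order + 1):
        raise ValueError("trace too short to filter")
    out = signal.sosfiltfilt(sos, trace.data, padtype="even", padlen=padlen)
    return trace.with_data(out)


class TapWindow(NamedTuple):
    """One tap-aligned analysis window."""

    start_time: float
    start_index: int
    samples: np.ndarray


def trigger_edges(trigger: SensorTrace) -> np.ndarray:
    """Times of rising crossings of 50% of the trigger amplitude."""
    x = trigger.data
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        return np.array([])
    thr = 0.5 * (lo + hi)
    above = x >= thr
    idx = np.flatnonzero(~above[:-1] & above[1:]) + 1
    return trigger.t0 + idx / trigger.rate


def tap_windows(trace: SensorTrace, trigger: SensorTrace,
                window_len: int | None = None) -> list[TapWindow]:
    """Segment a trace into windows starting at each trigger leading edge.

    The trigger and trace must share a time origin; they may be sampled at
    different rates (edge times are mapped onto the trace's sample grid).
    Windows that would run past the end of the trace are discarded.  Default
    window length is 20 ms of the trace's rate (1000 samples at 50 kHz).
    """
    if window_len is None:
        window_len = int(round(0.02 * trace.rate))
    edges = trigger_edges(trigger)
    if edges.size == 0:
        log.warning("tap_windows: no trigger edges found")
        return []
    out: list[TapWindow] = []
    for t_edge in edges:
        i0 = int(round((t_edge - trace.t0) * trace.rate))
        if i0 < 0 or i0 + window_len > trace.data.size:
            continue
        out.append(TapWindow(trace.t0 + i0 / trace.rate, i0,
                             trace.data[i0:i0 + window_len]))
    return out


def spectral_peak_frequency(window: np.ndarray, rate: float) -> float:
    """Frequency of the magnitude-spectrum maximum of a tap window, Hz.

    The mean is removed, a Hann window applied to control leakage, and the
    FFT zero-padded by a factor of 4; the peak bin is refined by parabolic
    interpolation over its two neighbours.
    """
    x = np.asarray(window, dtype=float)
    if x.size < 64:
        raise ValueError("window too short for spectral estimation (< 64 samples)")
    x = x - x.mean()
    if np.allclose(x, 0.0):
        raise ValueError("no dominant frequency: constant input")
    n_fft = 4 * x.size
    spec = np.abs(np.fft.rfft(x * np.hanning(x.size), n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    # exclude near-DC bins blurred by the Hann mainlobe
    guard = 8  # 2 original bins * padding factor
    k = guard + int(np.argmax(spec[guard:]))
    if spec[k] <= 0:
        raise ValueError("no dominant frequency: flat spectrum")
    if 0 < k < spec.size - 1:
        ym, y0, yp = spec[k - 1], spec[k], spec[k + 1]
        denom = ym - 2 * y0 + yp
        delta = 0.0 if denom == 0 else 0.5 * (ym - yp) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return float((k + delta) * freqs[1])


class SubSampleOffset(NamedTuple):
    """Sub-sample peak offset and whether the parabolic fallback was used."""

    delta: float
    fallback: bool


def cosine_interp_peak(y_minus: float, y_zero: float,
                       y_plus: float) -> SubSampleOffset:
    """Sub-sample offset of a correlation peak from three samples.

    Models the correlation near its peak as a sampled cosine
    ``y(k) = A*cos(omega*(k - delta))``:

        omega = arccos((y- + y+) / (2*y0))
        theta = arctan((y- - y+) / (2*y0*sin(omega)))
        delta = -theta / omega

    Exact for pure-cosine correlation functions.  When the cosine model is
    infeasible (|arccos argument| >= 1) the standard parabolic vertex is used
    and flagged.
    """
    if y_zero == 0:
        raise ValueError("y_zero must be non-zero")
    arg = (y_minus + y_plus) / (2.0 * y_zero)
    if abs(arg) >= 1.0:
        denom = y_minus - 2.0 * y_zero + y_plus
        delta = 0.0 if denom == 0 else 0.5 * (y_minus - y_plus) / denom
        return SubSampleOffset(float(np.clip(delta, -1.0, 1.0)), True)
    omega = np.arccos(arg)
    theta = np.arctan((y_minus - y_plus) / (2.0 * y_zero * np.sin(omega)))
    return SubSampleOffset(float(-theta / omega), False)
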