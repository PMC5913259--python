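"""Ex vivo standing-wave wave-speed pipeline.

On a gripped (fixed-fixed) tendon each tap rings an underdamped standing wave.
The fundamental has wavelength twice the grip-to-grip length, so the wave
speed follows from the dominant vibration frequency: c = 2*f*L.  Kernel
velocities from speckle tracking are band-pass filtered, aggregated across
kernels, segmented per tap, and the spectral peak of each tap window yields
one speed estimate.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import SensorTrace
from .dsp import (EXVIVO_BAND, FilterSpec, spectral_peak_frequency,
                  tap_windows, zero_lag_filter)
from .physics import BeamSpec, standing_wave_speed
from .speckle import KernelTrack
from .tensiometer import SpeedSeries

__all__ = ["exvivo_speed_series"]

log = logging.getLogger(__name__)

#: warn when the second spectral peak reaches this fraction of the first
MODE_CONTAMINATION_RATIO = 0.8


def _second_peak_ratio(window: np.ndarray, rate: float, f_peak: float) -> float:
    """Amplitude ratio of the strongest spectral peak away from f_peak."""
    x = window - window.mean()
    n_fft = 4 * x.size
    spec = np.abs(np.fft.rfft(x * np.hanning(x.size), n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    main = spec.max()
    if main == 0:
        return 0.0
    # exclude the mainlobe neighbourhood of the primary peak and DC
    df = 2.0 * rate / x.size  # Hann mainlobe half-width
    mask = (np.abs(freqs - f_peak) > df) & (freqs > df)
    return float(spec[mask].max() / main) if mask.any() else 0.0


def exvivo_speed_series(track, trigger: SensorTrace,
                        beam: BeamSpec, band: tuple = EXVIVO_BAND,
                        window_len: int | None = None,
                        apply_filter: bool = True) -> SpeedSeries:
    """Per-tap standing-wave speed estimates from tracked kernel velocities.

    ``track`` is a :class:`~tensiometry.speckle.KernelTrack` (kernel
    velocities are reduced to one trace by the median across kernels, robust
    to edge kernels) or a velocity :class:`~tensiometry.containers.SensorTrace`
    measured directly.  The trace is band-pass filtered (default 50-2000 Hz,
    zero-lag) and windowed at each trigger leading edge (default: one
    inter-tap interval).  Per window the FFT peak frequency gives
    ``c = 2*f*L``.  Windows with no dominant frequency are flagged invalid;
    ``corr`` carries one minus the second-peak contamination ratio as a
    quality score, and possible higher-mode contamination is logged.
    """
    if isinstance(track, SensorTrace):
        v, frame_rate = track.data, track.rate
    elif isinstance(track, KernelTrack):
        v, frame_rate = track.median_velocity(), track.frame_rate
    else:
        raise TypeError("track must be a KernelTrack or a SensorTrace")
    good = np.isfinite(v)
    if not good.all():
        idx = np.arange(v.size)
        if good.sum() < 2:
            raise ValueError("kernel track has too few valid velocity samples")
        v = np.interp(idx, idx[good], v[good])
    vtrace = SensorTrace(v, frame_rate, "velocity")
    if apply_filter:
        vtrace = zero_lag_filter(vtrace, FilterSpec("band", tuple(band)))

    if window_len is None:
        # one inter-tap interval: the standing wave rings down between taps,
        # and the full interval gives the best frequency resolution
        from .dsp import trigger_edges
        edges = trigger_edges(trigger)
        if edges.size >= 2:
            window_len = int(round(float(np.median(np.diff(edges)))
                                   * vtrace.rate))
    windows = tap_windows(vtrace, trigger, window_len)
    n = len(windows)
    t = np.zeros(n)
    speed = np.full(n, np.nan)
    freq = np.full(n, np.nan)
    lag = np.full(n, np.nan)
    quality = np.zeros(n)
    valid = np.zeros(n, dtype=bool)

    for i, win in enumerate(windows):
        t[i] = win.start_time
        try:
            f = spectral_peak_frequency(win.samples, vtrace.rate)
        except ValueError:
            continue
        ratio = _second_peak_ratio(win.samples, vtrace.rate, f)
        if ratio > MODE_CONTAMINATION_RATIO:
            log.warning(
                "tap %d: second spectral peak at %.0f%% of the first - "
                "possible higher-mode contamination", i, 100 * ratio)
        freq[i] = f
        speed[i] = standing_wave_speed(f, beam.length)
        quality[i] = 1.0 - ratio
        valid[i] = True

    return SpeedSeries(t, speed, lag, quality, valid, freq=freq,
                       meta={"length_m": beam.length, "band_hz": tuple(band)})
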