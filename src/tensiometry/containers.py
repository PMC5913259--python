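"""Shared in-memory containers for uniformly sampled sensor data."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["SensorTrace"]


@dataclass
class SensorTrace:
    """A uniformly sampled single-channel time series.

    Parameters
    ----------
    data:
        Sample values in SI units for the tagged quantity.
    rate:
        Sampling rate in Hz.
    quantity:
        Physical quantity tag, e.g. ``"displacement"``, ``"velocity"``,
        ``"acceleration"``, ``"force"``, ``"torque"``, ``"stress"``,
        ``"trigger"``.
    position:
        Axial position of the sensor along the beam in metres, if applicable.
    t0:
        Time of the first sample in seconds (shared clock across traces).
    """

    data: np.ndarray
    rate: float
    quantity: str = ""
    position: float | None = None
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("SensorTrace data must be one-dimensional")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.size) / self.rate

    @property
    def duration(self) -> float:
        return self.data.size / self.rate

    def __len__(self) -> int:
        return self.data.size

    def with_data(self, data: np.ndarray, quantity: str | None = None) -> "SensorTrace":
        """Copy of the trace with new samples (same clock and rate)."""
        out = replace(self, data=np.asarray(data, dtype=float))
        if quantity is not None:
            out.quantity = quantity
        return out

    def sample_at(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation of the trace at arbitrary times."""
        return np.interp(t, self.times, self.data)
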