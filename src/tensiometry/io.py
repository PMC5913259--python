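"""File formats and configuration.

SensorTrace round-trips through CSV with ``# key: value`` metadata header
lines followed by ``time_s,value`` rows; RF sequences use an HDF5 container
(see :class:`tensiometry.synthetic.RFSequence`).  Run configuration is a YAML
file with ``beam``, ``material``, ``taps`` and ``seed`` blocks; unknown keys
are rejected.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import yaml

from .constitutive import MaterialParams
from .containers import SensorTrace
from .physics import BeamSpec
from .synthetic import TapTrain

__all__ = ["read_trace", "write_trace", "load_config", "RunConfig"]

_JITTER_TOL = 1e-6  # relative non-uniformity allowed in sample spacing


def write_trace(path, trace: SensorTrace) -> None:
    """Write a trace as CSV with metadata header lines."""
    with open(path, "w") as fh:
        # repr of builtin floats is the shortest round-trippable decimal;
        # numpy scalars repr as "np.float64(...)", so cast first
        fh.write(f"# rate_hz: {float(trace.rate)!r}\n")
        fh.write(f"# quantity: {trace.quantity}\n")
        if trace.position is not None:
            fh.write(f"# position_m: {float(trace.position)!r}\n")
        fh.write(f"# t0_s: {float(trace.t0)!r}\n")
        fh.write("time_s,value\n")
        t = trace.times
        for ti, vi in zip(t, trace.data):
            fh.write(f"{float(ti)!r},{float(vi)!r}\n")


def read_trace(path) -> SensorTrace:
    """Read a trace CSV; infers and cross-checks the sampling rate.

    Raises when the time column is non-monotone or non-uniform beyond 1 ppm
    jitter, or when the header rate disagrees with the inferred rate.
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            line = fh.readline()
        if not line.startswith("time_s"):
            raise ValueError(f"{path}: expected a 'time_s,value' header row")
        body = fh.read()
    arr = np.loadtxt(_io.StringIO(body), delimiter=",", ndmin=2)
    if arr.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns")
    t, v = arr[:, 0], arr[:, 1]
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    dt_med = np.median(dt)
    if np.max(np.abs(dt - dt_med)) > _JITTER_TOL * dt_med:
        raise ValueError(f"{path}: non-uniform sampling beyond 1 ppm jitter")
    rate = 1.0 / dt_med
    if "rate_hz" in meta:
        header_rate = float(meta["rate_hz"])
        if abs(header_rate - rate) > _JITTER_TOL * header_rate:
            raise ValueError(
                f"{path}: header rate {header_rate} Hz disagrees with the "
                f"inferred rate {rate} Hz")
        rate = header_rate
    position = float(meta["position_m"]) if "position_m" in meta else None
    t0 = float(meta["t0_s"]) if "t0_s" in meta else float(t[0])
    return SensorTrace(v, rate, meta.get("quantity", ""), position, t0)


_BEAM_KEYS = {"rho_eff", "mu", "k_shear", "area", "length"}
_MATERIAL_KEYS = {"c1", "c2", "c3", "c4", "c5", "lambda_star", "bulk"}
_TAP_KEYS = {"rate", "pulse_width", "amplitude", "mode"}
_FILTER_KEYS = {"kind", "corners", "order"}
_TOP_KEYS = {"beam", "material", "taps", "filters", "seed"}


class RunConfig:
    """Validated run configuration (beam, material, taps, filters, seed)."""

    def __init__(self, beam: BeamSpec | None = None,
                 material: MaterialParams | None = None,
                 taps: TapTrain | None = None,
                 filters: dict | None = None, seed: int | None = None):
        self.beam = beam
        self.material = material
        self.taps = taps
        self.filters = filters or {}
        self.seed = seed


def _check_keys(block: dict, allowed: set, name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {name} config: {sorted(unknown)}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top-level")
    beam = material = taps = None
    if "beam" in raw:
        _check_keys(raw["beam"], _BEAM_KEYS, "beam")
        beam = BeamSpec(**raw["beam"])
    if "material" in raw:
        _check_keys(raw["material"], _MATERIAL_KEYS, "material")
        material = MaterialParams(**raw["material"])
    if "taps" in raw:
        _check_keys(raw["taps"], _TAP_KEYS, "taps")
        taps = TapTrain(**raw["taps"])
    filters = {}
    for fname, fblock in (raw.get("filters") or {}).items():
        _check_keys(fblock, _FILTER_KEYS, f"filters.{fname}")
        filters[fname] = dict(fblock)
    seed = raw.get("seed")
    if seed is not None:
        seed = int(seed)
    return RunConfig(beam, material, taps, filters, seed)
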