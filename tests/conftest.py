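"""Shared fixtures: expensive simulations reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from tensiometry.physics import INVIVO_BEAM, stress_from_speed
from tensiometry.synthetic import (DEFAULT_SEED, SKIN_TAP_AMPLITUDE, TapTrain,
                                   load_profile, simulate_beam_wave,
                                   synthesize_rf)
from tensiometry.containers import SensorTrace

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

#: in vivo tap train used by the recovery and gait simulations
INVIVO_TAPS = TapTrain(rate=50.0, amplitude=SKIN_TAP_AMPLITUDE)
SENSORS = (0.04, 0.05)
SENSOR_DISTANCE = 0.01


@pytest.fixture(scope="session")
def recovery_sims():
    """Noiseless absorbing-end simulations at the four in vivo speeds."""
    out = {}
    for c_true in (15.0, 30.0, 50.0, 80.0):
        sigma = stress_from_speed(INVIVO_BEAM, c_true).sigma
        out[c_true] = simulate_beam_wave(
            INVIVO_BEAM, sigma, INVIVO_TAPS, list(SENSORS), "absorbing",
            duration=0.5)
    return out


@pytest.fixture(scope="session")
def cyclic_sim():
    """Noiseless in vivo simulation under a cyclic 10-300 N load."""
    prof = load_profile("cyclic", duration=2.0, rate=2000.0,
                        area=INVIVO_BEAM.area)
    sim = simulate_beam_wave(INVIVO_BEAM, prof.stress_fn, INVIVO_TAPS,
                             list(SENSORS), "absorbing", duration=2.0)
    return prof, sim


@pytest.fixture(scope="session")
def gait_sim():
    """Noiseless gait-profile simulation with enough strides to ensemble."""
    prof = load_profile("gait", duration=5.0, rate=2000.0)
    sim = simulate_beam_wave(INVIVO_BEAM, prof.stress_fn, INVIVO_TAPS,
                             list(SENSORS), "absorbing", duration=5.0)
    return prof, sim


@pytest.fixture(scope="session")
def rf_sine():
    """RF sequence for an imposed 10 um, 300 Hz sinusoidal motion."""
    from tensiometry.synthetic import RF_FRAME_RATE

    n = int(0.05 * RF_FRAME_RATE)
    t = np.arange(n) / RF_FRAME_RATE
    disp = 10e-6 * np.sin(2 * np.pi * 300.0 * t)
    motion = SensorTrace(disp, RF_FRAME_RATE, "displacement")
    return motion, synthesize_rf(motion, seed=DEFAULT_SEED)
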