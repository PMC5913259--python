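"""Finite-difference wave simulator, RF/accelerometer synthesis, load profiles."""

import numpy as np
import pytest

from tensiometry.containers import SensorTrace
from tensiometry.physics import EXVIVO_BEAM, INVIVO_BEAM, BeamSpec, wave_speed
from tensiometry.synthetic import (DEFAULT_SEED, SKIN_TAP_AMPLITUDE,
                                   RFSequence, TapTrain,
                                   load_profile, simulate_beam_wave,
                                   synthesize_accel, synthesize_rf)


class TestTapTrain:
    def test_onsets_start_one_period_in(self):
        taps = TapTrain(rate=25.0)
        onsets = taps.onset_times(0.5)
        assert onsets[0] == pytest.approx(0.04)
        assert np.allclose(np.diff(onsets), 0.04)

    def test_trigger_high_during_pulse(self):
        taps = TapTrain(rate=25.0, pulse_width=1e-3)
        trig = taps.trigger_trace(0.2, 50000.0)
        t = trig.times
        active = trig.data > 0.5
        assert active[(t >= 0.0401) & (t < 0.0405)].all()
        assert not active[t < 0.0399].any()

    @pytest.mark.parametrize("kwargs", [
        {"rate": 0.0}, {"pulse_width": 0.0},
        {"rate": 25.0, "pulse_width": 0.05}, {"mode": "sideways"},
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            TapTrain(**kwargs)


class TestSimulateBeamWave:
    def test_no_tap_zero_field(self):
        taps = TapTrain(rate=25.0)  # first onset at 40 ms > duration
        sim = simulate_beam_wave(EXVIVO_BEAM, 5e6, taps, [0.05],
                                 "fixed-fixed", duration=0.02)
        assert np.allclose(sim.displacement[0].data, 0.0)
        assert np.allclose(sim.field.w, 0.0)

    def test_fundamental_frequency_matches_analytic(self):
        from tensiometry.dsp import spectral_peak_frequency, tap_windows

        sigma = 5e6
        taps = TapTrain(rate=12.5)
        sim = simulate_beam_wave(EXVIVO_BEAM, sigma, taps, [0.05],
                                 "fixed-fixed", duration=0.25)
        v = sim.velocity[0]
        wins = tap_windows(v, sim.trigger,
                           window_len=int(round(0.08 * v.rate)))
        f = spectral_peak_frequency(wins[0].samples, v.rate)
        f_true = wave_speed(EXVIVO_BEAM, sigma) / (2 * EXVIVO_BEAM.length)
        assert f == pytest.approx(f_true, rel=0.02)

    def test_arrival_lag_125us(self):
        """Absorbing ends, sensors 10 mm apart, c = 80 m/s -> lag 125 us."""
        from tensiometry.physics import stress_from_speed

        sigma = stress_from_speed(INVIVO_BEAM, 80.0).sigma
        taps = TapTrain(rate=50.0, amplitude=SKIN_TAP_AMPLITUDE)
        sim = simulate_beam_wave(INVIVO_BEAM, sigma, taps, [0.04, 0.05],
                                 "absorbing", duration=0.06)
        near, far = sim.acceleration
        t = near.times
        sel = (t > 0.020) & (t < 0.040)
        a, b = near.data[sel], far.data[sel]
        xc = np.correlate(b - b.mean(), a - a.mean(), mode="full")
        lag = (np.argmax(xc) - (a.size - 1)) / near.rate
        assert lag == pytest.approx(125e-6, abs=1.0 / near.rate)

    def test_grid_convergence_of_lag(self):
        """Halving dx changes the measured arrival lag by < 0.5%."""
        from tensiometry.physics import stress_from_speed
        from tensiometry.tensiometer import speed_series

        sigma = stress_from_speed(INVIVO_BEAM, 50.0).sigma
        taps = TapTrain(rate=50.0, amplitude=SKIN_TAP_AMPLITUDE)
        lags = []
        for dx in (INVIVO_BEAM.length / 300, INVIVO_BEAM.length / 600):
            sim = simulate_beam_wave(INVIVO_BEAM, sigma, taps, [0.04, 0.05],
                                     "absorbing", duration=0.1, dx=dx)
            sp = speed_series(sim.acceleration[0], sim.acceleration[1],
                              sim.trigger, distance=0.01)
            lags.append(np.nanmedian(sp.lag[sp.valid]))
        assert abs(lags[1] - lags[0]) / lags[0] < 0.005

    def test_fixed_ends_stay_zero(self):
        sim = simulate_beam_wave(EXVIVO_BEAM, 5e6, TapTrain(rate=25.0),
                                 [0.05], "fixed-fixed", duration=0.1)
        assert np.allclose(sim.field.w[:, 0], 0.0)
        assert np.allclose(sim.field.w[:, -1], 0.0)

    def test_cfl_violation_names_grid(self):
        with pytest.raises(ValueError, match="CFL"):
            simulate_beam_wave(EXVIVO_BEAM, 5e6, TapTrain(rate=25.0),
                               [0.05], "fixed-fixed", duration=0.1,
                               dx=1e-3, dt=1e-4)

    def test_sensor_outside_beam_rejected(self):
        with pytest.raises(ValueError, match="sensor"):
            simulate_beam_wave(EXVIVO_BEAM, 5e6, TapTrain(rate=25.0),
                               [0.2], "fixed-fixed", duration=0.1)

    def test_unknown_boundary_rejected(self):
        with pytest.raises(ValueError, match="boundary"):
            simulate_beam_wave(EXVIVO_BEAM, 5e6, TapTrain(rate=25.0),
                               [0.05], "periodic", duration=0.1)

    def test_kelvin_voigt_requires_fixed_ends(self):
        with pytest.raises(ValueError, match="fixed-fixed"):
            simulate_beam_wave(EXVIVO_BEAM, 5e6, TapTrain(rate=25.0),
                               [0.05], "absorbing", duration=0.1,
                               kelvin_voigt=0.05)

    def test_deterministic(self):
        kwargs = dict(stress=5e6, taps=TapTrain(rate=25.0),
                      sensor_positions=[0.05], boundary="fixed-fixed",
                      duration=0.1)
        a = simulate_beam_wave(EXVIVO_BEAM, **kwargs)
        b = simulate_beam_wave(EXVIVO_BEAM, **kwargs)
        assert np.array_equal(a.displacement[0].data, b.displacement[0].data)


class TestSynthesizeRF:
    def test_zero_motion_identical_frames(self):
        motion = SensorTrace(np.zeros(20), 14100.0, "displacement")
        rf = synthesize_rf(motion, seed=DEFAULT_SEED)
        assert np.array_equal(rf.data, np.broadcast_to(rf.data[0],
                                                       rf.data.shape))

    def test_same_seed_same_sequence(self):
        motion = SensorTrace(np.linspace(0, 5e-6, 10), 14100.0,
                             "displacement")
        a = synthesize_rf(motion, seed=7)
        b = synthesize_rf(motion, seed=7)
        assert np.array_equal(a.data, b.data)
        c = synthesize_rf(motion, seed=8)
        assert not np.array_equal(a.data, c.data)

    def test_depth_increment(self):
        motion = SensorTrace(np.zeros(2), 14100.0, "displacement")
        rf = synthesize_rf(motion, seed=0)
        assert rf.depth_increment == pytest.approx(1560.0 / (2 * 40e6),
                                                   rel=1e-12)

    def test_excess_displacement_rejected(self):
        motion = SensorTrace([0.0, 2e-3], 14100.0, "displacement")
        with pytest.raises(ValueError, match="depth window"):
            synthesize_rf(motion, seed=0)

    def test_hdf5_round_trip(self, tmp_path):
        motion = SensorTrace(np.linspace(0, 5e-6, 5), 14100.0,
                             "displacement")
        rf = synthesize_rf(motion, seed=11)
        path = tmp_path / "rf.h5"
        rf.to_hdf5(path)
        back = RFSequence.from_hdf5(path)
        assert np.array_equal(back.data, rf.data)
        assert back.frame_rate == rf.frame_rate
        assert back.seed == 11


class TestSynthesizeAccel:
    def _trace(self, n=100000):
        t = np.arange(n) / 50000.0
        return SensorTrace(np.sin(2 * np.pi * 300 * t), 50000.0,
                           "acceleration")

    def test_zero_noise_identity(self):
        tr = self._trace(1000)
        out = synthesize_accel(tr, 0.0, seed=1)
        assert np.array_equal(out.data, tr.data)

    def test_noise_rms_fraction(self):
        tr = self._trace()
        out = synthesize_accel(tr, 0.1, seed=3)
        noise = out.data - tr.data
        ratio = np.sqrt(np.mean(noise**2)) / np.sqrt(np.mean(tr.data**2))
        assert ratio == pytest.approx(0.1, rel=0.05)

    def test_seeded_reproducibility(self):
        tr = self._trace(1000)
        a = synthesize_accel(tr, 0.1, seed=5)
        b = synthesize_accel(tr, 0.1, seed=5)
        assert np.array_equal(a.data, b.data)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            synthesize_accel(self._trace(100), -0.1)


class TestLoadProfile:
    def test_cyclic_bounds(self):
        prof = load_profile("cyclic", duration=3.0)
        f = prof.force.data
        assert f.min() == pytest.approx(10.0, abs=1e-6)
        assert f.max() == pytest.approx(300.0, abs=1e-6)

    def test_stress_is_force_over_area(self):
        prof = load_profile("cyclic", duration=1.0, area=22.6e-6)
        assert prof.stress.data.max() == pytest.approx(300.0 / 22.6e-6,
                                                       rel=1e-9)
        assert prof.stress.data.max() == pytest.approx(13.3e6, rel=0.01)

    def test_gait_two_peaks_stance_larger(self):
        from scipy.signal import argrelmax

        prof = load_profile("gait", duration=1.1, rate=2000.0,
                            stride_time=1.1)
        sigma = prof.stress.data
        peaks = argrelmax(sigma, order=20, mode="wrap")[0]
        assert peaks.size == 2
        vals = np.sort(sigma[peaks])
        assert vals[1] > 2 * vals[0]  # stance clearly dominates

    def test_gait_grf_single_onset_per_stride(self):
        prof = load_profile("gait", duration=5.0, rate=2000.0)
        g = prof.grf.data
        above = g >= 20.0
        onsets = np.flatnonzero(~above[:-1] & above[1:])
        # stance begins once per stride; five stance onsets fall inside 5 s
        assert onsets.size == 5
        assert np.allclose(np.diff(onsets) / 2000.0, 1.1, atol=0.01)

    def test_isometric_torque_range(self):
        prof = load_profile("isometric", duration=4.0)
        tq = prof.torque.data
        assert tq.min() == pytest.approx(2.0, abs=1e-6)
        assert tq.max() == pytest.approx(45.0, abs=1e-6)

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown"):
            load_profile("ballistic")

    def test_unknown_params_rejected(self):
        with pytest.raises(TypeError, match="unknown"):
            load_profile("cyclic", wavelength=3.0)
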