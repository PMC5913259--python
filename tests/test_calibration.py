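"""Squared-speed-versus-load calibration and rate-independence statistics."""

import numpy as np
import pytest

from tensiometry.calibration import (calibrate_tension, fit_speed2_vs_load,
                                     rate_independence_test,
                                     torque_from_force)
from tensiometry.containers import SensorTrace
from tensiometry.physics import INVIVO_BEAM, wave_speed
from tensiometry.tensiometer import SpeedSeries


def _series_from_load(force, rate, beam=INVIVO_BEAM, noise=0.0, seed=0):
    """SpeedSeries generated analytically from a force trace."""
    sigma = force / beam.area
    c = wave_speed(beam, sigma)
    if noise:
        rng = np.random.default_rng(seed)
        c = c * (1.0 + noise * rng.standard_normal(c.size))
    n = c.size
    t = np.arange(n) / rate
    return SpeedSeries(t, c, np.full(n, np.nan), np.ones(n),
                       np.ones(n, dtype=bool))


def _cyclic_force(duration=10.0, rate=50.0, f_lo=10.0, f_hi=300.0):
    t = np.arange(int(duration * rate)) / rate
    force = f_lo + (f_hi - f_lo) * 0.5 * (1 - np.cos(2 * np.pi * 1.0 * t))
    return SensorTrace(force, rate, "force")


class TestFitSpeed2VsLoad:
    def test_noiseless_fit_is_exact(self):
        load = _cyclic_force()
        sp = _series_from_load(load.data, load.rate)
        fit = fit_speed2_vs_load(sp, load, lowpass_hz=None)
        # c^2 = (k'mu + F/A) / rho -> slope 1/(rho A) in (m/s)^2 per N
        expected_slope = 1.0 / (INVIVO_BEAM.rho_eff * INVIVO_BEAM.area)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.slope == pytest.approx(expected_slope, rel=1e-9)
        assert fit.intercept == pytest.approx(
            INVIVO_BEAM.k_shear * INVIVO_BEAM.mu / INVIVO_BEAM.rho_eff,
            rel=1e-6)

    def test_slope_recovered_under_noise(self):
        load = _cyclic_force(duration=20.0)
        sp = _series_from_load(load.data, load.rate, noise=0.02, seed=1)
        fit = fit_speed2_vs_load(sp, load)
        expected_slope = 1.0 / (INVIVO_BEAM.rho_eff * INVIVO_BEAM.area)
        assert fit.slope == pytest.approx(expected_slope, rel=0.01)
        assert fit.r2 > 0.95

    def test_r2_degrades_with_noise(self):
        load = _cyclic_force(duration=20.0)
        r2 = []
        for noise in (0.01, 0.05, 0.10):
            sp = _series_from_load(load.data, load.rate, noise=noise, seed=2)
            r2.append(fit_speed2_vs_load(sp, load, lowpass_hz=None).r2)
        assert r2[0] > r2[1] > r2[2]

    def test_binned_summaries(self):
        load = _cyclic_force()
        sp = _series_from_load(load.data, load.rate)
        fit = fit_speed2_vs_load(sp, load, n_bins=15, lowpass_hz=None)
        assert fit.bin_centers.size == 15
        assert np.all(np.diff(fit.bin_centers) > 0)
        good = fit.bin_n > 0
        assert np.all(np.isfinite(fit.bin_means[good]))
        # on noiseless data each bin mean sits on the line somewhere inside
        # its own bin (the within-bin load mean need not be the bin centre)
        half = 0.5 * (fit.bin_centers[1] - fit.bin_centers[0])
        lo = fit.predict_speed2(fit.bin_centers[good] - half)
        hi = fit.predict_speed2(fit.bin_centers[good] + half)
        assert np.all(fit.bin_means[good] >= lo - 1e-9)
        assert np.all(fit.bin_means[good] <= hi + 1e-9)
        assert np.all(np.diff(fit.bin_means[good]) > 0)

    def test_invalid_samples_excluded_and_counted(self):
        load = _cyclic_force()
        sp = _series_from_load(load.data, load.rate)
        sp.valid[::10] = False
        fit = fit_speed2_vs_load(sp, load, lowpass_hz=None)
        assert fit.n_excluded == int((~sp.valid).sum())
        assert fit.n_valid == int(sp.valid.sum())

    def test_constant_load_rejected(self):
        load = SensorTrace(np.full(500, 100.0), 50.0, "force")
        sp = _series_from_load(load.data, load.rate)
        with pytest.raises(ValueError, match="constant load"):
            fit_speed2_vs_load(sp, load, lowpass_hz=None)

    def test_too_few_pairs_rejected(self):
        load = _cyclic_force(duration=0.2)
        sp = _series_from_load(load.data, load.rate)
        sp.valid[5:] = False
        with pytest.raises(ValueError, match="valid speed/load pairs"):
            fit_speed2_vs_load(sp, load, lowpass_hz=None)

    def test_load_quantity_propagated(self):
        load = _cyclic_force()
        sp = _series_from_load(load.data, load.rate)
        fit = fit_speed2_vs_load(sp, load, lowpass_hz=None)
        assert fit.load_quantity == "force"

    def test_invert_load_round_trip(self):
        load = _cyclic_force()
        sp = _series_from_load(load.data, load.rate)
        fit = fit_speed2_vs_load(sp, load, lowpass_hz=None)
        f = np.array([50.0, 150.0, 250.0])
        assert np.allclose(fit.invert_load(fit.predict_speed2(f)), f,
                           rtol=1e-9)


class TestTorqueFromForce:
    def test_scalar(self):
        assert torque_from_force(100.0, 0.3) == pytest.approx(30.0)

    def test_array(self):
        out = torque_from_force(np.array([0.0, 10.0]), 0.5)
        assert np.allclose(out, [0.0, 5.0])

    def test_invalid_lever(self):
        with pytest.raises(ValueError):
            torque_from_force(10.0, 0.0)


class TestRateIndependence:
    def test_identical_slopes(self):
        slopes = np.tile([[1.0], [1.2], [0.9]], (1, 4))
        f, p = rate_independence_test(slopes)
        assert f == 0.0
        assert p == 1.0

    def test_matches_statsmodels(self):
        from statsmodels.stats.anova import AnovaRM
        import pandas as pd

        rng = np.random.default_rng(7)
        n, k = 8, 3
        slopes = 1.0 + 0.1 * rng.standard_normal((n, k))
        f, p = rate_independence_test(slopes)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "rate": np.tile(np.arange(k), n),
            "slope": slopes.ravel(),
        })
        res = AnovaRM(df, "slope", "subject", within=["rate"]).fit()
        assert f == pytest.approx(res.anova_table["F Value"].iloc[0],
                                  rel=1e-9)
        assert p == pytest.approx(res.anova_table["Pr > F"].iloc[0],
                                  rel=1e-9)

    def test_injected_rate_effect_detected(self):
        rng = np.random.default_rng(11)
        n, k = 10, 3
        slopes = 1.0 + 0.01 * rng.standard_normal((n, k))
        slopes[:, 2] += 0.2  # strong systematic rate effect
        f, p = rate_independence_test(slopes)
        assert p < 0.01

    def test_missing_cell_rejected(self):
        slopes = np.ones((3, 3))
        slopes[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rate_independence_test(slopes)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            rate_independence_test(np.ones((1, 3)))
        with pytest.raises(ValueError):
            rate_independence_test(np.ones(5))


class TestCalibrateTension:
    def test_unit_conversion(self):
        from tensiometry.calibration import CalibrationFit

        fit = CalibrationFit(slope=2.0, intercept=100.0, r2=1.0,
                             bin_centers=np.array([]),
                             bin_means=np.array([]),
                             bin_sds=np.array([]), bin_n=np.array([]),
                             n_valid=0, n_excluded=0,
                             load_quantity="torque")
        tension = calibrate_tension(fit, moment_arm=0.05, load_share=1.0)
        # c^2 = 200 -> torque = (200 - 100)/2 = 50 N*m -> T = 1000 N
        assert tension(200.0) == pytest.approx(1000.0)

    def test_closed_loop_recovers_rho_area(self):
        load = _cyclic_force()
        sp = _series_from_load(load.data, load.rate)
        fit = fit_speed2_vs_load(sp, load, lowpass_hz=None)
        assert 1.0 / fit.slope == pytest.approx(
            INVIVO_BEAM.rho_eff * INVIVO_BEAM.area, rel=1e-6)

    def test_load_share_scales(self):
        from tensiometry.calibration import CalibrationFit

        fit = CalibrationFit(slope=1.0, intercept=0.0, r2=1.0,
                             bin_centers=np.array([]),
                             bin_means=np.array([]),
                             bin_sds=np.array([]), bin_n=np.array([]),
                             n_valid=0, n_excluded=0)
        full = calibrate_tension(fit, moment_arm=0.05, load_share=1.0)
        half = calibrate_tension(fit, moment_arm=0.05, load_share=0.5)
        assert half(10.0) == pytest.approx(0.5 * full(10.0))

    @pytest.mark.parametrize("kwargs", [
        {"moment_arm": 0.0}, {"moment_arm": 0.05, "load_share": 0.0},
        {"moment_arm": 0.05, "load_share": 1.5},
    ])
    def test_invalid_args(self, kwargs):
        from tensiometry.calibration import CalibrationFit

        fit = CalibrationFit(slope=1.0, intercept=0.0, r2=1.0,
                             bin_centers=np.array([]),
                             bin_means=np.array([]),
                             bin_sds=np.array([]), bin_n=np.array([]),
                             n_valid=0, n_excluded=0)
        with pytest.raises(ValueError):
            calibrate_tension(fit, **kwargs)
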