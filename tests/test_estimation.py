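"""Parameter-recovery and conversion tests for the estimation pipeline."""

import numpy as np
import pytest

from ivdds.errors import CalibrationError, EstimationError, InputError
from ivdds.estimation import (
    Biexponential,
    BloodSampleSeries,
    CalibrationSpec,
    FluorescenceTrace,
    biexponential_from_rate_constants,
    estimate_transit_time,
    fit_biexponential,
    fit_permeability,
    fluorescence_to_concentration,
    initial_distribution_volume,
    rate_constants,
    simulate_uptake_intensity,
)
from ivdds.synth import NoiseSpec


def make_uptake_trace(PS=0.012, k_av=0.5, v_e=0.56, dt=4.0, duration=600.0):
    t = np.arange(0.0, duration, dt)
    I_v = 10.0 * (1.0 - np.exp(-t / 5.0)) * np.exp(-1e-3 * t)
    I_e = simulate_uptake_intensity(t, I_v, PS, k_av, v_e)
    return FluorescenceTrace(t, I_v, I_e), v_e


class TestFitPermeability:
    def test_noise_free_recovery(self):
        trace, v_e = make_uptake_trace()
        PS, k_av, diag = fit_permeability(trace, v_e=v_e)
        assert PS == pytest.approx(0.012, rel=1e-3)
        assert k_av == pytest.approx(0.5, rel=1e-3)
        assert diag["residual_norm"] < 1e-8

    def test_invariant_to_common_intensity_rescaling(self):
        trace, v_e = make_uptake_trace()
        scaled = FluorescenceTrace(trace.times, 7.3 * trace.I_v, 7.3 * trace.I_e)
        PS1, kav1, _ = fit_permeability(trace, v_e=v_e)
        PS2, kav2, _ = fit_permeability(scaled, v_e=v_e)
        assert PS2 == pytest.approx(PS1, rel=1e-6)
        assert kav2 == pytest.approx(kav1, rel=1e-6)

    def test_zero_vascular_signal_unidentifiable(self):
        t = np.arange(0.0, 100.0, 4.0)
        trace = FluorescenceTrace(t, np.zeros_like(t), np.zeros_like(t))
        with pytest.raises(EstimationError):
            fit_permeability(trace, v_e=0.56)

    def test_noisy_recovery_within_ten_percent(self):
        trace, v_e = make_uptake_trace()
        errs = []
        for seed in range(30):
            noise = NoiseSpec(multiplicative_sd=0.05, seed=seed)
            noisy = FluorescenceTrace(trace.times, trace.I_v,
                                      noise.apply(trace.I_e, noise.rng()))
            PS, _, _ = fit_permeability(noisy, v_e=v_e)
            errs.append(abs(PS - 0.012) / 0.012)
        assert np.median(errs) < 0.05 and np.max(errs) < 0.15


class TestEstimateTransitTime:
    @staticmethod
    def step_response(TT, A=1.0, t0=2.0, dt=0.25, window=30.0, noise=None):
        t = np.arange(0.0, window + dt, dt)
        I_v = A * (1.0 - np.exp(-np.maximum(t - t0, 0.0) / TT))
        if noise is not None:
            I_v = noise.apply(np.maximum(I_v, 0.0), noise.rng())
        return FluorescenceTrace(t, I_v, np.zeros_like(t))

    def test_noise_free_recovery(self):
        assert estimate_transit_time(self.step_response(5.0)) == pytest.approx(
            5.0, rel=1e-6)

    @pytest.mark.parametrize("TT", [2.0, 5.0, 11.0, 30.0])
    def test_recovery_across_tumor_range_with_noise(self, TT):
        # span of transit times reported across human tumor types
        errs = []
        for seed in range(10):
            noise = NoiseSpec(additive_sd=0.02, seed=seed)
            trace = self.step_response(TT, window=max(30.0, 4 * TT), noise=noise)
            errs.append(abs(estimate_transit_time(trace,
                                                  window=max(30.0, 4 * TT)) - TT) / TT)
        assert np.median(errs) < 0.10

    def test_flat_signal_rejected(self):
        t = np.arange(0.0, 30.0, 0.5)
        trace = FluorescenceTrace(t, np.zeros_like(t), np.zeros_like(t))
        with pytest.raises(EstimationError):
            estimate_transit_time(trace)


class TestBiexponentialFit:
    def test_round_trip_recovery(self):
        truth = Biexponential(C0=11.12, alpha=0.6, lambda1=3e-3, lambda2=2e-4)
        times = np.array([2, 4, 8, 16, 32, 64, 128]) * 60.0
        fit = fit_biexponential(BloodSampleSeries(times, truth(times)))
        assert fit.C0 == pytest.approx(truth.C0, rel=1e-6)
        assert fit.alpha == pytest.approx(truth.alpha, rel=1e-6)
        assert fit.lambda1 == pytest.approx(truth.lambda1, rel=1e-6)
        assert fit.lambda2 == pytest.approx(truth.lambda2, rel=1e-6)

    def test_mono_exponential_data_flagged_degenerate(self):
        times = np.array([2, 4, 8, 16, 32, 64, 128]) * 60.0
        conc = 10.0 * np.exp(-5e-4 * times)
        with pytest.warns(UserWarning, match="degenerate"):
            fit_biexponential(BloodSampleSeries(times, conc))

    def test_rate_constants_round_trip_through_fit(self):
        # forward-simulate the two-compartment model with the measured
        # rate constants, fit, convert back
        k_t, k_p, k_e = 0.9e-3, 1.29e-3, 0.8e-3
        truth = biexponential_from_rate_constants(k_t, k_p, k_e, C0=11.12)
        times = np.array([2, 4, 8, 16, 32, 64, 128]) * 60.0
        fit = fit_biexponential(BloodSampleSeries(times, truth(times)))
        out = rate_constants(fit)
        assert out == pytest.approx((k_t, k_p, k_e), rel=1e-6)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InputError):
            fit_biexponential(BloodSampleSeries(np.array([1.0, 2.0, 3.0]),
                                                np.array([3.0, 2.0, 1.0])))


class TestRateConstants:
    def test_equal_eigenvalues_collapse_to_single_rate(self):
        fit = Biexponential(C0=1.0, alpha=0.3, lambda1=2e-3, lambda2=2e-3)
        k_t, k_p, k_e = rate_constants(fit)
        assert k_t == pytest.approx(0.0, abs=1e-15)
        assert k_p == pytest.approx(2e-3)
        assert k_e == pytest.approx(2e-3)

    def test_hand_evaluated_example(self):
        k_t, k_p, k_e = rate_constants(Biexponential(1.0, 0.5, 2.0, 1.0))
        assert k_p == pytest.approx(1.5)
        assert k_e == pytest.approx(2.0 / 1.5)
        assert k_t == pytest.approx(0.25 / 1.5)


class TestInitialDistributionVolume:
    def test_reference_value(self):
        # constructed so the quotient reproduces the measured 8.99 mL
        assert initial_distribution_volume(11.12, 100.0) == pytest.approx(
            8.99, abs=0.005)

    def test_unit_quotient(self):
        assert initial_distribution_volume(42.0, 42.0) == 1.0

    def test_scales_linearly_with_dose(self):
        assert initial_distribution_volume(11.12, 200.0) == pytest.approx(
            2 * initial_distribution_volume(11.12, 100.0))

    def test_zero_concentration_rejected(self):
        with pytest.raises(InputError):
            initial_distribution_volume(0.0, 100.0)


class TestFluorescenceToConcentration:
    def calib(self):
        return CalibrationSpec(scale=0.05, Hct_mv=0.19, k_av=0.5)

    def test_free_mode_uses_available_volume_fractions(self):
        t = np.arange(3.0)
        trace = FluorescenceTrace(t, np.array([0.0, 8.1, 16.2]),
                                  np.array([0.0, 5.0, 10.0]))
        c_p, c_e = fluorescence_to_concentration(trace, self.calib(), "free")
        np.testing.assert_allclose(c_p, 0.05 * trace.I_v / 0.81)
        np.testing.assert_allclose(c_e, 0.05 * trace.I_e / 0.5)

    def test_tsl_baseline_maps_to_zero_release(self):
        t = np.arange(3.0)
        trace = FluorescenceTrace(t, np.array([4.0, 4.0, 4.0]), np.zeros(3))
        c_p, _ = fluorescence_to_concentration(
            trace, self.calib(), "tsl", baseline_I_v=4.0,
            baseline_concentration=2.5)
        np.testing.assert_allclose(c_p, 0.0, atol=1e-15)

    def test_tsl_full_dequench_maps_to_encapsulated_concentration(self):
        calib = self.calib()
        t = np.arange(2.0)
        trace = FluorescenceTrace(t, np.array([4.0, 4.0 * calib.dequench_factor]),
                                  np.zeros(2))
        c_p, _ = fluorescence_to_concentration(
            trace, calib, "tsl", baseline_I_v=4.0, baseline_concentration=2.5)
        assert c_p[0] == pytest.approx(0.0, abs=1e-15)
        assert c_p[1] == pytest.approx(2.5, rel=1e-12)

    def test_tsl_released_concentration_affine_in_intensity(self):
        calib = self.calib()
        t = np.arange(3.0)
        trace = FluorescenceTrace(t, np.array([4.0, 6.0, 8.0]), np.zeros(3))
        c_p, _ = fluorescence_to_concentration(
            trace, calib, "tsl", baseline_I_v=4.0, baseline_concentration=2.5)
        assert c_p[2] == pytest.approx(2 * c_p[1], rel=1e-12)

    def test_missing_baseline_rejected(self):
        t = np.arange(3.0)
        trace = FluorescenceTrace(t, np.ones(3), np.ones(3))
        with pytest.raises(CalibrationError):
            fluorescence_to_concentration(trace, self.calib(), "tsl")
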