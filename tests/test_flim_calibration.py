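"""Decay simulation, photon-count ratio, Hill calibration, reconvolution
fitting and the decay-constant correction map."""

import numpy as np
import pytest

from caflim import flim_calibration as fc
from caflim import synth

LONG_RECORD = dict(t0_ns=1.5, irf_sigma_ns=1e-6, record_length_ns=25.0,
                   bin_width_ns=0.1)


class TestSimulateDecayHistogram:
    def test_zero_budget_gives_empty_histogram(self):
        m = fc.DecayModel((1.0,), (2.0,))
        assert fc.simulate_decay_histogram(m, 0, seed=0).sum() == 0

    def test_total_counts_conserved_within_poisson_error(self):
        m = fc.DecayModel((1.0, 0.5), (0.8, 3.0))
        budget = 1e5
        h = fc.simulate_decay_histogram(m, budget, seed=3)
        assert abs(h.sum() - budget) < 4 * np.sqrt(budget)

    def test_mean_counts_match_budget_over_seeds(self):
        m = fc.DecayModel((1.0,), (2.0,))
        totals = [fc.simulate_decay_histogram(m, 10_000, seed=s).sum()
                  for s in range(100)]
        assert abs(np.mean(totals) / 10_000 - 1) < 0.01

    def test_mono_exponential_mean_arrival_time(self):
        # narrow IRF, long record: empirical mean arrival - t0 ~ tau
        m = fc.DecayModel((1.0,), (2.0,), **LONG_RECORD)
        h = fc.simulate_decay_histogram(m, 1_000_000, seed=1)
        mid = m.bin_midpoints()
        mean_arrival = (h * mid).sum() / h.sum() - m.t0_ns
        assert mean_arrival == pytest.approx(2.0, rel=0.01)

    def test_reproducible_under_seed(self):
        m = fc.DecayModel((1.0,), (2.0,))
        a = fc.simulate_decay_histogram(m, 1e4, seed=7)
        b = fc.simulate_decay_histogram(m, 1e4, seed=7)
        assert np.array_equal(a, b)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            fc.DecayModel((1.0,), (-2.0,))
        with pytest.raises(ValueError):
            fc.DecayModel((0.0,), (2.0,))


class TestPhotonCountRatio:
    WINDOWS = fc.LifetimeWindows(0.0, 2.0, 2.0, 8.0)

    def test_direct_count(self):
        counts = np.zeros(80)
        counts[5] = 300   # midpoint 0.55 ns -> window 1
        counts[40] = 100  # midpoint 4.05 ns -> window 2
        assert fc.photon_count_ratio(counts, self.WINDOWS, 0.1) == 3.0

    def test_deterministic_on_identical_histograms(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=80)
        r1 = fc.photon_count_ratio(counts, self.WINDOWS, 0.1)
        r2 = fc.photon_count_ratio(counts.copy(), self.WINDOWS, 0.1)
        assert r1 == r2

    def test_zero_denominator_signalled(self):
        counts = np.zeros(80)
        counts[5] = 10
        with pytest.raises(fc.UndefinedRatioError):
            fc.photon_count_ratio(counts, self.WINDOWS, 0.1)

    def test_nd_input_yields_nan_for_empty_window(self):
        counts = np.zeros((2, 80))
        counts[0, 5] = 300
        counts[0, 40] = 100
        counts[1, 5] = 10
        r = fc.photon_count_ratio(counts, self.WINDOWS, 0.1)
        assert r[0] == 3.0 and np.isnan(r[1])

    def test_matches_closed_form_exponential_integral(self):
        # tau = 2 ns, windows [0,2) / [2,8): oracle is the analytic window
        # integral (1 - e^-1) / (e^-1 - e^-4) = 1.8083
        oracle = (1 - np.exp(-1)) / (np.exp(-1) - np.exp(-4))
        m = fc.DecayModel((1.0,), (2.0,), t0_ns=0.0, irf_sigma_ns=1e-9,
                          record_length_ns=8.0, bin_width_ns=0.01)
        assert fc.expected_ratio(m, self.WINDOWS) == pytest.approx(
            oracle, rel=1e-3)
        h = fc.simulate_decay_histogram(m, 1_000_000, seed=5)
        r = fc.photon_count_ratio(h, self.WINDOWS, 0.01)
        assert r == pytest.approx(oracle, rel=0.01)


class TestFitCalibration:
    def test_noiseless_hill_recovered(self):
        ca = np.array([10, 30, 100, 300, 1000, 3000, 10000], dtype=float)
        truth = fc.CalibrationCurve(1.0, 3.0, 300.0, 1.0)
        curve, diag = fc.fit_calibration(ca, truth.forward(ca))
        assert curve.k_app_nm == pytest.approx(300.0, rel=1e-6)
        assert curve.hill_h == pytest.approx(1.0, rel=1e-6)
        assert curve.r_at_zero == pytest.approx(1.0, abs=1e-6)
        assert curve.r_at_sat == pytest.approx(3.0, abs=1e-6)
        assert diag["monotone"]

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError):
            fc.fit_calibration([10, 100, 1000, 10000], [2.0, 2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            fc.fit_calibration([10, 10, 10, 10], [1, 2, 3, 4])

    def test_simulated_series_recovers_generative_half_point(self, calibration):
        from scipy.optimize import brentq

        curve, _, diag = calibration
        # generative half-point: Ca where the noiseless expected ratio sits
        # midway between its extremes (independent forward computation)
        ind = synth.CALIB_INDICATOR
        r0 = fc.expected_ratio(ind.mixture_model(1e-6), curve.windows)
        rinf = fc.expected_ratio(ind.mixture_model(1e7), curve.windows)
        target = (r0 + rinf) / 2

        def gap(ca):
            return fc.expected_ratio(ind.mixture_model(ca),
                                     curve.windows) - target

        k_gen = brentq(gap, 1.0, 1e5)
        assert curve.k_app_nm == pytest.approx(k_gen, rel=0.10)
        assert diag["monotone"]


class TestRatioToCa:
    CURVE = fc.CalibrationCurve(1.0, 3.0, 300.0, 1.0)

    def test_half_saturation_identity(self):
        ca, clamped = fc.ratio_to_ca(self.CURVE, 2.0)
        assert ca == pytest.approx(300.0, rel=1e-9)
        assert not clamped

    def test_inverse_of_forward(self):
        r = self.CURVE.forward(100.0)
        ca, _ = fc.ratio_to_ca(self.CURVE, r)
        assert ca == pytest.approx(100.0, rel=1e-6)

    def test_out_of_range_ratio_clamped_and_flagged(self):
        ca, clamped = fc.ratio_to_ca(self.CURVE, 0.5)
        assert clamped and ca > 0
        ca_hi, clamped_hi = fc.ratio_to_ca(self.CURVE, 3.5)
        assert clamped_hi and np.isfinite(ca_hi)

    def test_monotone_in_ratio(self):
        ratios = np.linspace(1.05, 2.95, 50)
        ca, _ = fc.ratio_to_ca(self.CURVE, ratios)
        assert np.all(np.diff(ca) > 0)

    def test_decreasing_curve_inverts_too(self):
        curve = fc.CalibrationCurve(3.0, 1.0, 300.0, 1.0)
        r = curve.forward(150.0)
        ca, _ = fc.ratio_to_ca(curve, r)
        assert ca == pytest.approx(150.0, rel=1e-6)


class TestAmplitudeWeightedTau:
    @pytest.mark.parametrize("amps,taus,expected", [
        ((1, 0, 0), (2, 5, 9), 2.0),
        ((1, 1, 1), (1, 2, 3), 2.0),
        ((2, 1, 1), (1, 2, 4), 2.0),
    ])
    def test_formula(self, amps, taus, expected):
        assert fc.amplitude_weighted_tau(amps, taus) == pytest.approx(expected)

    def test_all_zero_amplitudes_error(self):
        with pytest.raises(ValueError):
            fc.amplitude_weighted_tau((0, 0, 0), (1, 2, 3))


class TestReconvolutionFit:
    def test_mono_exponential_round_trip(self):
        m = fc.DecayModel((1.0,), (2.0,), bin_width_ns=0.05)
        h = fc.simulate_decay_histogram(m, 1_000_000, seed=0)
        fit = fc.fit_decay_reconvolution(h, m.t0_ns, m.irf_sigma_ns, 0.05,
                                         n_components=1)
        assert fit.success
        assert fit.taus_ns[0] == pytest.approx(2.0, rel=0.02)

    def test_below_minimum_counts_rejected(self):
        with pytest.raises(ValueError):
            fc.fit_decay_reconvolution(np.zeros(250), 1.5, 0.15, 0.05)

    def test_three_component_amplitude_weighted_tau(self):
        amps, taus = (0.5, 0.3, 0.2), (0.5, 1.6, 3.5)
        m = fc.DecayModel(amps, taus, bin_width_ns=0.05)
        h = fc.simulate_decay_histogram(m, 1_000_000, seed=1)
        fit = fc.fit_decay_reconvolution(h, m.t0_ns, m.irf_sigma_ns, 0.05)
        gen = fc.amplitude_weighted_tau(amps, taus)
        assert fit.tau_amplitude_weighted_ns == pytest.approx(gen, rel=0.05)
        assert fit.taus_ns == tuple(sorted(fit.taus_ns))

    def test_wls_objective_agrees_on_mono(self):
        m = fc.DecayModel((1.0,), (2.0,), bin_width_ns=0.05)
        h = fc.simulate_decay_histogram(m, 1_000_000, seed=2)
        fit = fc.fit_decay_reconvolution(h, m.t0_ns, m.irf_sigma_ns, 0.05,
                                         n_components=1, objective="wls")
        assert fit.taus_ns[0] == pytest.approx(2.0, rel=0.02)


class TestTauCorrectionMap:
    def test_identity_when_taus_equal(self):
        taus = (0.6, 3.5)
        cmap = fc.build_tau_correction(taus, taus)
        ri = np.asarray(cmap.ratio_intra)
        rc = np.asarray(cmap.ratio_calib)
        assert np.allclose(ri, rc, rtol=1e-9)

    def test_columns_strictly_monotone_for_defaults(self):
        cmap = fc.build_tau_correction((0.55, 3.2), (0.6, 3.5))
        assert np.all(np.diff(cmap.ratio_intra) > 0)
        assert np.all(np.diff(cmap.ratio_calib) > 0)

    def test_non_monotone_pairing_rejected(self):
        with pytest.raises(fc.NonMonotoneMapError):
            fc.TauCorrectionMap((1.0, 2.0, 3.0), (1.0, 3.0, 2.0))

    def test_three_component_map_builds_monotone(self):
        cmap = fc.build_tau_correction((0.5, 1.5, 3.2), (0.55, 1.65, 3.5),
                                       resolution=8)
        assert np.all(np.diff(cmap.ratio_calib) > 0)

    def test_noiseless_end_to_end_recovery(self, calibration):
        # intracellular decay -> correction -> Hill inverse recovers the
        # generative concentration over the physiological range
        curve, correction, _ = calibration
        for ca in (20, 50, 100, 200, 500):
            r = fc.expected_ratio(synth.INTRA_INDICATOR.mixture_model(ca),
                                  curve.windows)
            rec, _ = fc.ratio_to_ca(curve, r, correction)
            assert rec == pytest.approx(ca, rel=0.05)


def test_window_selection_prefers_discriminative_boundary():
    free = synth.CALIB_INDICATOR.free_model()
    bound = synth.CALIB_INDICATOR.bound_model()
    w = fc.select_window_boundary(free, bound)
    # boundary should land between the two lifetimes' scales, after t0
    assert free.t0_ns < w.w1_end < 6.0


def test_saturation_sanity_at_population_max_peak(calibration):
    # the largest observed peak sits mid-range on the ratio curve, far from
    # the rails of the calibration
    curve, _, _ = calibration
    r = fc.expected_ratio(synth.CALIB_INDICATOR.mixture_model(191.2),
                          curve.windows)
    frac = (curve.r_max - r) / (curve.r_max - curve.r_min)
    assert curve.r_min < r < curve.r_max
    assert 0.4 < frac < 0.7
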