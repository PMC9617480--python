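"""Trace extraction, normalization identities, FRAP and model fitting."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import convolve2d

from nerupture.errors import (
    ConfigurationError,
    DegenerateTraceError,
    InsufficientDataError,
)
from nerupture.kinetics import (
    FRAPTrace,
    KineticTrace,
    KineticsConfig,
    cn_ratio_trace,
    enrichment_call,
    fit_accumulation,
    fit_recovery,
    frap_normalize,
    line_profile,
    normalize_initial,
    normalize_peak,
    onset_time,
    roi_trace,
    snapshot_max,
)
from nerupture.simgen import (
    SceneGeometry,
    SimulationParams,
    default_frap_params,
    simulate_frap_timelapse,
    simulate_rupture_timelapse,
)


def make_trace(values, times=None, normalization="none"):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(len(values), dtype=float)
    return KineticTrace(cell_id="c0", times=times, values=values,
                        normalization=normalization)


class TestRoiTrace:
    def test_constant_frames_pass_through_the_filter(self):
        stack = np.full((4, 32, 32), 7.0)
        mask = np.zeros((32, 32), bool)
        mask[10:20, 10:20] = True
        for statistic in ("max", "mean"):
            tr = roi_trace(stack, mask, KineticsConfig(statistic=statistic))
            np.testing.assert_allclose(tr.values, 7.0, rtol=1e-12)

    def test_impulse_max_matches_direct_convolution(self):
        """sigma=2 filtered impulse peak against an explicit truncated-kernel
        convolution (radius 4*sigma, normalized), computed independently."""
        frame = np.zeros((65, 65))
        frame[32, 32] = 1.0
        sigma, radius = 2.0, 8  # gaussian_filter truncates at 4 sigma
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-(x**2) / (2 * sigma**2))
        k1 /= k1.sum()
        expected = convolve2d(frame, np.outer(k1, k1), mode="same")
        mask = np.zeros_like(frame, bool)
        mask[20:45, 20:45] = True
        tr = roi_trace(frame[None], mask, KineticsConfig(gaussian_sigma=sigma))
        assert tr.values[0] == pytest.approx(expected.max(), rel=1e-9)

    def test_zero_sigma_is_identity_filter(self):
        rng = np.random.default_rng(3)
        frame = rng.uniform(0, 10, (16, 16))
        mask = np.ones((16, 16), bool)
        tr = roi_trace(frame[None], mask, KineticsConfig(gaussian_sigma=0.0))
        assert tr.values[0] == frame.max()

    def test_empty_roi_rejected(self):
        with pytest.raises(ConfigurationError):
            roi_trace(np.ones((2, 8, 8)), np.zeros((8, 8), bool))


class TestNormalization:
    def test_initial_normalization_arithmetic(self):
        tr = normalize_initial(make_trace([5.0, 10.0, 15.0]))
        np.testing.assert_array_equal(tr.values, [1.0, 2.0, 3.0])
        assert tr.values[0] == 1.0
        assert tr.normalization == "initial"

    def test_peak_normalization_and_tie_rule(self):
        tr = normalize_peak(make_trace([1.0, 4.0, 2.0]))
        np.testing.assert_array_equal(tr.values, [0.25, 1.0, 0.5])
        assert tr.peak_index == 1
        tied = normalize_peak(make_trace([1.0, 3.0, 3.0]))
        assert tied.peak_index == 1  # earliest of the tied maxima
        flat = normalize_peak(make_trace([2.0, 2.0, 2.0]))
        assert flat.peak_index == 0
        np.testing.assert_array_equal(flat.values, 1.0)

    def test_degenerate_baselines_raise(self):
        with pytest.raises(DegenerateTraceError):
            normalize_initial(make_trace([0.0, 1.0, 2.0]))
        with pytest.raises(DegenerateTraceError):
            normalize_peak(make_trace([-3.0, -1.0, -2.0]))

    @given(
        st.lists(st.floats(min_value=0.1, max_value=1e4), min_size=2, max_size=30),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_idempotence_and_scale_invariance(self, values, scale):
        tr = make_trace(values)
        for norm in (normalize_initial, normalize_peak):
            once = norm(tr)
            twice = norm(once)
            np.testing.assert_allclose(twice.values, once.values, rtol=1e-12)
            scaled = norm(make_trace(np.asarray(values) * scale))
            np.testing.assert_allclose(scaled.values, once.values, rtol=1e-9)


class TestCnRatio:
    @staticmethod
    def masks():
        nuc = np.zeros((32, 32), bool)
        cyt = np.zeros((32, 32), bool)
        nuc[8:16, 8:16] = True
        cyt[20:28, 20:28] = True
        return nuc, cyt

    def test_equal_concentrations_give_unit_ratio(self):
        nuc, cyt = self.masks()
        stack = np.full((3, 32, 32), 50.0)
        tr = cn_ratio_trace(stack, nuc, cyt, KineticsConfig(gaussian_sigma=0.0))
        np.testing.assert_allclose(tr.values, 1.0, rtol=1e-12)

    def test_scale_invariance(self):
        nuc, cyt = self.masks()
        rng = np.random.default_rng(0)
        stack = rng.uniform(10, 100, (4, 32, 32))
        a = cn_ratio_trace(stack, nuc, cyt).values
        b = cn_ratio_trace(stack * 7.3, nuc, cyt).values
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_no_leak_means_constant_ratio(self, geometry, clean_params):
        params = dataclasses.replace(clean_params, leak_conductance=0.0,
                                     reporter_cyto0=100.0)
        stack, truth = simulate_rupture_timelapse(geometry, params)
        tr = cn_ratio_trace(stack.channel("reporter"), truth.masks["nucleus"],
                            truth.masks["cytoplasm"])
        assert np.ptp(tr.values) < 1e-9

    def test_leakage_matches_closed_form_within_one_percent(self, geometry):
        params = SimulationParams(background=0.0, V_n=1.0, V_c=1.0,
                                  reseal_time=1e9, n_frames=61)
        stack, truth = simulate_rupture_timelapse(geometry, params)
        tr = cn_ratio_trace(stack.channel("reporter"), truth.masks["nucleus"],
                            truth.masks["cytoplasm"],
                            KineticsConfig(gaussian_sigma=0.0))
        expected = truth.traces["reporter_cytoplasm"] / truth.traces["reporter_nucleus"]
        np.testing.assert_allclose(tr.values, expected, rtol=0.01)
        # long open window with equal volumes approaches ratio 1 from below
        assert tr.values[-1] > 0.9 * expected[-1]
        assert np.all(tr.values <= 1.0 + 1e-9)

    def test_nuclear_mean_at_background_rejected(self):
        nuc, cyt = self.masks()
        stack = np.zeros((2, 32, 32))
        with pytest.raises(DegenerateTraceError):
            cn_ratio_trace(stack, nuc, cyt)


class TestFrapNormalization:
    def test_shared_multiplicative_drift_cancels(self):
        t = np.arange(20, dtype=float)
        drift = np.exp(-0.03 * t)
        g = np.full_like(t, 5.0)
        frap = FRAPTrace(times=t, bleached=100 * drift + 5.0,
                         reference=200 * drift + 5.0, background=g, n_pre=5)
        out = frap_normalize(frap)
        np.testing.assert_allclose(out.normalized, 1.0, rtol=1e-12)

    def test_prebleach_mean_is_exactly_one(self):
        rng = np.random.default_rng(1)
        t = np.arange(30, dtype=float)
        frap = FRAPTrace(times=t, bleached=rng.uniform(50, 150, 30),
                         reference=rng.uniform(150, 250, 30),
                         background=np.full(30, 3.0), n_pre=5)
        out = frap_normalize(frap)
        assert out.normalized[:5].mean() == pytest.approx(1.0, abs=1e-12)

    def test_acquisition_bleaching_cancels_against_bleach_free_run(self, geometry):
        """Paired simulations: beta = 0.01/frame vs beta = 0 produce the same
        double-normalized trace to high precision (noiseless)."""
        results = {}
        for beta in (0.0, 0.01):
            params = default_frap_params(beta=beta)
            stack, truth = simulate_frap_timelapse(geometry, params)
            cfg = KineticsConfig(gaussian_sigma=2.0, statistic="max")
            traces = {
                name: roi_trace(stack.channel(0), truth.masks[name], cfg).values
                for name in ("spot", "reference", "background")
            }
            out = frap_normalize(FRAPTrace(
                times=stack.times, bleached=traces["spot"],
                reference=traces["reference"], background=traces["background"],
                n_pre=5))
            results[beta] = out.normalized
        np.testing.assert_allclose(results[0.01], results[0.0], atol=1e-9)

    def test_nonpositive_reference_rejected(self):
        t = np.arange(10, dtype=float)
        frap = FRAPTrace(times=t, bleached=np.ones(10), reference=np.ones(10),
                         background=np.ones(10), n_pre=3)
        with pytest.raises(DegenerateTraceError):
            frap_normalize(frap)


class TestRecoveryFit:
    def test_exact_model_data_recovered(self):
        t = np.linspace(0, 60, 80)
        f0, f_inf, k = 0.3, 0.86, 0.1
        y = f_inf - (f_inf - f0) * np.exp(-k * t)
        fit = fit_recovery(y, t)
        assert fit.converged
        assert fit.f0 == pytest.approx(f0, abs=1e-6)
        assert fit.f_inf == pytest.approx(f_inf, abs=1e-6)
        assert fit.k_rec == pytest.approx(k, abs=1e-6)
        assert fit.mobile_fraction == pytest.approx((f_inf - f0) / (1 - f0), abs=1e-6)
        assert fit.half_time == pytest.approx(np.log(2) / k, rel=1e-5)

    def test_flat_trace_flags_unidentifiable_rate(self):
        t = np.linspace(0, 30, 40)
        fit = fit_recovery(np.full_like(t, 0.3), t)
        assert fit.mobile_fraction == pytest.approx(0.0, abs=1e-6)
        assert not fit.k_identifiable

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_recovery(np.ones(3), np.arange(3.0))

    def test_end_to_end_double_normalized_plateau(self, geometry):
        """Simulated bleach with floor 0.3 and mobility 0.8: the normalized
        plateau measured on the spot itself is b + M(1-b) = 0.86, and the
        fitted mobile fraction matches truth."""
        params = default_frap_params(n_frames=205, background=0.0)
        stack, truth = simulate_frap_timelapse(geometry, params)
        cfg = KineticsConfig(gaussian_sigma=0.0, statistic="mean")
        traces = {
            name: roi_trace(stack.channel(0), truth.masks[name], cfg).values
            for name in ("spot", "reference", "background")
        }
        out = frap_normalize(FRAPTrace(
            times=stack.times, bleached=traces["spot"],
            reference=traces["reference"], background=traces["background"], n_pre=5))
        assert out.normalized[-1] == pytest.approx(0.3 + 0.8 * 0.7, abs=1e-3)
        fit = fit_recovery(out.normalized[5:], stack.times[5:] - stack.times[5])
        assert fit.mobile_fraction == pytest.approx(0.8, abs=1e-6)

    def test_mobile_fraction_invariant_to_filter_mixing(self, geometry):
        """A sigma=2 max measurement mixes unbleached signal into the spot
        trace, raising floor and plateau — but the double-normalized mobile
        fraction is invariant under that linear mixing."""
        params = default_frap_params(background=0.0)
        stack, truth = simulate_frap_timelapse(geometry, params)
        cfg = KineticsConfig(gaussian_sigma=2.0, statistic="max")
        traces = {
            name: roi_trace(stack.channel(0), truth.masks[name], cfg).values
            for name in ("spot", "reference", "background")
        }
        out = frap_normalize(FRAPTrace(
            times=stack.times, bleached=traces["spot"],
            reference=traces["reference"], background=traces["background"], n_pre=5))
        fit = fit_recovery(out.normalized[5:], stack.times[5:] - stack.times[5])
        assert fit.f0 > 0.3  # the floor is mixed upward by the filter
        assert fit.mobile_fraction == pytest.approx(0.8, abs=1e-6)
        assert fit.k_rec == pytest.approx(0.1, rel=1e-4)


class TestAccumulationFit:
    def test_exact_model_data_recovered(self):
        t = np.arange(0, 300, 10.0)
        a, k, t0 = 1.5, 0.05, 10.0
        y = np.where(t >= t0, 1 + a * (1 - np.exp(-k * (t - t0))), 1.0)
        fit = fit_accumulation(make_trace(y, times=t, normalization="initial"), t0)
        assert fit.amplitude == pytest.approx(a, abs=1e-6)
        assert fit.k_acc == pytest.approx(k, abs=1e-6)

    def test_flat_trace_fits_zero_amplitude(self):
        t = np.arange(0, 200, 10.0)
        fit = fit_accumulation(make_trace(np.ones_like(t), times=t,
                                          normalization="initial"), 10.0)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)
        assert not fit.k_identifiable

    def test_too_few_post_rupture_samples_rejected(self):
        t = np.arange(0, 60, 10.0)
        tr = make_trace(np.ones_like(t), times=t, normalization="initial")
        with pytest.raises(InsufficientDataError):
            fit_accumulation(tr, 40.0)

    def test_unnormalized_trace_rejected(self):
        tr = make_trace([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ConfigurationError):
            fit_accumulation(tr, 0.0)


class TestOnsetAndEnrichment:
    def test_onset_reads_first_sustained_crossing(self):
        tr = make_trace([1.0, 1.0, 1.3, 1.4, 1.5], times=np.arange(5) * 10.0,
                        normalization="initial")
        assert onset_time(tr, threshold_fold=1.2) == 20.0

    def test_transient_spike_not_sustained(self):
        tr = make_trace([1.0, 1.3, 1.0, 1.0, 1.0], normalization="initial")
        assert onset_time(tr, threshold_fold=1.2) is None

    def test_flat_trace_has_no_onset(self):
        tr = make_trace(np.ones(6), normalization="initial")
        assert onset_time(tr) is None

    def test_pool_dependent_onset_on_paired_simulations(self, geometry, clean_params):
        """Large-pool probe reaches the 1.2-fold criterion within tens of
        seconds; a pool-free probe never does."""
        cfg = KineticsConfig(gaussian_sigma=2.0, statistic="max")
        onsets = {}
        for pool in (0.7, 0.0):
            params = dataclasses.replace(clean_params, pool_fraction=pool)
            stack, truth = simulate_rupture_timelapse(geometry, params)
            tr = roi_trace(stack.channel("probe"), truth.masks["site"], cfg,
                           times=stack.times)
            onsets[pool] = onset_time(normalize_initial(tr))
        assert onsets[0.0] is None
        assert onsets[0.7] is not None and onsets[0.7] <= 50.0

    def test_enrichment_threshold_is_inclusive(self):
        assert not enrichment_call(100.0, 100.0, fold_threshold=1.5).positive
        assert enrichment_call(150.0, 100.0, fold_threshold=1.5).positive
        with pytest.raises(DegenerateTraceError):
            enrichment_call(10.0, 0.0)

    def test_snapshot_max_equals_single_frame_roi_trace(self):
        rng = np.random.default_rng(8)
        frame = rng.uniform(0, 100, (48, 48))
        mask = np.zeros((48, 48), bool)
        mask[10:30, 10:30] = True
        cfg = KineticsConfig(gaussian_sigma=2.0)
        assert snapshot_max(frame, mask, cfg) == roi_trace(
            frame[None], mask, cfg).values[0]


class TestLineProfile:
    def test_constant_image_gives_constant_profile(self):
        prof = line_profile(np.full((40, 40), 9.0), (5, 5), (30, 30))
        np.testing.assert_allclose(prof["value"], 9.0, rtol=1e-12)

    def test_step_edge_located_within_one_pixel(self):
        frame = np.zeros((40, 40))
        frame[:, 20:] = 100.0
        prof = line_profile(frame, (20, 2), (20, 37))
        crossing = np.argmax(prof["value"].values >= 50.0)
        edge_distance = 20 - 2
        assert abs(crossing - edge_distance) <= 1
        assert np.all(np.diff(prof["value"]) >= 0)

    def test_width_averages_thin_line_with_background(self):
        frame = np.zeros((40, 40))
        frame[20, :] = 90.0  # 1-px bright line along the profile
        prof = line_profile(frame, (20, 5), (20, 35), width_px=3)
        np.testing.assert_allclose(prof["value"][1:-1], 30.0, rtol=1e-9)

    def test_degenerate_segments_rejected(self):
        frame = np.zeros((20, 20))
        with pytest.raises(ConfigurationError):
            line_profile(frame, (5, 5), (5, 5))
        with pytest.raises(ConfigurationError):
            line_profile(frame, (5, 5), (25, 5))
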