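import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

import soxkin as sk
from conftest import trace_truth
from soxkin.errors import InsufficientDataError, ValidationError


class TestEvalModel:
    def test_signal_starts_at_baseline(self):
        p = sk.HomogeneousParams(1.0, 3.5, 2.0, 0.0, 0.0)
        assert sk.eval_model(p, [0.0])[0] == 0.0
        p2 = sk.HomogeneousParams(1.0, 3.5, 2.0, 1.3, 4.0)
        assert sk.eval_model(p2, [0.0, 1.3]).tolist() == [4.0, 4.0]

    def test_full_decay_returns_to_baseline(self):
        p = sk.HomogeneousParams(1.0, 3.5, 2.0, 0.0, 0.7)
        assert sk.eval_model(p, [100.0])[0] == pytest.approx(0.7, abs=1e-10)

    @pytest.mark.parametrize("ratio", [0.1, 0.5, 0.9, 2.0, 10.0])
    def test_area_identity_by_quadrature(self, ratio):
        # integral of the baseline-free signal equals alpha * tau_delta
        td = 3.5
        p = sk.HomogeneousParams(1.0, td, td * ratio, 0.0, 0.0)
        area, _ = quad(lambda t: sk.eval_model(p, [t])[0], 0.0,
                       60 * max(td, td * ratio), limit=400)
        assert area == pytest.approx(td, rel=1e-3)

    def test_equal_lifetime_limit_peaks_at_alpha_over_e(self):
        p = sk.HomogeneousParams(1.0, 3.0, 3.0, 0.0, 0.0)
        assert sk.eval_model(p, [3.0])[0] == pytest.approx(np.exp(-1.0))

    def test_near_equal_lifetimes_continuous(self):
        t = np.linspace(0, 20, 200)
        a = sk.eval_model(sk.HomogeneousParams(1, 3.0, 3.0 * (1 - 2e-6)), t)
        b = sk.eval_model(sk.HomogeneousParams(1, 3.0, 3.0 * (1 - 5e-7)), t)
        assert np.max(np.abs(a - b)) < 1e-5

    @pytest.mark.parametrize("ratio", [0.2, 0.6, 1.7, 5.0])
    def test_peak_time_identity(self, ratio):
        p = sk.HomogeneousParams(1.0, 3.5, 3.5 * ratio, 0.4, 0.0)
        t = np.arange(0.0, 80.0, 0.002)
        numeric = t[np.argmax(sk.eval_model(p, t))]
        assert abs(numeric - sk.peak_time(p)) <= 0.002

    def test_nonpositive_lifetime_rejected(self):
        with pytest.raises(ValidationError):
            sk.HomogeneousParams(1.0, -3.5, 2.0)


class TestFitHomogeneous:
    def test_noiseless_roundtrip_to_1e6(self, noiseless_water_trace):
        fit = sk.canonicalize_assignment(
            sk.fit_homogeneous(noiseless_water_trace), 3.5)
        truth = trace_truth(noiseless_water_trace)
        for name in ("alpha", "tau_delta", "tau_T", "t0", "y0"):
            fitted = getattr(fit.params, name)
            ref = truth[name] if truth[name] != 0 else 1.0
            assert abs(fitted - truth[name]) / abs(ref) < 1e-6, name

    def test_noisy_fit_within_2_sigma(self, noisy_water_trace):
        fit = sk.canonicalize_assignment(sk.fit_homogeneous(noisy_water_trace),
                                         3.5)
        truth = trace_truth(noisy_water_trace)
        for name in ("tau_delta", "tau_T"):
            err = abs(getattr(fit.params, name) - truth[name])
            assert err <= 2 * fit.uncertainties[name] + 1e-12, name

    def test_too_few_bins_rejected(self):
        tr = sk.KineticTrace(np.arange(10) * 0.1, np.arange(10))
        with pytest.raises(InsufficientDataError):
            sk.fit_homogeneous(tr)

    def test_fixed_t0_honored(self, noisy_water_trace):
        fit = sk.fit_homogeneous(noisy_water_trace, fix_t0=True, t0_value=0.0)
        assert fit.t0_mode == "fixed" and fit.params.t0 == 0.0
        assert fit.uncertainties["t0"] == 0.0

    def test_fixed_tau_T_constraint(self, noisy_water_trace):
        fit = sk.fit_homogeneous(noisy_water_trace, fixed_tau_T=2.0)
        assert fit.params.tau_T == 2.0

    def test_uncropped_sta_with_fixed_t0_biases_lifetimes(self, water_params):
        # forcing the onset to the contaminated region distorts both
        # lifetimes relative to the properly cropped free-t0 fit
        tr = sk.generate_homogeneous_trace(
            water_params, sk.NoiseSpec(seed=3, sta=sk.STASpec(5.0, 0.3, 0.0)))
        bad = sk.canonicalize_assignment(
            sk.fit_homogeneous(tr, fix_t0=True, t0_value=0.0), 3.5)
        end = sk.detect_sta(tr, sk.estimate_baseline(tr))
        good = sk.canonicalize_assignment(
            sk.fit_homogeneous(sk.crop_and_origin(tr, end, 0.0)), 3.5)
        bias_bad = max(abs(bad.params.tau_delta - 3.5) / 3.5,
                       abs(bad.params.tau_T - 2.0) / 2.0)
        bias_good = max(abs(good.params.tau_delta - 3.5) / 3.5,
                        abs(good.params.tau_T - 2.0) / 2.0)
        assert bias_bad > 2 * bias_good


class TestCanonicalization:
    def test_swap_example(self):
        fit = sk.HomogeneousFit(
            sk.HomogeneousParams(10.0, 2.0, 3.5, 0.0, 0.0),
            sk.FitStats(1.0, 0.99, 100, 5, np.zeros(100), None,
                        np.arange(100) * 0.1),
            {"alpha": 1.0, "tau_delta": 0.1, "tau_T": 0.2, "t0": 0.0,
             "y0": 0.1}, "free")
        out = sk.canonicalize_assignment(fit, 3.5)
        assert out.params.tau_delta == 3.5 and out.params.tau_T == 2.0
        # amplitude rescales to preserve alpha * tau_delta (curve invariance)
        assert out.params.alpha == pytest.approx(10.0 * 2.0 / 3.5)
        assert out.uncertainties["tau_delta"] == 0.2

    def test_already_canonical_unchanged(self):
        fit = sk.HomogeneousFit(
            sk.HomogeneousParams(10.0, 3.5, 2.0, 0.0, 0.0),
            sk.FitStats(1.0, 0.99, 100, 5, np.zeros(100), None,
                        np.arange(100) * 0.1),
            dict.fromkeys(("alpha", "tau_delta", "tau_T", "t0", "y0"), 0.1),
            "free")
        out = sk.canonicalize_assignment(fit, 3.5)
        assert out.params == fit.params

    @given(st.floats(0.5, 10.0), st.floats(0.2, 8.0), st.floats(1.0, 1e4))
    def test_swap_never_changes_curve(self, td, tT, alpha):
        t = np.linspace(0.0, 60.0, 400)
        fit = sk.HomogeneousFit(
            sk.HomogeneousParams(alpha, td, tT, 0.3, 5.0),
            sk.FitStats(1.0, 0.99, 400, 5, np.zeros(400), None, t),
            dict.fromkeys(("alpha", "tau_delta", "tau_T", "t0", "y0"), 0.1),
            "free")
        out = sk.canonicalize_assignment(fit, 3.5)
        before = sk.eval_model(fit.params, t)
        after = sk.eval_model(out.params, t)
        assert np.max(np.abs(after - before)) < 1e-10 * np.max(before)


class TestTailFit:
    def test_tail_only_lifetime_biased_upward(self, water_params):
        # restricting to the decay phase couples the lifetimes and
        # lengthens the apparent tau_delta
        for seed in (0, 1, 2):
            tr = sk.generate_homogeneous_trace(water_params,
                                               sk.NoiseSpec(seed=seed))
            cmp_ = sk.tail_fit_demo(tr, t_tail=2.8)
            assert cmp_.tau_tail >= cmp_.tau_full

    def test_monoexponential_trace_no_bias(self):
        # with a vanishing rise the tail fit and full fit agree
        t = np.arange(0.0, 40.0, 0.02)
        p = sk.HomogeneousParams(100.0, 3.5, 0.2, 0.0, 0.0)
        rng = np.random.default_rng(0)
        tr = sk.KineticTrace(t, rng.poisson(
            2000 * sk.eval_model(p, t) / sk.eval_model(p, [sk.peak_time(p)])[0]
            + 50))
        cmp_ = sk.tail_fit_demo(tr, t_tail=1.5)
        assert abs(cmp_.tau_tail - cmp_.tau_full) < 3 * np.hypot(
            cmp_.tau_tail_sigma, cmp_.tau_full_sigma)

    def test_tail_beyond_trace_rejected(self, noisy_water_trace):
        with pytest.raises(InsufficientDataError):
            sk.tail_fit_demo(noisy_water_trace, t_tail=100.0)


class TestSurplus:
    def test_homogeneous_trace_has_no_surplus(self, noisy_water_trace):
        res = sk.surplus_analysis(noisy_water_trace, t_tail=7.0)
        # weighted mean surplus consistent with zero
        w = 1.0 / np.maximum(np.asarray(noisy_water_trace.counts, float), 1.0)
        mean = np.sum(w * res.surplus) / np.sum(w)
        sem = 1.0 / np.sqrt(np.sum(w))
        assert abs(mean) < 3 * sem
        assert res.time[-1] - 7.0 > 20  # tail window dominates the sweep

    def test_lipid_trace_has_early_positive_surplus(self, liposome_setup):
        s = liposome_setup
        tr = sk.generate_heterogeneous_trace(
            s["geom"], s["phases"], s["source"], s["tau_delta_W"],
            3.43, 1.0, 0.0, sk.NoiseSpec(seed=2, scale=2500, dark_rate=2500),
            grid=s["grid"])
        res = sk.surplus_analysis(tr, t_tail=7.0, expected_tau_delta=4.0)
        early = res.surplus[res.time <= 3.0]
        late = res.surplus[res.time > 7.0]
        assert early.mean() > 5 * np.abs(late.mean())
        assert res.init_estimates["tau_T"] is not None


class TestLinearity:
    def test_proportional_series_clean(self):
        rep = sk.linearity_absorbance(
            sk.generate_linearity_series("absorbance", 10, seed=0))
        assert rep.flags == []
        assert abs(rep.intercept) <= 3 * rep.intercept_sigma

    def test_saturation_beyond_A03_flags_curvature(self):
        rep = sk.linearity_absorbance(
            sk.generate_linearity_series("absorbance", 12,
                                         distortion="saturation", seed=4))
        assert "curvature" in rep.flags
        x_at_03 = 1.0 - 10.0 ** -0.3
        assert rep.linear_range_end is not None
        assert rep.linear_range_end <= x_at_03 * 1.15

    def test_constant_offset_flags_intercept(self):
        rep = sk.linearity_absorbance(
            sk.generate_linearity_series("absorbance", 10,
                                         distortion="offset", seed=4))
        assert "nonzero_intercept" in rep.flags

    def test_power_series_through_origin(self):
        rep = sk.linearity_power(
            sk.generate_linearity_series("power", 10, slope=200.0, seed=0))
        assert rep.flags == []
        assert rep.slope == pytest.approx(200.0, rel=0.05)

    def test_photobleaching_bend_near_4mJ(self):
        rep = sk.linearity_power(
            sk.generate_linearity_series("power", 12,
                                         distortion="saturation", seed=4))
        assert "deviation" in rep.flags
        assert rep.linear_range_end is not None
        assert rep.linear_range_end <= 4.6

    def test_all_zero_alpha_degenerate(self):
        pairs = [(1.0, 0.0, 1.0), (2.0, 0.0, 1.0), (3.0, 0.0, 1.0)]
        rep = sk.linearity_power(pairs)
        assert rep.slope == 0.0 and "degenerate" in rep.flags

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            sk.linearity_absorbance([(0.1, 1.0, 0.1), (0.2, 2.0, 0.1)])
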