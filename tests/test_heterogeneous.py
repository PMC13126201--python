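import numpy as np
import pytest

import soxkin as sk
from soxkin.errors import ValidationError
from soxkin.heterogeneous import fit_linear_combination, runs_test_pvalue


@pytest.fixture(scope="module")
def default_basis(liposome_setup):
    s = liposome_setup
    return sk.simulate_basis(s["geom"], s["phases"], s["source"],
                             s["tau_delta_W"], s["grid"])


class TestShellSolver:
    def test_zero_source_gives_zero_populations(self, liposome_setup):
        s = liposome_setup
        src = sk.SourceSpec(tau_T=2.0, w_lipid=0.0, w_water=0.0)
        b = sk.simulate_basis(s["geom"], s["phases"], src, 4.0, s["grid"])
        assert np.all(b.n_L == 0) and np.all(b.n_W == 0)

    def test_mass_balance_below_1e4(self, default_basis):
        assert np.max(sk.mass_balance_residual(default_basis)) < 1e-4

    def test_populations_nonnegative_and_decaying(self, default_basis):
        b = default_basis
        assert np.all(b.n_L >= 0) and np.all(b.n_W >= 0)
        assert b.n_L[-1] < 1e-3 * b.n_L.max()
        assert b.n_W[-1] < 1e-2 * b.n_W.max()

    def test_homogeneous_limit_matches_rise_decay_kernel(self, liposome_setup):
        s = liposome_setup
        phases = sk.PhaseParams(D_W=2000.0, D_L=2000.0, tau_delta_L=3.5,
                                K_partition=1.0, allow_tau_L_outside=True)
        b = sk.simulate_basis(s["geom"], phases, s["source"], 3.5, s["grid"])
        td, tT = 3.5, s["source"].tau_T
        kernel = td / (td - tT) * (np.exp(-b.time / td) - np.exp(-b.time / tT))
        dev = np.abs(b.n_L + b.n_W - kernel)
        assert np.max(dev) < 0.01 * np.max(kernel)

    def test_grid_convergence_below_half_percent(self, liposome_setup,
                                                 default_basis):
        s = liposome_setup
        fine = sk.SimGrid(t_max=s["grid"].t_max, dt_out=s["grid"].dt_out,
                          dt=s["grid"].dt / 2, n_mem_cells=2 * s["grid"].n_mem_cells)
        b2 = sk.simulate_basis(s["geom"], s["phases"], s["source"],
                               s["tau_delta_W"], fine)
        assert np.max(np.abs(b2.n_L - default_basis.n_L)) < 0.005 * default_basis.n_L.max()
        assert np.max(np.abs(b2.n_W - default_basis.n_W)) < 0.005 * default_basis.n_W.max()

    def test_water_population_monotone_in_its_lifetime(self, liposome_setup):
        s = liposome_setup
        integrals = []
        for tau_w in (3.0, 3.5, 4.0, 4.5):
            b = sk.simulate_basis(s["geom"], s["phases"], s["source"], tau_w,
                                  s["grid"])
            integrals.append(np.trapezoid(b.n_W, b.time))
        assert all(a < b for a, b in zip(integrals, integrals[1:]))

    def test_membrane_resolution_enforced(self, liposome_setup):
        with pytest.raises(ValidationError):
            sk.SimGrid(n_mem_cells=4)

    def test_lipid_lifetime_range_guard(self):
        with pytest.raises(ValidationError):
            sk.PhaseParams(tau_delta_L=5.0)
        assert sk.PhaseParams(tau_delta_L=5.0,
                              allow_tau_L_outside=True).tau_delta_L == 5.0


class TestLinearCombinationFit:
    def test_exact_coefficients_recovered(self, default_basis):
        b = default_basis
        tr = sk.KineticTrace(b.time[1:], 2.0 * b.n_L[1:] + 3.0 * b.n_W[1:] + 1.0)
        A, B, C, chi2 = fit_linear_combination(tr, b, weights="uniform")
        assert (A, B, C) == pytest.approx((2.0, 3.0, 1.0), abs=1e-8)

    def test_water_only_trace(self, default_basis):
        b = default_basis
        tr = sk.KineticTrace(b.time[1:], b.n_W[1:])
        A, B, C, _ = fit_linear_combination(tr, b, weights="uniform")
        assert A == pytest.approx(0.0, abs=1e-8)
        assert B == pytest.approx(1.0, abs=1e-8)
        assert C == pytest.approx(0.0, abs=1e-8)

    def test_ab_ratio_recovered_from_poisson_trace(self, liposome_setup):
        # fit against the true basis: the coefficient estimator itself
        s = liposome_setup
        tr = sk.generate_heterogeneous_trace(
            s["geom"], s["phases"], s["source"], s["tau_delta_W"],
            3.0, 1.0, 0.0, sk.NoiseSpec(seed=0, scale=2500, dark_rate=2500),
            grid=s["grid"])
        basis = sk.simulate_basis(s["geom"], s["phases"], s["source"],
                                  s["tau_delta_W"], s["grid"])
        A, B, C, _ = fit_linear_combination(tr, basis)
        assert A / B == pytest.approx(3.0, rel=0.10)

    def test_collinear_basis_warns(self, default_basis):
        b = default_basis
        collinear = sk.BasisFunctions(b.time, b.n_W.copy(), 2.0 * b.n_W,
                                      dict(b.normalization))
        tr = sk.KineticTrace(b.time[1:], 3.0 * b.n_W[1:] + 1.0)
        with pytest.warns(UserWarning, match="collinear"):
            fit_linear_combination(tr, collinear, weights="uniform")


class TestParameterScan:
    TT = np.arange(1.8, 2.21, 0.1)
    TW = np.arange(3.8, 4.21, 0.1)

    def test_noiseless_scan_recovers_exact_cell(self, liposome_setup):
        s = liposome_setup
        tr = sk.generate_heterogeneous_trace(
            s["geom"], s["phases"], s["source"], 4.0, 3.43, 1.0, 0.0,
            sk.NoiseSpec(seed=0, scale=2500, dark_rate=0, poisson=False),
            grid=s["grid"])
        surf, fit = sk.scan_parameter_grid(tr, s["geom"], s["phases"],
                                           s["source"], self.TT, self.TW,
                                           grid=s["grid"])
        assert fit.tau_T == pytest.approx(2.0)
        assert fit.tau_delta_W == pytest.approx(4.0)
        assert fit.AB_ratio == pytest.approx(3.43, rel=1e-6)
        assert surf.chi2_red[surf.argmin] == pytest.approx(0.0, abs=1e-12)

    def test_flat_trace_degenerate_surface(self, liposome_setup):
        s = liposome_setup
        t = np.arange(0.0, 20.0, 0.05)
        tr = sk.KineticTrace(t, np.full_like(t, 50.0))
        with pytest.warns(UserWarning, match="degenerate"):
            surf, fit = sk.scan_parameter_grid(
                tr, s["geom"], s["phases"], s["source"],
                [1.9, 2.0], [3.9, 4.0], grid=s["grid"])
        assert fit.A == pytest.approx(0.0, abs=1e-6)
        assert fit.B == pytest.approx(0.0, abs=1e-6)

    def test_lipid_lifetime_insensitivity(self, liposome_setup):
        # varying tau_delta_L across its literature range moves the
        # best-fit cell by at most one grid step
        s = liposome_setup
        tr = sk.generate_heterogeneous_trace(
            s["geom"], s["phases"], s["source"], 4.0, 3.43, 1.0, 0.0,
            sk.NoiseSpec(seed=0, scale=2500, dark_rate=0, poisson=False),
            grid=s["grid"])
        best = {}
        for tau_L in (12.0, 16.0):
            phases = sk.PhaseParams(tau_delta_L=tau_L)
            _, fit = sk.scan_parameter_grid(tr, s["geom"], phases,
                                            s["source"], self.TT, self.TW,
                                            grid=s["grid"])
            best[tau_L] = (fit.tau_T, fit.tau_delta_W)
        assert abs(best[12.0][0] - best[16.0][0]) <= 0.1 + 1e-9
        assert abs(best[12.0][1] - best[16.0][1]) <= 0.1 + 1e-9


class TestDeconvolution:
    def test_lipid_component_peaks_before_water(self, liposome_setup):
        s = liposome_setup
        tr = sk.generate_heterogeneous_trace(
            s["geom"], s["phases"], s["source"], 4.0, 3.43, 1.0, 0.0,
            sk.NoiseSpec(seed=1, scale=2500, dark_rate=2500), grid=s["grid"])
        _, fit = sk.scan_parameter_grid(tr, s["geom"], s["phases"],
                                        s["source"], [2.0], [4.0],
                                        grid=s["grid"])
        d = sk.deconvolve_components(fit)
        assert d["summary"]["early_rise"] == "lipid"
        assert d["summary"]["lipid_peak_us"] < d["summary"]["water_peak_us"]

    def test_components_sum_to_model(self, liposome_setup):
        s = liposome_setup
        tr = sk.generate_heterogeneous_trace(
            s["geom"], s["phases"], s["source"], 4.0, 3.43, 1.0, 5.0,
            sk.NoiseSpec(seed=1, scale=2500, dark_rate=2500), grid=s["grid"])
        _, fit = sk.scan_parameter_grid(tr, s["geom"], s["phases"],
                                        s["source"], [2.0], [4.0],
                                        grid=s["grid"])
        d = sk.deconvolve_components(fit)
        assert np.allclose(d["lipid"] + d["water"] + fit.C, fit.predict(),
                           atol=1e-12)


class TestModelSelection:
    def test_runs_test_detects_structure(self):
        rng = np.random.default_rng(0)
        random = rng.standard_normal(200)
        assert runs_test_pvalue(random) > 0.01
        structured = np.sin(np.linspace(0, 6 * np.pi, 200))
        assert runs_test_pvalue(structured) < 1e-6

    def test_homogeneous_trace_routed_homogeneous(self, noisy_water_trace):
        fit = sk.canonicalize_assignment(sk.fit_homogeneous(noisy_water_trace),
                                         3.5)
        rec = sk.select_model(fit, expected_tau_delta=3.5)
        assert rec.choice == "homogeneous"

    def test_wrong_expected_lifetime_triggers_heterogeneous(self,
                                                            noisy_water_trace):
        fit = sk.canonicalize_assignment(sk.fit_homogeneous(noisy_water_trace),
                                         3.5)
        rec = sk.select_model(fit, expected_tau_delta=66.0)  # D2O expectation
        assert rec.choice == "heterogeneous"
        assert "deviates" in rec.rationale


class TestGeometry:
    def test_outer_radius_from_lipid_fraction(self):
        g = sk.VesicleGeometry.from_lipid_fraction(0.01, r_core=46.0,
                                                   d_mem=4.0)
        v_lip = 50.0**3 - 46.0**3
        assert v_lip / g.r_cell**3 == pytest.approx(0.01)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValidationError):
            sk.VesicleGeometry(r_core=46.0, d_mem=4.0, r_cell=49.0)
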