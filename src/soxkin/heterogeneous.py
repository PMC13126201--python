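"""Diffusion-coupled ¹O₂ kinetics in lipid-vesicle suspensions.

A photosensitizer that partitions into lipid bilayers generates ¹O₂ in two
microenvironments with different lifetimes (τ_Δ,L ≈ 12–16 µs in the
membrane vs τ_Δ,W ≈ 3.5–4 µs in water), coupled by diffusion across the
interface.  The suspension is modelled as a mean-field spherical unit cell:
aqueous core, lipid shell of thickness d_mem, and an outer water shell
whose radius fixes the lipid volume fraction, with reflective boundaries.

The concentration obeys, in spherical symmetry,

    ∂c/∂t = D(r)·(1/r²) ∂/∂r ( r² ∂c/∂r ) − c/τ_Δ(r) + g(r, t)

with g(r,t) = w_phase/V_phase · (1/τ_T)·e^{−t/τ_T} (triplet-mediated
generation, total amount normalized to 1), flux continuity and a
concentration jump c_L = K·c_W at the interfaces.  The solver uses a
conservative finite-volume discretization in u = c/K(r) (which is
continuous across the interface), harmonic-mean face conductances of D·K,
and Crank–Nicolson stepping with two backward-Euler startup steps; the
per-step source is injected as its exact time integral so the cumulative
generated amount is analytic.

The detected signal is S(t) = A·n_L(t) + B·n_W(t) + C where n_L, n_W are
the phase-integrated ¹O₂ amounts (the basis functions) and A, B, C come
from weighted linear least squares (A, B ≥ 0).  τ_T and τ_Δ,W are found by
scanning a grid and locating the reduced-χ² minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse
from scipy.sparse.linalg import splu
from scipy.stats import norm

from .errors import FitError, NumericalError, ValidationError
from .homogeneous import HomogeneousFit
from .traces import KineticTrace

__all__ = [
    "VesicleGeometry", "PhaseParams", "SourceSpec", "SimGrid",
    "BasisFunctions", "HeterogeneousFit", "ChiSquareSurface", "ShellSolver",
    "simulate_basis", "mass_balance_residual", "fit_linear_combination",
    "scan_parameter_grid", "deconvolve_components", "select_model",
    "ModelRecommendation", "runs_test_pvalue",
]


@dataclass
class VesicleGeometry:
    """Unit cell: aqueous core | lipid membrane | outer water shell (nm)."""

    r_core: float = 46.0
    d_mem: float = 4.0
    r_cell: float = 250.0

    def __post_init__(self):
        if self.r_core < 0 or self.d_mem <= 0:
            raise ValidationError("r_core must be >= 0 and d_mem > 0")
        if self.r_cell <= self.r_core + self.d_mem:
            raise ValidationError("r_cell must exceed r_core + d_mem")

    @classmethod
    def from_lipid_fraction(cls, lipid_volume_fraction: float,
                            r_core: float = 46.0, d_mem: float = 4.0):
        """Outer cell radius such that the membrane occupies the given
        volume fraction of the suspension."""
        if not 0 < lipid_volume_fraction < 1:
            raise ValidationError("lipid volume fraction must be in (0, 1)")
        r_out = r_core + d_mem
        v_lipid = r_out**3 - r_core**3
        r_cell = (v_lipid / lipid_volume_fraction) ** (1.0 / 3.0)
        return cls(r_core, d_mem, float(r_cell))


@dataclass
class PhaseParams:
    """Transport and decay constants of the two phases.

    Diffusion coefficients in nm²/µs (2000 nm²/µs = 2×10⁻⁵ cm²/s).  The
    lipid lifetime is constrained to its literature range 12–16 µs unless
    ``allow_tau_L_outside`` is set.  K_partition is the lipid/water
    equilibrium concentration ratio at the interface (1 = continuity).
    """

    D_W: float = 2000.0
    D_L: float = 1000.0
    tau_delta_L: float = 14.0
    K_partition: float = 1.0
    allow_tau_L_outside: bool = False

    def __post_init__(self):
        if self.D_W <= 0 or self.D_L <= 0 or self.K_partition <= 0:
            raise ValidationError("D_W, D_L and K_partition must be positive")
        if self.tau_delta_L <= 0:
            raise ValidationError("tau_delta_L must be positive")
        if not self.allow_tau_L_outside and not 12.0 <= self.tau_delta_L <= 16.0:
            raise ValidationError(
                "tau_delta_L outside 12-16 µs; set allow_tau_L_outside to override")


@dataclass
class SourceSpec:
    """Triplet-mediated ¹O₂ generation: lifetime and phase localization.

    ``w_lipid``/``w_water`` are the fractions of the total generated amount
    produced in each phase (sensitizer localization); they must sum to 1.
    Generation is uniform within each phase.
    """

    tau_T: float
    w_lipid: float = 0.0
    w_water: float = 1.0

    def __post_init__(self):
        if self.tau_T <= 0:
            raise ValidationError("tau_T must be positive")
        if self.w_lipid < 0 or self.w_water < 0:
            raise ValidationError("source weights must be nonnegative")
        total = self.w_lipid + self.w_water
        if total > 0 and abs(total - 1.0) > 1e-9:
            raise ValidationError("source weights must sum to 1 (or both be 0)")


@dataclass
class SimGrid:
    """Temporal/spatial resolution of the shell simulation.

    ``dt`` is the internal step, ``dt_out`` the output sampling (must be an
    integer multiple of ``dt``); the membrane is resolved with
    ``n_mem_cells`` uniform cells and the water regions with geometrically
    graded cells starting at the membrane cell width.
    """

    t_max: float = 40.0
    dt_out: float = 0.1
    dt: float = 0.02
    n_mem_cells: int = 10
    growth: float = 1.35

    def __post_init__(self):
        if self.t_max <= 0 or self.dt <= 0 or self.dt_out <= 0:
            raise ValidationError("times and steps must be positive")
        if self.n_mem_cells < 8:
            raise ValidationError("membrane must be resolved with >= 8 cells")
        ratio = self.dt_out / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValidationError("dt_out must be an integer multiple of dt")


@dataclass
class BasisFunctions:
    """Phase-integrated ¹O₂ amounts on the output time grid (total
    generated amount normalized to 1)."""

    time: np.ndarray
    n_L: np.ndarray
    n_W: np.ndarray
    normalization: dict = field(default_factory=dict)


def _graded_widths(total: float, h0: float, growth: float) -> np.ndarray:
    if total <= 0:
        return np.empty(0)
    widths, s, h = [], 0.0, h0
    while s < total - 1e-12:
        w = min(h, total - s)
        widths.append(w)
        s += w
        h *= growth
    return np.asarray(widths)


class ShellSolver:
    """Factorized Crank–Nicolson operator for one (geometry, phases, τ_Δ,W).

    The linear operator is independent of the source, so a single
    factorization serves every triplet lifetime; :meth:`run_many` advances
    all requested τ_T values in one time loop (one multi-column solve per
    step).  This is what makes the χ² grid scan affordable.
    """

    def __init__(self, geom: VesicleGeometry, phases: PhaseParams,
                 tau_delta_W: float, grid: SimGrid):
        if tau_delta_W <= 0:
            raise ValidationError("tau_delta_W must be positive")
        self.geom, self.phases, self.grid = geom, phases, grid
        self.tau_delta_W = float(tau_delta_W)

        h_mem = geom.d_mem / grid.n_mem_cells
        w_core = _graded_widths(geom.r_core, h_mem, grid.growth)[::-1]
        w_mem = np.full(grid.n_mem_cells, h_mem)
        r_out = geom.r_core + geom.d_mem
        w_outer = _graded_widths(geom.r_cell - r_out, h_mem, grid.growth)
        widths = np.concatenate([w_core, w_mem, w_outer])
        edges = np.concatenate([[0.0], np.cumsum(widths)])
        edges[-1] = geom.r_cell
        self.edges = edges
        self.centers = 0.5 * (edges[:-1] + edges[1:])
        self.volume = 4.0 * np.pi / 3.0 * np.diff(edges**3)
        n = len(self.centers)
        self.is_lipid = (self.centers > geom.r_core) & (self.centers < r_out)
        if self.is_lipid.sum() < 8:
            raise ValidationError("membrane resolved with fewer than 8 cells")

        K = np.where(self.is_lipid, phases.K_partition, 1.0)
        D = np.where(self.is_lipid, phases.D_L, phases.D_W)
        tau = np.where(self.is_lipid, phases.tau_delta_L, tau_delta_W)
        self.K, self.tau = K, tau
        self.M = K * self.volume  # mass matrix diag: amount = M @ u

        # face conductances (amount/time per unit u difference)
        face_r = edges[1:-1]
        area = 4.0 * np.pi * face_r**2
        d_lo = face_r - self.centers[:-1]
        d_hi = self.centers[1:] - face_r
        G = area / (d_lo / (D[:-1] * K[:-1]) + d_hi / (D[1:] * K[1:]))

        diag = np.zeros(n)
        diag[:-1] -= G
        diag[1:] -= G
        diag -= self.M / self.tau
        L = sparse.diags([G, diag, G], offsets=[-1, 0, 1], format="csc")
        Mdiag = sparse.diags(self.M, format="csc")
        dt = grid.dt
        self._lu_cn = splu((Mdiag - 0.5 * dt * L).tocsc())
        self._B_cn = (Mdiag + 0.5 * dt * L).tocsc()
        # startup damping: the first full step is taken as backward-Euler
        # quarter-steps to suppress Crank-Nicolson ringing of stiff modes
        self._n_quarter = 4
        self._lu_be_q = splu((Mdiag - (dt / self._n_quarter) * L).tocsc())
        self._Mdiag = Mdiag

    def _source_shape(self, w_lipid: float, w_water: float) -> np.ndarray:
        q = np.zeros(len(self.centers))
        v_lip = float(self.volume[self.is_lipid].sum())
        v_wat = float(self.volume[~self.is_lipid].sum())
        if w_lipid > 0:
            q[self.is_lipid] = w_lipid * self.volume[self.is_lipid] / v_lip
        if w_water > 0:
            q[~self.is_lipid] = w_water * self.volume[~self.is_lipid] / v_wat
        return q

    def run_many(self, tau_Ts, w_lipid: float, w_water: float
                 ) -> list[BasisFunctions]:
        """Simulate basis functions for several triplet lifetimes at once."""
        tau_Ts = np.atleast_1d(np.asarray(tau_Ts, dtype=float))
        if np.any(tau_Ts <= 0):
            raise ValidationError("tau_T must be positive")
        g = self.grid
        n_sub = int(round(g.dt_out / g.dt))
        n_out = int(round(g.t_max / g.dt_out)) + 1
        t_out = np.arange(n_out) * g.dt_out
        q = self._source_shape(w_lipid, w_water)
        total_w = w_lipid + w_water

        n_cells, n_tau = len(q), len(tau_Ts)
        u = np.zeros((n_cells, n_tau))
        n_L = np.zeros((n_out, n_tau))
        n_W = np.zeros((n_out, n_tau))
        decayed = np.zeros((n_out, n_tau))
        dec_cum = np.zeros(n_tau)
        decay_coeff = (self.M / self.tau)[:, None]
        lip = self.is_lipid

        rate_prev = np.zeros(n_tau)
        t = 0.0
        step = 0
        for k_out in range(1, n_out):
            for _ in range(n_sub):
                if step == 0:
                    # damped startup: backward-Euler quarter-steps
                    dq = g.dt / self._n_quarter
                    for _q in range(self._n_quarter):
                        f = np.exp(-t / tau_Ts) - np.exp(-(t + dq) / tau_Ts)
                        S = q[:, None] * f[None, :]
                        u = self._lu_be_q.solve(self.M[:, None] * u + S)
                        rate = (decay_coeff * u).sum(axis=0)
                        dec_cum += dq * rate  # right-point rule matches BE
                        t += dq
                else:
                    # exact amount generated during the step, per tau_T
                    f = np.exp(-t / tau_Ts) - np.exp(-(t + g.dt) / tau_Ts)
                    S = q[:, None] * f[None, :]
                    u = self._lu_cn.solve(self._B_cn.dot(u) + S)
                    rate = (decay_coeff * u).sum(axis=0)
                    dec_cum += 0.5 * g.dt * (rate_prev + rate)
                    t += g.dt
                rate_prev = rate
                step += 1
            amount = self.M[:, None] * u
            if amount.min() < -1e-8 * max(amount.max(), 1e-30):
                raise NumericalError(
                    "negative concentrations beyond tolerance; reduce dt or "
                    "refine the spatial grid")
            n_L[k_out] = amount[lip].sum(axis=0)
            n_W[k_out] = amount[~lip].sum(axis=0)
            decayed[k_out] = dec_cum

        generated = total_w * (1.0 - np.exp(-t_out[:, None] / tau_Ts[None, :]))
        out = []
        for j, tau_T in enumerate(tau_Ts):
            out.append(BasisFunctions(
                t_out.copy(),
                np.maximum(n_L[:, j], 0.0),
                np.maximum(n_W[:, j], 0.0),
                {"generated": generated[:, j], "decayed": decayed[:, j],
                 "total": n_L[:, j] + n_W[:, j], "tau_T": float(tau_T),
                 "tau_delta_W": self.tau_delta_W,
                 "w_lipid": w_lipid, "w_water": w_water}))
        return out

    def run(self, source: SourceSpec) -> BasisFunctions:
        return self.run_many([source.tau_T], source.w_lipid, source.w_water)[0]


def simulate_basis(geom: VesicleGeometry, phases: PhaseParams,
                   source: SourceSpec, tau_delta_W: float,
                   grid: SimGrid | None = None) -> BasisFunctions:
    """Simulate n_L(t), n_W(t) for one (τ_T, τ_Δ,W) pair."""
    return ShellSolver(geom, phases, tau_delta_W, grid or SimGrid()).run(source)


def mass_balance_residual(basis: BasisFunctions) -> np.ndarray:
    """|generated − decayed − remaining| relative to the generated amount."""
    gen = basis.normalization["generated"]
    dec = basis.normalization["decayed"]
    rem = basis.n_L + basis.n_W
    return np.abs(gen - dec - rem) / np.maximum(gen, 1e-15)


# ---------------------------------------------------------------------------
# fitting


def _fit_weights(counts: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "poisson":
        return 1.0 / np.maximum(counts, 1.0)
    if scheme == "uniform":
        return np.ones_like(counts, dtype=float)
    raise ValidationError(f"unknown weighting scheme {scheme!r}")


def fit_linear_combination(trace: KineticTrace, basis: BasisFunctions,
                           weights: str = "poisson"
                           ) -> tuple[float, float, float, float]:
    """Weighted least squares of S = A·n_L + B·n_W + C with A, B ≥ 0.

    Basis functions are interpolated onto the trace grid.  Returns
    (A, B, C, χ²_red); warns with the condition number when the two basis
    columns are nearly collinear (the phases then cannot be separated).
    """
    t = trace.time
    y = np.asarray(trace.counts, float)
    nL = np.interp(t, basis.time, basis.n_L)
    nW = np.interp(t, basis.time, basis.n_W)
    w = _fit_weights(y, weights)
    sw = np.sqrt(w)
    X = np.column_stack([nL, nW, np.ones_like(t)])
    Xw = X * sw[:, None]
    cond = np.linalg.cond(Xw[:, :2]) if (nL.any() and nW.any()) else np.inf
    if cond > 1e8:
        warnings.warn(f"basis functions nearly collinear (cond={cond:.3g}); "
                      "A/B is ill-determined", stacklevel=2)
    res = optimize.lsq_linear(Xw, y * sw,
                              bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]))
    A, B, C = (float(v) for v in res.x)
    r = (X @ res.x - y) * sw
    chi2_red = float(np.sum(r**2)) / max(len(y) - 3, 1)
    return A, B, C, chi2_red


@dataclass
class HeterogeneousFit:
    A: float
    B: float
    C: float
    tau_T: float
    tau_delta_W: float
    chi2_red: float
    time: np.ndarray
    lipid_component: np.ndarray   # A·n_L on the trace grid
    water_component: np.ndarray   # B·n_W on the trace grid
    basis: BasisFunctions | None = None

    @property
    def AB_ratio(self) -> float | None:
        return self.A / self.B if self.B > 0 else None

    def predict(self) -> np.ndarray:
        return self.lipid_component + self.water_component + self.C


@dataclass
class ChiSquareSurface:
    tau_T_grid: np.ndarray
    tau_dW_grid: np.ndarray
    chi2_red: np.ndarray          # shape (len(tau_T), len(tau_dW))
    coeffs: np.ndarray            # shape (len(tau_T), len(tau_dW), 3)
    argmin: tuple[int, int]
    refined_min: tuple[float, float] | None = None


_basis_cache: dict[tuple, BasisFunctions] = {}


def _cache_key(geom, phases, grid, tau_dW, tau_T, w_lipid, w_water):
    return (round(geom.r_core, 6), round(geom.d_mem, 6), round(geom.r_cell, 6),
            round(phases.D_W, 6), round(phases.D_L, 6),
            round(phases.tau_delta_L, 6), round(phases.K_partition, 9),
            grid.t_max, grid.dt_out, grid.dt, grid.n_mem_cells, grid.growth,
            round(tau_dW, 9), round(tau_T, 9), round(w_lipid, 9), round(w_water, 9))


def scan_parameter_grid(trace: KineticTrace, geom: VesicleGeometry,
                        phases: PhaseParams, source_template: SourceSpec,
                        tau_T_values, tau_dW_values,
                        grid: SimGrid | None = None,
                        weights: str = "poisson", refine: bool = False
                        ) -> tuple[ChiSquareSurface, HeterogeneousFit]:
    """Scan (τ_T, τ_Δ,W), fitting (A, B, C) at every pair.

    The simulation operator depends only on τ_Δ,W, so each column of the
    surface reuses one matrix factorization and all triplet lifetimes are
    advanced in a single time loop.  Simulated bases are cached by rounded
    parameter key for repeated scans.  Returns the full χ²_red surface and
    the fit at the grid argmin (with optional 1-D parabolic sub-grid
    refinement of the minimum location, reported on the surface).
    """
    grid = grid or SimGrid()
    tau_T_values = np.sort(np.atleast_1d(np.asarray(tau_T_values, float)))
    tau_dW_values = np.sort(np.atleast_1d(np.asarray(tau_dW_values, float)))
    if np.any(tau_T_values <= 0) or np.any(tau_dW_values <= 0):
        raise ValidationError("scan ranges must be positive")
    wl, ww = source_template.w_lipid, source_template.w_water

    nT, nW_ = len(tau_T_values), len(tau_dW_values)
    chi2 = np.full((nT, nW_), np.nan)
    coeffs = np.full((nT, nW_, 3), np.nan)
    bases: dict[tuple[int, int], BasisFunctions] = {}
    failures = []
    for j, tau_dW in enumerate(tau_dW_values):
        missing = [i for i in range(nT)
                   if _cache_key(geom, phases, grid, tau_dW, tau_T_values[i],
                                 wl, ww) not in _basis_cache]
        if missing:
            try:
                solver = ShellSolver(geom, phases, tau_dW, grid)
                fresh = solver.run_many(tau_T_values[missing], wl, ww)
            except (NumericalError, ValidationError) as exc:
                failures.append((float(tau_dW), str(exc)))
                continue
            for i, b in zip(missing, fresh):
                _basis_cache[_cache_key(geom, phases, grid, tau_dW,
                                        tau_T_values[i], wl, ww)] = b
        for i in range(nT):
            basis = _basis_cache[_cache_key(geom, phases, grid, tau_dW,
                                            tau_T_values[i], wl, ww)]
            bases[(i, j)] = basis
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                A, B, C, c2 = fit_linear_combination(trace, basis, weights)
            chi2[i, j] = c2
            coeffs[i, j] = (A, B, C)

    if np.all(np.isnan(chi2)):
        raise FitError("all grid cells failed", {"failures": failures})
    i_min, j_min = np.unravel_index(np.nanargmin(chi2), chi2.shape)
    A, B, C = coeffs[i_min, j_min]
    best_basis = bases[(i_min, j_min)]
    if A + B <= 1e-12 * max(float(np.max(trace.counts)), 1.0):
        warnings.warn("degenerate surface: no resolvable signal (A ~ B ~ 0)",
                      stacklevel=2)

    refined = None
    if refine:
        refined = (_parabolic_min(tau_T_values, chi2[:, j_min], i_min),
                   _parabolic_min(tau_dW_values, chi2[i_min, :], j_min))

    t = trace.time
    fit = HeterogeneousFit(
        float(A), float(B), float(C),
        float(tau_T_values[i_min]), float(tau_dW_values[j_min]),
        float(chi2[i_min, j_min]), t.copy(),
        A * np.interp(t, best_basis.time, best_basis.n_L),
        B * np.interp(t, best_basis.time, best_basis.n_W),
        basis=best_basis)
    surface = ChiSquareSurface(tau_T_values, tau_dW_values, chi2, coeffs,
                               (int(i_min), int(j_min)), refined)
    return surface, fit


def _parabolic_min(x: np.ndarray, f: np.ndarray, i: int) -> float:
    if i == 0 or i == len(x) - 1 or not np.all(np.isfinite(f[i - 1:i + 2])):
        return float(x[i])
    denom = f[i - 1] - 2 * f[i] + f[i + 1]
    if denom <= 0:
        return float(x[i])
    shift = 0.5 * (f[i - 1] - f[i + 1]) / denom
    return float(x[i] + shift * (x[i + 1] - x[i]))


def deconvolve_components(fit: HeterogeneousFit) -> dict:
    """Split the fitted signal into its lipid and water contributions.

    Returns both component traces plus a summary naming which phase
    dominates the early rise and which the late decay (by comparing the
    component maxima positions).  Components sum with C to the full model
    prediction by construction.
    """
    summary: dict = {"flags": []}
    if fit.B <= 0:
        summary["flags"].append("water_component_undefined")
    lip, wat = fit.lipid_component, fit.water_component
    if lip.max() > 0 and wat.max() > 0:
        t_lip = float(fit.time[np.argmax(lip)])
        t_wat = float(fit.time[np.argmax(wat)])
        early = "lipid" if t_lip < t_wat else "water"
        summary.update(lipid_peak_us=t_lip, water_peak_us=t_wat,
                       early_rise=early,
                       late_decay="water" if early == "lipid" else "lipid")
    return {"lipid": lip.copy(), "water": wat.copy(), "summary": summary}


# ---------------------------------------------------------------------------
# model selection


def runs_test_pvalue(x: np.ndarray) -> float:
    """Two-sided Wald–Wolfowitz runs test on the signs of x (zeros dropped),
    normal approximation."""
    x = np.asarray(x, float)
    x = x[x != 0]
    n = len(x)
    if n < 5:
        return 1.0
    pos = x > 0
    n1, n2 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n2 == 0:
        return 0.0  # single-sign residuals: maximally structured
    runs = 1 + int(np.sum(pos[1:] != pos[:-1]))
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (runs - mu) / np.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


@dataclass
class ModelRecommendation:
    choice: str  # "homogeneous" | "heterogeneous"
    rationale: str
    diagnostics: dict = field(default_factory=dict)


def select_model(hom_fit: HomogeneousFit, expected_tau_delta: float,
                 tau_tolerance: float = 0.20,
                 runs_alpha: float = 0.05) -> ModelRecommendation:
    """Decide whether a homogeneous fit suffices or the diffusion-coupled
    model is required.

    Heterogeneous is recommended when the fitted τ_Δ deviates from the
    expected solvent value by more than ``tau_tolerance`` relative, or when
    a runs test on the weighted residuals in the first quarter of the time
    window rejects randomness (structured early residuals are the signature
    of unmodelled lipid-phase ¹O₂).
    """
    if expected_tau_delta <= 0:
        raise ValidationError("expected_tau_delta must be positive")
    tau_dev = abs(hom_fit.params.tau_delta - expected_tau_delta) / expected_tau_delta
    t = hom_fit.stats.time
    r = hom_fit.stats.residuals
    q1 = t[0] + 0.25 * (t[-1] - t[0])
    p_runs = runs_test_pvalue(r[t <= q1])
    diag = {"tau_delta_rel_dev": float(tau_dev), "runs_pvalue": float(p_runs),
            "tau_tolerance": tau_tolerance, "runs_alpha": runs_alpha}
    if tau_dev > tau_tolerance:
        return ModelRecommendation(
            "heterogeneous",
            f"fitted tau_delta {hom_fit.params.tau_delta:.3g} µs deviates "
            f"{100 * tau_dev:.0f}% from expected {expected_tau_delta:g} µs",
            diag)
    if p_runs < runs_alpha:
        return ModelRecommendation(
            "heterogeneous",
            f"structured early residuals (runs test p = {p_runs:.3g})", diag)
    return ModelRecommendation(
        "homogeneous",
        f"tau_delta within {100 * tau_tolerance:.0f}% of expected and early "
        "residuals consistent with randomness", diag)
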