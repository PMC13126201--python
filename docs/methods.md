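# Methods

This note documents the models implemented in `soxkin`, the numerical
choices behind them, the synthetic study conditions used by the test
suite and `scripts/acceptance.py`, and the limits of what the synthetic
data can demonstrate.

## 1. Homogeneous rise–decay kinetics

### Model

In a single phase, sensitized ¹O₂ kinetics follow two coupled first-order
steps: the sensitizer triplet decays with lifetime τ_T, transferring
energy to dissolved O₂, and the resulting ¹O₂ population decays with
lifetime τ_Δ.  The detected phosphorescence is proportional to the ¹O₂
population:

S(t) = α · τ_Δ/(τ_Δ − τ_T) · (e^−(t−t₀)/τ_Δ − e^−(t−t₀)/τ_T) + y₀,  t ≥ t₀,

and S = y₀ before the onset t₀.  Two exact identities serve as oracles
throughout the test suite:

* area: ∫(S − y₀)dt = α·τ_Δ over [t₀, ∞);
* peak position: t₀ + τ_Δτ_T/(τ_Δ − τ_T)·ln(τ_Δ/τ_T).

The curve is *shape-invariant* under exchanging the two lifetimes with α
rescaled so that α·τ_Δ is preserved, so a fit alone cannot say which
lifetime is which.  `canonicalize_assignment` relabels against the
expected solvent ¹O₂ lifetime (H₂O 3.5 µs, D₂O 66 µs, 7% EtOH(aq)
4.1 µs, air-saturated, room temperature) and records the decision; when
the two fitted lifetimes agree within 15% the assignment is flagged
ambiguous and both readings are reported in the note.

### Numerical evaluation

The difference of exponentials is computed as
e^{−x/τ_Δ}·(−expm1(−xδ)) with δ = 1/τ_T − 1/τ_Δ, which is stable for
nearly equal lifetimes; below 10⁻⁶ relative separation the analytic
limit α·(x/τ)e^{−x/τ} + y₀ is used.  Both branches agree to better than
10⁻⁵ across the switch.

### Fitting

Weighted nonlinear least squares (Levenberg–Marquardt via lmfit) with
per-bin weights:

* `poisson` (default): w_i = 1/max(counts_i, 1) — the variance of a
  photon-counting bin estimated by its own count;
* `uniform`: w_i = 1;
* an explicit weight array — used after off-band subtraction, where the
  correct variance is the sum of the channel variances, not the
  (floored) corrected counts.

Reported statistics: χ²_red = Σw r²/(N − p) and a weighted adjusted R².
Parameter uncertainties come from the scaled covariance (lmfit default);
with Poisson weights and a correct model χ²_red ≈ 1 and the scaling is
benign.  Initialization is multi-start: τ_Δ at the expected solvent
value, τ_T ∈ {0.3, 0.7, 1.5}·τ_Δ,expected, α from the observed peak, y₀
from the final 10% of the sweep; the start with the lowest χ²_red wins.
t₀ is free by default with lower bound 0 (fixing t₀ = 0 is only safe
when no artifact overlaps the rise); an independently measured triplet
lifetime can be pinned via `fixed_tau_T`.

### Diagnostics

* **Tail fitting** (`tail_fit_demo`): restricting a monoexponential fit
  to the decay phase couples the lifetimes and lengthens the apparent
  τ_Δ; the routine quantifies the bias and is flagged "not recommended".
* **Surplus analysis** (`surplus_analysis`): the late decay (t > 7 µs by
  default) is fitted with the rise–decay model and extrapolated; the
  residual over the full grid exposes early excess signal
  (lipid-phase ¹O₂ in vesicle samples).  A log-linear regression on the
  positive post-peak surplus yields rough (τ_T, amplitude) starting
  values that narrow the heterogeneous grid scan.  The exact form of
  this estimator is a package choice.
* **Linearity checks**: α vs absorbed fraction 1 − 10^−A by weighted
  regression (flags: intercept beyond 3σ; curvature by an F-test on an
  added quadratic term at the 5% level — the F-test is a package choice,
  the literature names only the symptom) and α vs pulse energy by
  through-origin regression (flag: any standardized residual beyond 3).
  `linear_range_end` is found by trimming the highest-x points until the
  flags clear.

## 2. Preprocessing and QC

* **Baseline (IBL)**: mean ± SD over a window, by default the final 10%
  of the sweep — valid when the signal has fully decayed within the
  acquisition (true for H₂O sweeps of ≥ 40 µs; D₂O needs an extended
  sweep or an explicit pre-trigger window).
* **STA detection**: the physical signal starts at the baseline
  (S(t₀) = y₀), so a sweep whose smoothed counts begin elevated by more
  than k·noise (k = 3) and descend carries a short-time artifact
  (scatter, detector transients, prompt sensitizer luminescence).  The
  crop point is the threshold-crossing into the k·noise band above the
  valley between spike and rise, extended by an exponential
  extrapolation of the spike (decay constant fitted on raw,
  spike-dominated bins) to the time where the artifact is buried at
  0.3× the local noise.  The burial factor trades residual-spike bias
  against loss of rise information; 0.3 keeps the residual below ~1σ
  summed over the first retained bins.  A manual policy (fixed crop
  time) and an off policy are available, and every decision is recorded
  in the QC report.
* **Time origin**: cropping removes bins before the STA end and shifts
  the axis so t = 0 is the excitation-pulse onset; retained counts are
  never modified.
* **Peak SNR**: (smoothed peak − baseline)/baseline SD, smoothing over
  5 bins.  Gates: ≥ 5 for a usable rise–decay separation, ≥ 50 targeted
  for liposome work.  Peak-based (not integrated) SNR is a package
  choice.
* **Off-band subtraction**: corrected = c₁₂₇₀ − weighted mean of the
  1250/1300 nm channels (default weights ½/½, configurable); negative
  bins floored at zero with the floored fraction flagged, and the
  propagated per-bin variance returned for downstream weighting.
* **Spectral validation**: Gaussian + constant fitted over ≥ 1240–1320
  nm.  The fitted center classifies the band: 1270–1281 nm zone of
  confidence (authentic ¹O₂ emission), 1260–1270 nm zone of deception
  (background-prone), otherwise outside.  Passing additionally requires
  a width between 1 nm and half the covered span (a sub-nm "band" is a
  line artifact) and a peak resolved at 3× the spectral noise.

## 3. Relative quantum yield

Φ_Δ = Φ_Δ^Std·(α/α_Std)·(1 − 10^−A_Std)/(1 − 10^−A), with first-order
propagation over the five independent inputs (Φ_Std, both amplitudes,
both absorbances), using d(1 − 10^−A)/dA = 10^−A ln10.  The
absorbance-matched flag (|A − A_Std| ≤ 0.02, a package tolerance) is
informational: σ is always the full propagation, because the inputs are
treated as independent and shrinking σ on a flag would break the
Monte-Carlo agreement the package itself tests (propagated σ vs 10⁵-draw
MC within 10% at input CVs ≤ 10%).  Matching absorbances nevertheless
helps in reality by cancelling correlated spectrometer errors — a
correlation the error model does not claim to know.  Φ > 1.2 raises a
nonphysical-yield warning.  No refractive-index corrections are applied.

The standards registry ships PN (0.98 ± 0.08) and riboflavin
(0.58 ± 0.06) as primary standards plus TMPyP (0.74) and Rose Bengal
(0.76) as cross-check entries without catalogued uncertainties; it is
user-extensible via CSV.  `recommend_standard` ranks candidates by
|log(α_cand/α_sample)| (closest signal magnitude first; ties by smaller
literature σ).

## 4. Diffusion-coupled liposome model

### Physical picture

A sensitizer associated with small unilamellar vesicles generates ¹O₂
partly in the bilayer (lifetime τ_Δ,L ≈ 12–16 µs) and partly in water
(τ_Δ,W ≈ 3.5–4 µs); ¹O₂ diffuses across the interface on sub-µs
timescales, so the two populations are strongly coupled.  The suspension
is reduced to a mean-field unit cell: aqueous core (radius r_core),
membrane (thickness d_mem), outer water shell out to r_cell (fixed by
the lipid volume fraction), reflective at both ends.

∂c/∂t = D(r)·(1/r²)∂/∂r(r²∂c/∂r) − c/τ_Δ(r) + g(r,t),
g(r,t) = (w_phase/V_phase)·(1/τ_T)e^{−t/τ_T},

with flux continuity and a partition jump c_L = K·c_W at the
interfaces.  The detected signal is S(t) = A·n_L(t) + B·n_W(t) + C with
n_L, n_W the phase-integrated amounts normalized to unit total
generation, so A and B are detector-weight coefficients and A/B a signal
ratio — not a yield ratio per phase.

### Defaults (config-overridable; chosen from general literature, not
measured here)

| parameter | default | unit | note |
|---|---|---|---|
| D_W | 2000 | nm²/µs | 2×10⁻⁵ cm²/s, O₂ in water |
| D_L | 1000 | nm²/µs | half the aqueous value |
| τ_Δ,L | 14 | µs | midpoint of 12–16 µs; guarded range |
| K | 1 | — | concentration continuity; configurable |
| r_core / d_mem / r_cell | 46 / 4 / 250 | nm | 50 nm SUV, ~0.2% lipid volume |

τ_Δ,L is deliberately range-guarded (12–16 µs) because the fit is
insensitive to it relative to interfacial transport — verified by the
test that moving it 12 → 16 µs shifts the best-fit grid cell by at most
one step.

### Discretization

Finite volumes on a spherical grid: the membrane uniformly resolved with
≥ 8 cells (default 10), water regions geometrically graded (ratio 1.35)
away from the interfaces.  The scheme solves for u = c/K(r), which is
continuous across the interface; face conductances use the harmonic mean
of D·K, making the discrete fluxes exactly continuous and the scheme
conservative to machine precision.  Time stepping is Crank–Nicolson with
the first step taken as four backward-Euler quarter-steps (damps the
startup ringing of stiff interface modes); the per-step source is
injected as its exact time integral, so cumulative generation is
analytic and the mass-balance residual
|generated − decayed − remaining| reflects only the consistency of the
decay quadrature (measured ~10⁻¹⁴, budgeted < 10⁻⁴).  Grid-halving
(dt/2, doubled membrane cells) moves the basis functions by < 0.5% of
their peaks at the default resolution; in the homogeneous limit
(equal D, equal τ, K = 1) the summed basis reproduces the closed-form
rise–decay kernel within 1% of its peak (measured ~10⁻³%).

### Coefficient fit and grid scan

(A, B, C) by weighted linear least squares with A, B ≥ 0 (emission
weights are physical) and C free (baseline); near-collinear bases raise
an ill-conditioning warning with the condition number.  The (τ_T, τ_Δ,W)
grid scan exploits the operator structure: the linear operator depends
on τ_Δ,W but not τ_T, so each τ_Δ,W column factorizes one matrix and
advances all triplet lifetimes in a single multi-column time loop;
simulated bases are cached by rounded parameter key.  Default grid step
0.1 µs in both axes.  Optional 1-D parabolic interpolation refines the
minimum below the grid step; it is off by default and never moves the
reported grid argmin.

The (τ_T, τ_Δ,W, A/B) estimate is efficient in the Fisher sense — its
scatter at the study conditions matches the Cramér–Rao bound computed
from the Poisson information — so the quoted recovery tolerances are
statistical, not algorithmic, limits.

### Model selection

Heterogeneous analysis is recommended when the homogeneous fit's τ_Δ
deviates from the expected solvent value by > 20%, or when a
Wald–Wolfowitz runs test (normal approximation, hand-implemented; no
stable library version exists) rejects sign-randomness of the weighted
residuals in the first quarter of the time window at the 5% level —
structured early residuals being the signature of unmodelled lipid-phase
¹O₂.  Both thresholds are configurable.

## 5. Synthetic data: what it emulates, and what it does not

The generator draws independent Poisson counts per bin around
μ_i = scale·model(t_i)/model_peak + dark + STA, with the STA an additive
fast exponential from the sweep start.  Effective post-scaling
parameters are recorded in the trace metadata as the recovery oracle,
and identical seeds give bit-identical traces.

Canonical study conditions (fixed once; all tests and the acceptance
script use them):

* **Water**: τ_Δ = 3.5 µs, τ_T = 2.0 µs, t₀ = 0.2 µs, 0.05 µs bins to
  40 µs, peak 500 counts over a 100 counts/bin dark level — peak
  SNR 50.  The 0.2 µs onset delay is the physically resolvable lag the
  free-t₀ fit is designed to estimate.  Measured over 200 seeds: median
  lifetime errors 2–3%, 68%-interval coverage 0.66–0.67.
* **D₂O**: τ_Δ = 66 µs, sweep extended to 700 µs.
* **Liposome (Pheo/DPPC-like)**: lipid-localized generation,
  τ_Δ,W ≈ 4 µs, A/B = 3.43, 20 ns bins, peak 2500 counts over 2500
  dark — peak SNR 50 at long-average acquisition depth (high-dark-rate
  NIR PMT, ~10⁶ sweeps).  Peak SNR alone does not fix the information
  content of a trace; the binning and depth were set to a realistic
  averaged acquisition.  At these conditions the Cramér–Rao bound gives
  sd(τ_T) ≈ 0.05 µs, sd(τ_Δ,W) ≈ 0.06 µs and sd(A/B) ≈ 10%, so
  single-trace A/B recovery at 10% is a ~1σ statement; the acceptance
  script therefore reports medians over 5 replicate acquisitions.
* **STA for the recovery pipeline**: amplitude 20× peak with 0.05 µs
  decay — a fast scatter spike satisfying the validity condition that
  the artifact be much shorter than the rise.  A slower 0.2 µs spike
  (the detection-band test case) hides so much of the rise that even
  perfectly cropped traces lose τ_T beyond the 5% recovery budget;
  that is an information limit of the data, not of the detector.

Not modelled: detector afterpulsing and pile-up (beyond the parametric
spike), instrument response convolution, inner-filter geometry, vesicle
size polydispersity, O₂ concentration gradients, quencher kinetics.
Passing tests therefore demonstrate correctness of the estimators under
ideal counting statistics — they do not certify behavior under
instrument systematics absent from the noise model.

## 6. Known limitations

* The homogeneous fit covariance is curvature-based; strongly correlated
  (τ_Δ ≈ τ_T) fits report honest but wide, correlated uncertainties and
  are flagged ambiguous rather than resolved.
* The unit-cell model is monodisperse; real SUV preparations average
  over a size distribution.
* A/B from a single trace at peak SNR 50 carries ~10% statistical
  scatter (Cramér–Rao); replicate acquisitions are the remedy, not
  tighter fitting.
* The linear-range estimator trims from the highest x downward; it will
  not isolate nonlinearity confined to the interior of the range.
* Off-band subtraction assumes the background spectrum is flat across
  1250–1300 nm; a sloped background leaves a residual.
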