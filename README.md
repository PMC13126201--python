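# soxkin — singlet-oxygen phosphorescence kinetics

`soxkin` analyzes time-resolved near-infrared phosphorescence of singlet
oxygen (¹O₂, ¹Δg) detected at 1270 nm after pulsed excitation of a
photosensitizer.  It is written for photochemists and photobiologists who
quantify ¹O₂ production and decay — in photodynamic-therapy development,
sensitizer screening, and membrane photochemistry — and who need the
fitting choices (baseline, artifact cropping, time origin, weighting,
model selection) to be explicit, automated and reproducible instead of
hand-tuned per trace.

## The models

**Homogeneous solution.**  ¹O₂ is generated by the sensitizer triplet
(lifetime τ_T) and decays with its own lifetime τ_Δ, giving the
rise–decay signal

    S(t) = α · τ_Δ/(τ_Δ − τ_T) · ( e^−(t−t₀)/τ_Δ − e^−(t−t₀)/τ_T ) + y₀,   t₀ ≥ 0

fitted by weighted nonlinear least squares with Poisson (photon-counting)
weights.  Because the curve is invariant under exchanging τ_Δ ↔ τ_T (with
α rescaled to preserve α·τ_Δ), the package resolves the label against the
expected solvent lifetime (3.5 µs in air-saturated H₂O, 66 µs in D₂O,
4.1 µs in 7% aqueous EtOH).  Supporting diagnostics: baseline (IBL)
estimation, short-time-artifact (STA) detection and cropping, peak-SNR
gating, off-band (1250/1300 nm) background subtraction, Gaussian spectral
validation of the 1270–1281 nm emission band, linearity checks of α
against the absorbed fraction 1 − 10^−A(λ_EX) and against pulse energy,
and the tail-fit bias demonstration.

**Relative quantum yield.**  Against a reference sensitizer of known
Φ_Δ^Std measured under identical conditions,

    Φ_Δ = Φ_Δ^Std · (α/α_Std) · (1 − 10^−A_Std) / (1 − 10^−A)

with full first-order error propagation over the five uncertain inputs
and a registry of literature standards (phenalenone 0.98 ± 0.08,
riboflavin 0.58 ± 0.06, …).

**Liposome suspensions.**  When the sensitizer partitions into lipid
bilayers, ¹O₂ forms and decays in two coupled microenvironments.  The
vesicle is modelled as concentric spherical shells (aqueous core, lipid
membrane, outer water cell) and the reaction–diffusion equation

    ∂c/∂t = D(r)·(1/r²) ∂/∂r( r² ∂c/∂r ) − c/τ_Δ(r) + g(r,t)

is integrated by a conservative finite-volume / Crank–Nicolson scheme to
produce basis functions n_L(t), n_W(t) (¹O₂ amount in lipid and water).
The signal is fitted as S(t) = A·n_L(t) + B·n_W(t) + C, and (τ_T, τ_Δ,W)
are located by a reduced-χ² grid scan; A/B is the lipid/water signal
weight ratio.  A model-selection rule (lifetime agreement + runs test on
early residuals) decides when this machinery is needed.

A seeded synthetic-data generator (Poisson counting noise, dark baseline,
parametric STA spikes, spectra, linearity series) makes the entire stack
testable without instrument data.

## Worked example

```python
import soxkin as sk

# synthetic acquisition: tau_delta 3.5 us, tau_T 2.0 us, peak SNR 50
params = sk.HomogeneousParams(alpha=100.0, tau_delta=3.5, tau_T=2.0, t0=0.2)
trace = sk.generate_homogeneous_trace(params, sk.NoiseSpec(seed=5))

baseline = sk.estimate_baseline(trace)
print(f"baseline: {baseline.y0_hat:.1f} +- {baseline.sigma:.1f} counts/bin")
print(f"peak SNR: {sk.peak_snr(trace, baseline):.1f}")

fit = sk.canonicalize_assignment(sk.fit_homogeneous(trace),
                                 expected_tau_delta=3.5)
p, u = fit.params, fit.uncertainties
print(f"tau_delta = {p.tau_delta:.2f} +- {u['tau_delta']:.2f} us")
print(f"tau_T     = {p.tau_T:.2f} +- {u['tau_T']:.2f} us")
print(f"chi2_red  = {fit.stats.chi2_red:.3f}   adj-R2 = {fit.stats.adj_r2:.4f}")

qy = sk.relative_quantum_yield((77.6, 1.6, 0.10, 0.002),
                               (100.0, 2.0, 0.10, 0.002),
                               sk.STANDARDS["PN"])
print(f"Phi_Delta = {qy.phi_delta:.2f} +- {qy.sigma:.2f}")
```

prints

```
baseline: 99.0 +- 10.0 counts/bin
peak SNR: 51.8
tau_delta = 3.51 +- 0.11 us
tau_T     = 2.01 +- 0.08 us
chi2_red  = 1.034   adj-R2 = 0.9824
Phi_Delta = 0.76 +- 0.07
```

The fitted lifetimes recover the generating values within their quoted
1σ; a reduced χ² near one says the Poisson noise model accounts for the
residuals; and the quantum yield of a sample whose amplitude is 77.6% of
the phenalenone standard at matched absorbance is 0.76 ± 0.07, the
uncertainty being dominated by the standard's own ±0.08.

A command-line interface mirrors the library:

```sh
soxkin simulate hom --seed 1 --out trace.csv
soxkin qc trace.csv
soxkin fit-hom --trace trace.csv --expected-tau-delta 3.5 --out fit.json
soxkin fit-het --trace liposome.csv --taut 1.5:2.4:0.1 --taudw 3.6:4.6:0.1
```

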