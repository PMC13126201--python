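"""Seeded synthetic datasets emulating the instrument's observables.

Photon counting makes the noise model simple and faithful: expected counts
per bin are the kinetic model plus a constant dark/background level (IBL)
and, optionally, an additive fast-exponential spike at the sweep start (the
short-time artifact), and the observed counts are Poisson draws per bin.
Detector afterpulsing and pile-up are not modelled beyond that parametric
spike.  Every generator records its effective (post-scaling) parameters in
the trace metadata so recovery tests have an exact oracle, and identical
seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .heterogeneous import (PhaseParams, SimGrid, SourceSpec, VesicleGeometry,
                            simulate_basis)
from .homogeneous import HomogeneousParams, eval_model, peak_time
from .traces import EmissionSpectrum, KineticTrace

__all__ = ["STASpec", "NoiseSpec", "generate_homogeneous_trace",
           "generate_heterogeneous_trace", "generate_linearity_series",
           "generate_nir_spectrum"]


@dataclass
class STASpec:
    """Additive short-time artifact: amplitude is a multiple of the signal
    peak (scale-free), decaying exponentially from ``start_us``."""

    amplitude: float = 20.0
    decay_us: float = 0.2
    start_us: float = 0.0

    def __post_init__(self):
        if self.decay_us <= 0:
            raise ValidationError("STA decay constant must be positive")
        if self.amplitude < 0 or self.start_us < 0:
            raise ValidationError("STA amplitude and start must be nonnegative")


@dataclass
class NoiseSpec:
    """Counting-noise model: expected peak counts, dark level, optional STA.

    ``poisson=False`` returns the noiseless expected counts (real-valued),
    used for exact-recovery oracles.
    """

    seed: int = 0
    scale: float = 500.0      # expected peak counts above baseline
    dark_rate: float = 100.0  # baseline counts per bin (IBL); peak SNR 50
    sta: STASpec | None = None
    poisson: bool = True

    def __post_init__(self):
        if self.scale <= 0:
            raise ValidationError("scale must be positive")
        if self.dark_rate < 0:
            raise ValidationError("dark_rate must be nonnegative")


def _emit(time: np.ndarray, mu: np.ndarray, noise: NoiseSpec,
          meta: dict) -> KineticTrace:
    if noise.sta is not None:
        s = noise.sta
        sta = np.where(time >= s.start_us,
                       s.amplitude * noise.scale
                       * np.exp(-np.maximum(time - s.start_us, 0) / s.decay_us),
                       0.0)
        mu = mu + sta
        meta["sta_injected"] = (f"amp={s.amplitude:g}x peak, "
                                f"decay={s.decay_us:g} us, start={s.start_us:g} us")
    if noise.poisson:
        rng = np.random.default_rng(noise.seed)
        counts = rng.poisson(mu)
    else:
        counts = mu
    meta["seed"] = str(noise.seed)
    return KineticTrace(time, counts, channel_nm=1270.0, meta=meta)


def generate_homogeneous_trace(params: HomogeneousParams, noise: NoiseSpec,
                               t_max: float = 40.0, dt: float = 0.05
                               ) -> KineticTrace:
    """Poisson photon-counting trace following the rise–decay model.

    The model shape (baseline-free) is rescaled so its peak equals
    ``noise.scale`` counts, then ``dark_rate`` is added.  The effective
    amplitude after rescaling, together with all other generating
    parameters, is stored in the metadata (keys ``true_*``).
    """
    if t_max < 10 * max(params.tau_delta, params.tau_T):
        raise ValidationError("t_max must cover >= 10x the slower lifetime")
    if dt > params.tau_T / 10:
        raise ValidationError("dt must resolve the rise (dt <= tau_T/10)")
    time = np.arange(0.0, t_max + dt / 2, dt)
    shape = eval_model(
        HomogeneousParams(params.alpha, params.tau_delta, params.tau_T,
                          params.t0, 0.0), time)
    s_peak = float(eval_model(
        HomogeneousParams(params.alpha, params.tau_delta, params.tau_T,
                          params.t0, 0.0), [peak_time(params)])[0])
    factor = noise.scale / s_peak
    mu = factor * shape + noise.dark_rate
    meta = {
        "generator": "homogeneous",
        "true_alpha": repr(params.alpha * factor),
        "true_tau_delta": repr(params.tau_delta),
        "true_tau_T": repr(params.tau_T),
        "true_t0": repr(params.t0),
        "true_y0": repr(noise.dark_rate),
    }
    return _emit(time, mu, noise, meta)


def generate_heterogeneous_trace(geom: VesicleGeometry, phases: PhaseParams,
                                 source: SourceSpec, tau_delta_W: float,
                                 A: float, B: float, C: float,
                                 noise: NoiseSpec,
                                 t_max: float = 40.0, dt: float = 0.1,
                                 grid: SimGrid | None = None
                                 ) -> KineticTrace:
    """Poisson trace following S = A·n_L + B·n_W + C on simulated bases.

    A·n_L + B·n_W is rescaled so its peak equals ``noise.scale``; the
    rescaled effective coefficients (which preserve A/B) and the generating
    parameters are stored in the metadata.
    """
    if A < 0 or B < 0:
        raise ValidationError("A and B must be nonnegative")
    grid = grid or SimGrid(t_max=t_max, dt_out=dt, dt=dt / 5.0)
    basis = simulate_basis(geom, phases, source, tau_delta_W, grid)
    model = A * basis.n_L + B * basis.n_W
    peak = float(np.max(model))
    if peak <= 0:
        raise ValidationError("zero model signal; check A, B and the source")
    factor = noise.scale / peak
    mu = factor * model + C + noise.dark_rate
    meta = {
        "generator": "heterogeneous",
        "true_A": repr(A * factor), "true_B": repr(B * factor),
        "true_C": repr(C + noise.dark_rate),
        "true_AB_ratio": repr(A / B) if B > 0 else "inf",
        "true_tau_T": repr(source.tau_T),
        "true_tau_delta_W": repr(tau_delta_W),
        "true_w_lipid": repr(source.w_lipid),
    }
    return _emit(basis.time.copy(), mu, noise, meta)


def generate_linearity_series(kind: str, n_points: int = 10,
                              slope: float = 1000.0,
                              distortion: str = "none", seed: int = 0,
                              noise_rel: float = 0.01) -> np.ndarray:
    """Synthetic (x, α, σ_α) tables for the linearity diagnostics.

    ``kind="absorbance"`` spans A = 0.05–0.30 (extended to 0.50 under the
    saturation distortion so the nonlinear onset at A > 0.3 is visible);
    ``kind="power"`` spans 1–6 mJ with the photobleaching bend starting at
    4 mJ.  Distortions: ``none``, ``saturation`` (response bends to 40% of
    the linear slope beyond the onset), ``offset`` (constant additive
    background of 10σ).
    """
    if n_points < 3:
        raise ValidationError("need >= 3 points")
    if distortion not in ("none", "saturation", "offset"):
        raise ValidationError(f"unknown distortion {distortion!r}")
    rng = np.random.default_rng(seed)
    if kind == "absorbance":
        hi = 0.50 if distortion == "saturation" else 0.30
        A = np.linspace(0.05, hi, n_points)
        x = 1.0 - 10.0 ** (-A)
        onset = 1.0 - 10.0 ** (-0.3)
        raw = A
    elif kind == "power":
        x = np.linspace(1.0, 6.0, n_points)
        onset = 4.0
        raw = x
    else:
        raise ValidationError(f"unknown kind {kind!r}")
    alpha = slope * x
    if distortion == "saturation":
        bend = x > onset
        alpha[bend] = slope * (onset + 0.4 * (x[bend] - onset))
    sigma = noise_rel * float(np.max(alpha))
    alpha = alpha + rng.normal(0.0, sigma, size=n_points)
    if distortion == "offset":
        alpha = alpha + 10.0 * sigma
    return np.column_stack([raw, alpha, np.full(n_points, sigma)])


def generate_nir_spectrum(center_nm: float = 1273.0, width_nm: float = 6.0,
                          background: str = "flat", seed: int = 0,
                          amplitude: float = 1000.0,
                          noise_rel: float = 0.02) -> EmissionSpectrum:
    """Gaussian NIR emission band (1230–1330 nm) over a chosen background.

    ``background="broad"`` adds a wide luminescence pedestal centered in
    the zone of deception, emulating sensitizer phosphorescence tails.
    """
    if not 1240 <= center_nm <= 1320:
        raise ValidationError("center must lie within 1240-1320 nm")
    rng = np.random.default_rng(seed)
    wl = np.arange(1230.0, 1330.0 + 0.25, 0.5)
    width = max(width_nm, 1e-6)
    y = amplitude * np.exp(-0.5 * ((wl - center_nm) / width) ** 2)
    if background == "flat":
        y = y + 0.05 * amplitude
    elif background == "broad":
        y = y + 0.2 * amplitude * np.exp(-0.5 * ((wl - 1255.0) / 40.0) ** 2)
    else:
        raise ValidationError(f"unknown background {background!r}")
    y = y + rng.normal(0.0, noise_rel * amplitude, size=len(wl))
    return EmissionSpectrum(wl, y, atmosphere="air")
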