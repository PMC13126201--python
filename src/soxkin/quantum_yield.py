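"""Relative singlet-oxygen quantum yields with first-order error propagation.

The relative method compares the fitted signal amplitude α of a sample
against a reference photosensitizer of known Φ_Δ measured under identical
conditions (same solvent, excitation wavelength, geometry):

    Φ_Δ = Φ_Δ^Std · (α / α_Std) · (1 − 10^−A_Std) / (1 − 10^−A)

where A is the decadic absorbance at the excitation wavelength, so
1 − 10^−A is the absorbed fraction of the incident light.  Matching A and
A_Std makes the absorbance ratio unity and removes its contribution to the
systematic error budget; the flag is reported, but the returned σ is always
the full first-order propagation over the five independent inputs
(Φ_Std, α, α_Std, A, A_Std).  No refractive-index corrections are applied.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["StandardEntry", "QYResult", "absorbed_fraction",
           "relative_quantum_yield", "recommend_standard",
           "STANDARDS", "load_standards"]

LN10 = float(np.log(10.0))
MATCHED_ABS_TOL = 0.02  # absorbance units


@dataclass
class StandardEntry:
    """A reference photosensitizer with a literature Φ_Δ."""

    name: str
    phi_delta: float
    phi_sigma: float
    solvent: str
    lambda_min_nm: float
    lambda_max_nm: float
    note: str = ""

    def __post_init__(self):
        if not 0 < self.phi_delta <= 1:
            raise ValidationError("phi_delta must be in (0, 1]")
        if self.phi_sigma < 0:
            raise ValidationError("phi_sigma must be nonnegative")


#: Built-in registry.  PN and riboflavin carry literature uncertainties;
#: the TMPyP and Rose Bengal entries are cross-check values cited without a
#: stated uncertainty and should not be used as primary standards.
STANDARDS: dict[str, StandardEntry] = {
    "PN": StandardEntry("PN", 0.98, 0.08, "H2O", 310.0, 420.0,
                        note="phenalenone; high-efficiency reference"),
    "riboflavin": StandardEntry("riboflavin", 0.58, 0.06, "H2O", 370.0, 470.0),
    "TMPyP": StandardEntry("TMPyP", 0.74, 0.0, "H2O", 400.0, 450.0,
                           note="cross-check entry; uncertainty not catalogued"),
    "RoseBengal": StandardEntry("RoseBengal", 0.76, 0.0, "H2O", 520.0, 570.0,
                                note="cross-check entry; uncertainty not catalogued"),
}


def load_standards(path) -> dict[str, StandardEntry]:
    """Load a user registry CSV: name,phi,sigma,solvent,lambda_min,lambda_max."""
    with open(path, "r", encoding="utf-8") as fh:
        text = "\n".join(l for l in fh.read().splitlines()
                         if l.strip() and not l.lstrip().startswith("#"))
    df = pd.read_csv(io.StringIO(text))
    required = {"name", "phi", "sigma", "solvent", "lambda_min", "lambda_max"}
    if not required.issubset(df.columns):
        raise ValidationError(f"standards CSV must have columns {sorted(required)}")
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.name)] = StandardEntry(str(row.name), float(row.phi),
                                           float(row.sigma), str(row.solvent),
                                           float(row.lambda_min), float(row.lambda_max))
    return out


@dataclass
class QYResult:
    phi_delta: float
    sigma: float
    inputs: dict = field(default_factory=dict)
    absorbance_matched: bool = False
    flags: list = field(default_factory=list)


def absorbed_fraction(A: float) -> float:
    """Fraction of incident light absorbed at decadic absorbance A: 1 − 10^−A."""
    if A < 0:
        raise ValidationError("absorbance must be nonnegative")
    return float(-np.expm1(-LN10 * A))


def relative_quantum_yield(sample: tuple[float, float, float, float],
                           standard: tuple[float, float, float, float],
                           std_entry: StandardEntry) -> QYResult:
    """Relative Φ_Δ with 1σ from first-order (delta-method) propagation.

    ``sample`` and ``standard`` are (α, σ_α, A, σ_A).  The five uncertain
    inputs (Φ_Std and both amplitude/absorbance pairs) are treated as
    independent; the absorbance sensitivity uses
    d(1−10^−A)/dA = 10^−A·ln10.  Caller asserts identical solvent and
    excitation wavelength for the two measurements.
    """
    alpha, s_alpha, A, s_A = map(float, sample)
    alpha_s, s_alpha_s, A_s, s_A_s = map(float, standard)
    if alpha_s <= 0:
        raise ZeroDivisionError("standard amplitude must be positive")
    if A <= 0 or A_s <= 0:
        raise ValidationError("absorbances must be positive")
    if alpha < 0 or min(s_alpha, s_A, s_alpha_s, s_A_s) < 0:
        raise ValidationError("amplitudes and uncertainties must be nonnegative")

    f, f_s = absorbed_fraction(A), absorbed_fraction(A_s)
    phi = std_entry.phi_delta * (alpha / alpha_s) * (f_s / f)

    # relative variance: ratio/product form plus absorbance chain terms
    df_dA = 10.0 ** (-A) * LN10
    df_s_dA = 10.0 ** (-A_s) * LN10
    rel_var = 0.0
    if std_entry.phi_delta > 0:
        rel_var += (std_entry.phi_sigma / std_entry.phi_delta) ** 2
    if alpha > 0:
        rel_var += (s_alpha / alpha) ** 2
    rel_var += (s_alpha_s / alpha_s) ** 2
    rel_var += (df_dA * s_A / f) ** 2
    rel_var += (df_s_dA * s_A_s / f_s) ** 2
    sigma = abs(phi) * float(np.sqrt(rel_var))

    matched = abs(A - A_s) <= MATCHED_ABS_TOL
    flags = []
    if phi > 1.2:
        flags.append("nonphysical_phi")
        warnings.warn(f"relative quantum yield {phi:.3g} exceeds 1.2", stacklevel=2)
    inputs = {"alpha": alpha, "alpha_sigma": s_alpha, "A": A, "A_sigma": s_A,
              "alpha_std": alpha_s, "alpha_std_sigma": s_alpha_s,
              "A_std": A_s, "A_std_sigma": s_A_s,
              "phi_std": std_entry.phi_delta, "phi_std_sigma": std_entry.phi_sigma,
              "standard": std_entry.name}
    return QYResult(phi, sigma, inputs, matched, flags)


def recommend_standard(sample_alpha: float,
                       candidates: list[tuple[StandardEntry, float]]
                       ) -> list[tuple[StandardEntry, float]]:
    """Rank candidate standards by amplitude match to the sample.

    ``candidates`` pairs each registry entry with its measured α under
    conditions identical to the sample.  Ranking is ascending
    |log(α_candidate / α_sample)| (closest signal magnitude first), ties
    broken by the smaller literature uncertainty.
    """
    if not candidates:
        raise ValidationError("no candidate standards supplied")
    if sample_alpha <= 0:
        raise ValidationError("sample amplitude must be positive")
    for entry, a in candidates:
        if a <= 0:
            raise ValidationError(f"candidate {entry.name} has nonpositive amplitude")
    return sorted(candidates,
                  key=lambda ca: (abs(np.log(ca[1] / sample_alpha)), ca[0].phi_sigma))
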