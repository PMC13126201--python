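"""Analysis configuration: one YAML file, strict keys, validated defaults.

The config mirrors the pipeline stages.  Every key has a default so an empty
file is a valid config; unknown keys are rejected (typos must not silently
fall back to defaults).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ValidationError

__all__ = ["AnalysisConfig", "PreprocessOptions", "FitOptions",
           "HeterogeneousOptions", "SyntheticOptions", "read_config"]


@dataclass
class PreprocessOptions:
    baseline_window: tuple[float, float] | None = None  # µs; None -> final fraction
    baseline_fraction: float = 0.10
    sta_policy: str = "auto"  # auto | manual | off
    sta_k: float = 3.0
    sta_crop_us: float | None = None  # used when sta_policy == "manual"
    smooth_bins: int = 5
    offband_weights: tuple[float, float] = (0.5, 0.5)  # 1250 nm, 1300 nm

    def validate(self):
        if self.sta_policy not in ("auto", "manual", "off"):
            raise ValidationError(f"preprocess.sta_policy: unknown policy {self.sta_policy!r}")
        if self.sta_policy == "manual" and self.sta_crop_us is None:
            raise ValidationError("preprocess.sta_crop_us required when sta_policy is manual")
        if self.sta_k <= 0:
            raise ValidationError("preprocess.sta_k must be positive")
        if not 0 < self.baseline_fraction < 1:
            raise ValidationError("preprocess.baseline_fraction must be in (0, 1)")
        if self.smooth_bins < 1:
            raise ValidationError("preprocess.smooth_bins must be >= 1")


@dataclass
class FitOptions:
    fix_t0: bool = False
    expected_tau_delta: float = 3.5  # µs; air-saturated H2O
    weights: str = "poisson"  # poisson | uniform
    ambiguity_band: float = 0.15  # report both lifetime assignments below this
    tail_start_us: float = 7.0

    def validate(self):
        if self.expected_tau_delta <= 0:
            raise ValidationError("fit.expected_tau_delta must be positive")
        if self.weights not in ("poisson", "uniform"):
            raise ValidationError(f"fit.weights: unknown scheme {self.weights!r}")
        if self.tail_start_us <= 0:
            raise ValidationError("fit.tail_start_us must be positive")


@dataclass
class HeterogeneousOptions:
    r_core_nm: float = 46.0
    d_mem_nm: float = 4.0
    r_cell_nm: float = 250.0
    D_W: float = 2000.0  # nm^2/µs (2e-5 cm^2/s); not from this study
    D_L: float = 1000.0  # nm^2/µs; not from this study
    tau_delta_L: float = 14.0  # µs, midpoint of the 12-16 µs literature range
    K_partition: float = 1.0
    tau_T_range: tuple[float, float] = (1.0, 3.0)
    tau_T_step: float = 0.1
    tau_dW_range: tuple[float, float] = (3.0, 5.0)
    tau_dW_step: float = 0.1

    def validate(self):
        for name in ("d_mem_nm", "D_W", "D_L", "tau_delta_L", "K_partition",
                     "tau_T_step", "tau_dW_step"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"heterogeneous.{name} must be positive")
        if self.r_core_nm < 0:
            raise ValidationError("heterogeneous.r_core_nm must be nonnegative")
        if self.r_cell_nm <= self.r_core_nm + self.d_mem_nm:
            raise ValidationError("heterogeneous.r_cell_nm must exceed r_core_nm + d_mem_nm")
        for name in ("tau_T_range", "tau_dW_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValidationError(f"heterogeneous.{name} must be a positive nonempty range")


@dataclass
class SyntheticOptions:
    seed: int = 0
    scale: float = 500.0  # expected peak counts above baseline (peak SNR 50)
    dark_rate: float = 100.0  # baseline counts per bin

    def validate(self):
        if not float(self.seed).is_integer():
            raise ValidationError("synthetic.seed must be an integer")
        if self.scale <= 0:
            raise ValidationError("synthetic.scale must be positive")
        if self.dark_rate < 0:
            raise ValidationError("synthetic.dark_rate must be nonnegative")


@dataclass
class AnalysisConfig:
    preprocess: PreprocessOptions = field(default_factory=PreprocessOptions)
    fit: FitOptions = field(default_factory=FitOptions)
    heterogeneous: HeterogeneousOptions = field(default_factory=HeterogeneousOptions)
    synthetic: SyntheticOptions = field(default_factory=SyntheticOptions)

    def validate(self):
        self.preprocess.validate()
        self.fit.validate()
        self.heterogeneous.validate()
        self.synthetic.validate()

    def to_dict(self) -> dict:
        return asdict(self)


def _build(cls, data: dict, prefix: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(prefix + k for k in unknown)}")
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ValidationError(f"invalid config section {prefix.rstrip('.')}: {exc}") from exc


def read_config(path) -> AnalysisConfig:
    """Load and validate a YAML config; an empty file yields the defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError("config root must be a mapping")
    sections = {"preprocess": PreprocessOptions, "fit": FitOptions,
                "heterogeneous": HeterogeneousOptions, "synthetic": SyntheticOptions}
    unknown = set(data) - set(sections)
    if unknown:
        raise ValidationError(f"unknown config section(s): {sorted(unknown)}")
    cfg = AnalysisConfig(**{
        name: _build(cls, data.get(name, {}) or {}, name + ".")
        for name, cls in sections.items()
    })
    cfg.validate()
    return cfg
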