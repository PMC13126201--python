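"""Shared fixtures: canonical study conditions for the synthetic datasets."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import soxkin as sk

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: water truth: tau_delta 3.5 µs (air-saturated H2O), tau_T 2.0 µs,
#: onset delay 0.2 µs; acquisition at peak SNR 50 (500 peak counts over a
#: 100 counts/bin dark level), 0.05 µs bins to 40 µs.
WATER_TRUTH = dict(tau_delta=3.5, tau_T=2.0, t0=0.2)


@pytest.fixture(scope="session")
def water_params():
    return sk.HomogeneousParams(alpha=100.0, **WATER_TRUTH)


@pytest.fixture(scope="session")
def noisy_water_trace(water_params):
    return sk.generate_homogeneous_trace(water_params, sk.NoiseSpec(seed=2))


@pytest.fixture(scope="session")
def noiseless_water_trace(water_params):
    return sk.generate_homogeneous_trace(water_params,
                                         sk.NoiseSpec(seed=0, poisson=False))


def trace_truth(trace):
    """Effective generating parameters recorded by the generator."""
    return {k.removeprefix("true_"): float(v)
            for k, v in trace.meta.items() if k.startswith("true_")}


@pytest.fixture(scope="session")
def liposome_setup():
    """Pheo/DPPC-like study condition: lipid-localized generation,
    tau_T 2.0 µs, tau_delta_W 4.0 µs, A/B 3.43, 20 ns bins at peak SNR 50
    (long-averaged NIR acquisition)."""
    return dict(geom=sk.VesicleGeometry(), phases=sk.PhaseParams(),
                source=sk.SourceSpec(tau_T=2.0, w_lipid=1.0, w_water=0.0),
                tau_delta_W=4.0,
                grid=sk.SimGrid(dt_out=0.02, dt=0.01))
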