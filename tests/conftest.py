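"""Shared fixtures: small synthetic runs reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from mmcyto import (
    AcquisitionConfig,
    ClassSpec,
    SimulationParams,
    default_classes,
    generate_run,
)


@pytest.fixture(scope="session")
def config() -> AcquisitionConfig:
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def clean_params() -> SimulationParams:
    """Noise-free-ish conditions: no aggregates, no sizing jitter, no drift."""
    return SimulationParams(
        n_events_per_class=4,
        aggregate_probability=0.0,
        sizing_jitter_um=0.0,
        pi_event_noise_sd=0.0,
        pi_channel_noise_sd=0.0,
        gain_drift_sd=0.0,
        baseline_drift_amp=0.0,
        seed=13,
    )


@pytest.fixture(scope="session")
def unbiased_classes() -> list[ClassSpec]:
    """The four study classes without the class-2 imaging-halo bias."""
    out = []
    for c in default_classes():
        out.append(ClassSpec(c.class_id, c.name, c.diameter_range_um,
                             spectral_tilt=c.spectral_tilt, optical_bias_um=0.0))
    return out


@pytest.fixture(scope="session")
def small_run(config, unbiased_classes, clean_params):
    """A small clean run with all four classes, shared by extraction tests."""
    return generate_run(config, unbiased_classes, clean_params, run_id="small")


@pytest.fixture(scope="session")
def default_run(config):
    """A default-noise run (all realism on), moderate size."""
    params = SimulationParams(n_events_per_class=10, seed=42)
    return generate_run(config, default_classes(), params, run_id="default")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
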