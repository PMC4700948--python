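"""Shared fixtures and hypothesis settings for the hemix test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hemix.simulate import SimulationConfig

# Reproducible property tests: fixed example budget, no randomized replay.
settings.register_profile(
    "hemix",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("hemix")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150)


@pytest.fixture
def small_config() -> SimulationConfig:
    """A fast two-species config for smoke-level pipeline tests."""
    return SimulationConfig(n_scaffolds=60, genes_per_scaffold_mean=6.0, seed=11)
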