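from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cxreval.synthetic import SimulationConfig, simulate_study

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240611)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down study: same structure, 40/80 images per pathology."""
    return SimulationConfig(n_positive_per_label=40, n_negative_per_label=80)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config, seed=1234)
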