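"""Shared fixtures: small, fast simulation configs."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from warmgrowth.config import SimulationConfig, biotest_scenario, null_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def quiet_config():
    """All noise terms zero: fully deterministic simulation."""
    return SimulationConfig(
        recruits_per_year_per_area=5,
        reference_temp_sd=0.0,
        temp_obs_sd=0.0,
        reference_temp_trend=0.0,
        individual_growth_cv=0.0,
        annual_growth_cv=0.0,
        measurement_sd=0.0,
        radius_noise_cv=0.0,
        rng_seed=0,
    )


@pytest.fixture
def small_config():
    """Small but noisy scenario for fast end-to-end tests."""
    return biotest_scenario(seed=0, recruits_per_year_per_area=40)


@pytest.fixture
def small_null_config():
    return null_scenario(seed=0, recruits_per_year_per_area=40)
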