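"""Shared fixtures: one small world for geometry-level tests and one
default-scale campaign (world, observations, design matrix) reused by the
model and acceptance suites."""

from __future__ import annotations

import numpy as np
import pytest

from geodens import (
    CampaignConfig,
    SimulationConfig,
    StudyRegion,
    build_design_matrix,
    run_sampling_campaign,
)
from geodens.synthetic_data import assign_covariates, generate_tessellation, generate_world


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    return SimulationConfig(region=StudyRegion(0, 16, 0, 16), n_das=200, rng_seed=7)


@pytest.fixture(scope="session")
def small_world(small_sim_config):
    das, users = generate_world(small_sim_config)
    return das, users


@pytest.fixture(scope="session")
def small_campaign(small_sim_config, small_world):
    das, users = small_world
    config = CampaignConfig(sim=small_sim_config, grid_origin=(1.0, 1.0))
    observations = run_sampling_campaign(das, users, config)
    return config, das, users, observations


@pytest.fixture(scope="session")
def small_design(small_campaign):
    _, das, _, observations = small_campaign
    return build_design_matrix(observations, das)


@pytest.fixture(scope="session")
def default_campaign():
    """Default-scale campaign: ~256 buffers over a 32x32-mile region."""
    config = CampaignConfig()
    das, users = generate_world(config.sim)
    observations = run_sampling_campaign(das, users, config)
    return config, das, users, observations


@pytest.fixture(scope="session")
def default_design(default_campaign):
    config, das, _, observations = default_campaign
    return build_design_matrix(observations, das)


@pytest.fixture(scope="session")
def small_tessellation():
    """Geometry-only tessellation for areal-overlay tests."""
    region = StudyRegion(0, 10, 0, 10)
    das = generate_tessellation(region, 25, rng_seed=11)
    cfg = SimulationConfig(region=region, n_das=25, rng_seed=11)
    assign_covariates(das, cfg)
    return region, das


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260901)
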