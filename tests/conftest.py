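"""Shared fixtures: small synthetic scenes and derived thresholds."""

from __future__ import annotations

import numpy as np
import pytest

from geotrack import (
    RunConfig,
    SimParams,
    render_video,
    simulate_trajectories,
    synthetic_thresholds,
)


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    """A quick 5-fly, 120-frame scene used across detection/tracking tests."""
    return SimParams(n_flies=5, n_frames=120, rng_seed=7)


@pytest.fixture(scope="session")
def small_scene(small_params):
    truth = simulate_trajectories(small_params)
    stack = render_video(truth)
    return truth, stack


@pytest.fixture(scope="session")
def small_thresholds(small_params):
    return synthetic_thresholds(small_params)


@pytest.fixture()
def default_config() -> RunConfig:
    return RunConfig(rng_seed=0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
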