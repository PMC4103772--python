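"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from stclust import (
    PipelineConfig,
    SimConfig,
    combine_library,
    run_from_libraries,
    simulate_run,
    worked_example,
)


@pytest.fixture(scope="session")
def wx():
    """The deterministic synthetic worked-example fixture."""
    return worked_example()


@pytest.fixture(scope="session")
def wx_combined(wx):
    """Worked-example library after phase 2, with its combine records."""
    return combine_library(wx.library, 213)


@pytest.fixture(scope="session")
def zero_noise_run():
    """Small zero-noise simulated run plus its pipeline result."""
    cfg = SimConfig(
        n_samples=6,
        p_indel=0.0,
        p_sub=0.0,
        chimera_rate=0.0,
        seed=11,
        library_size_range=(200, 400),
    )
    libs, truth = simulate_run(cfg)
    result = run_from_libraries(
        libs, PipelineConfig(theta=1 / 22, delta=4.0, seed=11)
    )
    return libs, truth, result


@pytest.fixture(scope="session")
def noisy_libs():
    """A couple of realistically noisy libraries for property checks."""
    cfg = SimConfig(n_samples=3, seed=7, library_size_range=(150, 250))
    libs, truth = simulate_run(cfg)
    return libs, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
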