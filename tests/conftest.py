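"""Shared fixtures: one small virtual patient reused across the suite."""

import numpy as np
import pytest

import gliosel as g


@pytest.fixture(scope="session")
def anatomy():
    return g.make_anatomy(seed=3, dims=(16, 16, 3))


@pytest.fixture(scope="session")
def schedule(anatomy):
    return g.make_schedule(anatomy)


@pytest.fixture(scope="session")
def workspace(anatomy):
    return g.SimulationWorkspace(anatomy)


@pytest.fixture(scope="session")
def bounds():
    return g.ParameterBounds()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def growth_params():
    """Moderate no-treatment growth parameters (stable at dt = 0.1 day)."""
    return g.ParameterSet(
        kpE=0.05, kpN=0.03, D_w=0.15, D_g=0.05, f_NE=1.5,
        beta_NE=0.5, beta_EN=0.3, lambda1=0.4,
    )
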