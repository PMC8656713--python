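import numpy as np
import pytest

from daptsim.cohort import build_phantom, generate_cohort
from daptsim.config import PROFILES
from daptsim.pipeline import plan_for


@pytest.fixture(scope="session")
def tiny_profile():
    return PROFILES["tiny"]


@pytest.fixture(scope="session")
def coarse_profile():
    return PROFILES["coarse"]


@pytest.fixture(scope="session")
def tiny_phantom(tiny_profile):
    return build_phantom(tiny_profile.grid)


@pytest.fixture(scope="session")
def coarse_phantom(coarse_profile):
    return build_phantom(coarse_profile.grid)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_profile):
    return generate_cohort(3, 42, grid=tiny_profile.grid)


@pytest.fixture(scope="session")
def tiny_plan(tiny_cohort, tiny_profile):
    """Base plan for the first tiny-profile patient (shared, read-only)."""
    return plan_for(tiny_cohort[0], tiny_profile)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
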