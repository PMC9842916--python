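import numpy as np
import pytest

from lesionmap import CohortConfig, GridSpec, make_fiber_atlas, simulate_cohort


@pytest.fixture(scope="session")
def grid():
    return GridSpec(shape=(32, 32, 32))


@pytest.fixture(scope="session")
def atlas(grid):
    return make_fiber_atlas(grid, seed=11)


@pytest.fixture(scope="session")
def small_cohort(grid, atlas):
    """Default-conditions cohort, sized for unit tests."""
    cfg = CohortConfig(n_patients=40, n_controls=20, seed=42)
    return simulate_cohort(cfg, grid, atlas)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
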