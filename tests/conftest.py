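import numpy as np
import pytest

from pmburden.core_grid import AGE_GROUPS, GridSpec, PopulationGrid
from pmburden.exposure_response import GEMMParams
from pmburden.reporting import load_table1_fixture
from pmburden.synthetic import (
    SyntheticConfig,
    generate_baseline_mortality,
    generate_concentration_suite,
    generate_population,
)


@pytest.fixture(scope="session")
def fixture_table():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def gemm_fixture_params():
    """Declared fixture parameters (the combined-cause hazard shape)."""
    return GEMMParams(endpoint="NCD_LRI", theta=0.1430, alpha=1.6,
                      mu=15.5, nu=36.8)


@pytest.fixture(scope="session")
def small_cfg():
    """Small, fast suite configuration for unit tests."""
    return SyntheticConfig(seed=7, n_rows=12, n_cols=12)


@pytest.fixture(scope="session")
def small_suite(small_cfg):
    return generate_concentration_suite(small_cfg)


@pytest.fixture(scope="session")
def small_population(small_cfg):
    return generate_population(small_cfg)


@pytest.fixture(scope="session")
def baseline(small_cfg):
    return generate_baseline_mortality(small_cfg)


def one_cell_population(count: float, age_group: str, year: int = 2010):
    """A 1-cell grid holding ``count`` people in a single age group."""
    grid = GridSpec.uniform(1, 1)
    counts = np.zeros((1, 1, len(AGE_GROUPS)))
    counts[0, 0, AGE_GROUPS.index(age_group)] = count
    return PopulationGrid(grid=grid, counts=counts, age_groups=AGE_GROUPS,
                          year=year)
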