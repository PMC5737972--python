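import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lexiscreen as lx

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spec():
    return lx.GridSpec()


@pytest.fixture(scope="session")
def partition(spec):
    return lx.partition_cells(spec)


@pytest.fixture(scope="session")
def small_sim():
    """A fast microsimulation config + one realisation shared across tests."""
    config = lx.SimulationConfig(cohort_size=1000)
    records, wy = lx.simulate(config, seed=2024)
    return config, records, wy


@pytest.fixture(scope="session")
def expected_default():
    """Analytic expected surfaces for the default mechanism (small cohorts)."""
    config = lx.SimulationConfig(cohort_size=1000)
    return config, lx.expected_cell_rates(config)


def make_grid(spec, stage24=None, deaths=None, women_years=None):
    wy = women_years if women_years is not None else np.full(
        (spec.n_ages, spec.n_years, 2), 1.0
    )
    return lx.LexisGrid(spec, deaths=deaths, stage24_cases=stage24, women_years=wy)
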