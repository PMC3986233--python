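import numpy as np
import pytest

import dynapop as dp
import dynapop.fixtures as fx

BANDS4 = [(0, 20), (20, 40), (40, 60), (60, 100)]


@pytest.fixture(scope="session")
def bands4():
    return list(BANDS4)


@pytest.fixture(scope="session")
def small_region():
    """One 50-household ground-truth area, validated."""
    cfg = dp.RegionConfig(n_areas=1, households_per_area=50, seed=101)
    pop = dp.generate_true_population(cfg)
    pop.validate()
    return pop


@pytest.fixture(scope="session")
def two_area_region():
    cfg = dp.RegionConfig(n_areas=2, persons_per_area=150, seed=202)
    pop = dp.generate_true_population(cfg)
    pop.validate()
    return pop


@pytest.fixture(scope="session")
def printed_rates():
    """The published birth/death tables (everything else zero)."""
    return fx.vital_rates_fixture()


@pytest.fixture(scope="session")
def full_rates():
    """Printed birth/death plus synthetic marriage/divorce/leaving rates."""
    return fx.synthetic_event_rates()


def region_marginals(pop, bands=tuple(BANDS4), perturbation=0, seed=0):
    return fx.tabulate_marginals(pop, list(bands), perturbation, seed)
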