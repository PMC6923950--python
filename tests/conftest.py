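import numpy as np
import pytest

from yeastcolony import (LatticeConfig, generate_growth_curves,
                         initialize_colony)
from yeastcolony.synthdata import default_truth_params


@pytest.fixture(scope="session")
def truth():
    params, init = default_truth_params()
    return params, init


@pytest.fixture(scope="session")
def growth_data():
    """One synthetic wild-type growth dataset shared across tests."""
    return generate_growth_curves(seed=101)


@pytest.fixture
def small_lattice_config():
    return LatticeConfig(dims=(11, 11, 6), agar_layers=2,
                         disc_diameter_mm=0.8)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_colony(config, rng, fill=2.0):
    """Random non-agar mass/nutrient fields on an initialized lattice."""
    lat = initialize_colony(config)
    free = ~lat.agar
    lat.m_g += rng.random(config.dims) * free * fill
    lat.m_e += rng.random(config.dims) * free * 0.5 * fill
    lat.m_q += rng.random(config.dims) * free * 0.25 * fill
    lat.e += rng.random(config.dims) * free * 0.2
    return lat
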