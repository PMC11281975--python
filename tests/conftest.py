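import numpy as np
import pandas as pd
import pytest

from dryspell.config import SimulationConfig
from dryspell.synthetic import make_plot_metadata, simulate_climate


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def climate_tables(sim_config):
    """One shared synthetic climate realization (daily, monthly)."""
    return simulate_climate(sim_config)


@pytest.fixture(scope="session")
def metadata(sim_config):
    return make_plot_metadata(sim_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def constant_daily_t():
    """A year of constant 15 °C daily temperature."""
    return pd.DataFrame({"year": 2000, "doy": np.arange(1, 366),
                         "T": 15.0})
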