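import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import fragdep as fd

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def config():
    return fd.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def sites(config):
    return fd.generate_landscape(config)


@pytest.fixture(scope="session")
def pool(config):
    return fd.generate_species_pool(config)


@pytest.fixture(scope="session")
def effort(sites, config):
    return fd.design_effort_table(sites, config.design)


@pytest.fixture(scope="session")
def captures(sites, pool, effort, config):
    return fd.simulate_captures(sites, pool, effort, seed=config.seed)


@pytest.fixture(scope="session")
def community(captures, effort):
    return fd.standardize_abundance(captures, effort)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
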