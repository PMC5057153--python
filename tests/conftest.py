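import numpy as np
import pytest

from polpause import Dataset, SimulationConfig, analyze, simulate_experiment


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=7, n_genes=60, gene_length_range=(1200, 2500))


@pytest.fixture(scope="session")
def small_exp(small_config):
    return simulate_experiment(small_config)


@pytest.fixture(scope="session")
def default_exp():
    """Full-size synthetic experiment at the study's default conditions."""
    return simulate_experiment(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_result(default_exp):
    return analyze(Dataset.from_simulation(default_exp))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
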