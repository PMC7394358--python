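import numpy as np
import pytest

from irscan import SearchConfig, SimulationParams, simulate_genome
from irscan.simulate import DECOY_KINDS


@pytest.fixture(scope="session")
def default_config() -> SearchConfig:
    return SearchConfig()


@pytest.fixture(scope="session")
def sim_fixture():
    """One fully decoyed simulated genome (seed 7) with its truth table."""
    params = SimulationParams(seed=7, decoys=DECOY_KINDS)
    genome, annotations, truth = simulate_genome(params)
    return params, genome, annotations, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
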