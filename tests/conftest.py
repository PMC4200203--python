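import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from cleavecat.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def tiny_config():
    return SimulationConfig(seed=11, n_chromosomes=2, chrom_length=500_000,
                            n_coding_genes=40, n_lncRNA_genes=30)


@pytest.fixture(scope="session")
def tiny_sim(tiny_config):
    return simulate(tiny_config)


@pytest.fixture(scope="session")
def fixture_config():
    """The packaged full-size fixture: ~1500 genes, 24 samples, defaults."""
    return SimulationConfig(seed=202)


@pytest.fixture(scope="session")
def fixture_sim(fixture_config):
    return simulate(fixture_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
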