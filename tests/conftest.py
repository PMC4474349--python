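import numpy as np
import pytest

from homeopart.simulate import SimConfig, simulate_counts, simulate_reads, \
    simulate_triplets


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_triplets=20, gene_length=600, depth_mean=100.0,
                     rng_seed=7)


@pytest.fixture(scope="session")
def small_tripletset(small_config):
    return simulate_triplets(small_config)


@pytest.fixture(scope="session")
def small_countsim(small_config):
    return simulate_counts(small_config)


@pytest.fixture(scope="session")
def small_readsim(small_config, small_tripletset, small_countsim):
    return simulate_reads(small_tripletset, small_countsim)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
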