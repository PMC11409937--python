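import numpy as np
import pytest

from rbtnfit.simulate import SimConfig, simulate_community


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale-but-smaller conditions for fast unit tests."""
    return SimConfig(
        genome_length=50_000,
        n_genes=40,
        n_insertions=2_000,
        read_depth_per_sample=100_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_community(small_config)


@pytest.fixture(scope="session")
def default_sim():
    """One default-scale simulated experiment shared across tests."""
    return simulate_community(SimConfig(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
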