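import numpy as np
import pytest

from colseq import NetworkConfig, build_network


@pytest.fixture(scope="session")
def base_config() -> NetworkConfig:
    return NetworkConfig()


@pytest.fixture(scope="session")
def small_model():
    """Two-column baseline network, full population size."""
    return build_network(NetworkConfig(n_columns=2), seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
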