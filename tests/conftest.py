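import numpy as np
import pytest

from oakbiomass import GeneratorConfig, generate_trees, zero_noise_config


@pytest.fixture(scope="session")
def default_population():
    """Study-scale population under the default (noisy) conditions."""
    return generate_trees(GeneratorConfig(seed=20260921))


@pytest.fixture(scope="session")
def noiseless_population():
    """Same design with component noise off (height scatter retained)."""
    return generate_trees(zero_noise_config(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
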