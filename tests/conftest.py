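import numpy as np
import pytest

from radunet import PhantomSpec, RADUNetConfig, build_radunet, generate_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest model that still exercises every block."""
    return RADUNetConfig(base_channels=2, attention_reduction=2, seed=7)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return build_radunet(tiny_config)


@pytest.fixture(scope="session")
def phantom_sample():
    return generate_phantom(PhantomSpec(seed=11))
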