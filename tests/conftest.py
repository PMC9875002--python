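import numpy as np
import pytest

from dmffnet import phantoms
from dmffnet.network import NetworkConfig


@pytest.fixture(scope="session")
def tiny_config() -> NetworkConfig:
    """A network small enough to train on CPU in seconds per step."""
    return NetworkConfig(base_width=8, sdab_layers=4, sdab_growth=8,
                         carry_width=16, bottleneck_width=128, ca_reduction=8,
                         seed=1)


@pytest.fixture(scope="session")
def phantom_spec_64() -> phantoms.PhantomSpec:
    return phantoms.PhantomSpec(image_height=64, image_width=64,
                                lesion_radius_range=(5.0, 12.0))


@pytest.fixture(scope="session")
def phantom_pair(phantom_spec_64):
    return phantoms.generate_phantom(phantom_spec_64)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
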