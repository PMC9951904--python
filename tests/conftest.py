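import numpy as np
import pytest

from aimunet.config import NetworkConfig, PhantomConfig, TrainConfig
from aimunet.phantoms import generate_slice
from aimunet.preprocess import preprocess_slice, resize_to_network


@pytest.fixture(scope="session")
def small_phantom_config():
    """A 64x64 phantom world small enough for fast tests."""
    return PhantomConfig(height=64, width=64, liver_axes_range=(10, 20),
                         tumor_radius_range=(2, 6), seed=7)


@pytest.fixture(scope="session")
def small_pairs(small_phantom_config):
    """Five preprocessed (normalized image, mask) pairs at 64x64."""
    pairs = [generate_slice(small_phantom_config, f"p{i}", 0) for i in range(5)]
    images = [preprocess_slice(p.image, side=64) for p in pairs]
    masks = [resize_to_network(p.liver_mask, 64) for p in pairs]
    return images, masks


@pytest.fixture()
def tiny_network_config():
    """The smallest full-depth network that still exercises every layer kind."""
    return NetworkConfig(input_height=32, input_width=32, base_filters=2)


@pytest.fixture()
def reduced_network_config():
    return NetworkConfig(input_height=64, input_width=64, base_filters=8)


@pytest.fixture()
def quick_train_config():
    return TrainConfig(epochs=2, batch_size=3, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
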