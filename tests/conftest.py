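import numpy as np
import pytest

from heeseggan.phantom import PhantomConfig, generate_dataset, generate_phantom
from heeseggan.training import composites_from_phantoms


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def easy_phantom_config():
    """High-contrast solid nodules in small volumes: fast and learnable."""
    return PhantomConfig(volume_shape=(6, 64, 64), nodule_radius_range=(5.0, 9.0),
                         nodule_kind="solid", nodule_hu=200.0, n_vessels=2, seed=0)


@pytest.fixture(scope="session")
def phantom_sample(easy_phantom_config):
    return generate_phantom(easy_phantom_config)


@pytest.fixture(scope="session")
def tiny_dataset(easy_phantom_config):
    """16 preprocessed 32x32 training examples."""
    samples = generate_dataset(16, easy_phantom_config, seed=42)
    return composites_from_phantoms(samples, size=32)
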