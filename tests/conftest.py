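import numpy as np
import pytest

from mafcnn.synthetic import SyntheticDatasetConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Three well-separated classes, 8 samples each, 32px, light noise."""
    config = SyntheticDatasetConfig(n_per_class=(8, 8, 8), image_size=32,
                                    noise_sigma=0.03, seed=7)
    samples, manifest = generate_dataset(config)
    return samples, manifest


class StubRng:
    """Generator stand-in returning a fixed value for every draw."""

    def __init__(self, value: float):
        self.value = value

    def random(self, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)


@pytest.fixture
def stub_rng():
    return StubRng
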