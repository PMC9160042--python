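import numpy as np
import pytest

from aggrgan.imaging import GrayImage
from aggrgan.phantoms import PhantomSpec, make_dataset, make_phantom


def random_uint8(rng, m, n):
    return GrayImage(rng.integers(0, 256, (m, n), dtype=np.uint8), "uint8")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def desk_dataset():
    """64 jittered phantoms at 32x32: the desk-scale GAN training set."""
    return make_dataset(64, base=PhantomSpec(size=32), jitter=0.1, seed=1)
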