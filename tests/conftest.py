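import numpy as np
import pytest

from glioseg.labels import LabelVolume
from glioseg.phantom import PhantomConfig, generate_case


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom_config():
    """A 32³ phantom small enough for per-test generation."""
    return PhantomConfig(shape=(32, 32, 32), n_cases=3, radii=(8.0, 5.0, 3.0),
                         radius_jitter=0.5, center_jitter=1.5, seed=7)


@pytest.fixture(scope="session")
def phantom_case(small_phantom_config):
    return generate_case(small_phantom_config, 0)


def random_label_volume(rng, shape=(3, 3, 3)) -> LabelVolume:
    vals = np.array([0, 1, 2, 4], dtype=np.int16)
    return LabelVolume(rng.choice(vals, size=shape))
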