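import numpy as np
import pytest

from structwise import BinaryMask


def random_mask(rng, shape=(8, 8, 8), density=0.3, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    return BinaryMask(data=rng.random(shape) < density, spacing=spacing)


def random_nonempty_mask(rng, shape=(8, 8, 8), density=0.3, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    while True:
        m = random_mask(rng, shape, density, spacing)
        if not m.is_empty:
            return m


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def cube_mask():
    """Solid 5x5x5 cube centred in a 9x9x9 unit-spacing grid."""
    data = np.zeros((9, 9, 9), dtype=bool)
    data[2:7, 2:7, 2:7] = True
    return BinaryMask(data=data)
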