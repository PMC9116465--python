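import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ceiqa import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """16x16 8-bit random image (nonzero so ratio descriptors apply)."""
    return rng.integers(1, 256, size=(16, 16)).astype(float)


@pytest.fixture(scope="session")
def phantom():
    return generate_phantom(PhantomSpec(size=192, seed=7))


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(PhantomSpec(size=96, seed=11))
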