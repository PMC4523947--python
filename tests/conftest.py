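import numpy as np
import pytest

from boundarynet import gabor, stimuli


@pytest.fixture(scope="session")
def family32():
    return stimuli.ShapeFamilySpec(3, 2)


@pytest.fixture(scope="session")
def shapes32(family32):
    return stimuli.enumerate_shapes(family32)


@pytest.fixture(scope="session")
def small_bank():
    return gabor.build_bank(64)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
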