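import numpy as np
import pytest

from fracvq import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def phantom256():
    return make_phantom(PhantomSpec(size=256, seed=0))


@pytest.fixture(scope="session")
def phantom128():
    return make_phantom(PhantomSpec(size=128, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
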