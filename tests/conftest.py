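import numpy as np
import pytest

from sdsl import fixtures


@pytest.fixture(scope="session")
def toy_lib():
    return fixtures.make_toy_label_library()


@pytest.fixture(scope="session")
def helix10():
    return fixtures.make_helix(10)


@pytest.fixture(scope="session")
def helix16():
    return fixtures.make_helix(16)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
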