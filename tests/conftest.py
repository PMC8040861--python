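import numpy as np
import pytest

from helixgraft.fixtures import make_bab_fragment, make_mini_barrel


@pytest.fixture(scope="session")
def mini_barrel():
    return make_mini_barrel()


@pytest.fixture(scope="session")
def bab_fragment():
    return make_bab_fragment()


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)
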