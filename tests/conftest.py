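import numpy as np
import pytest

from ringcrowd import make_fixture


@pytest.fixture(scope="session")
def ring20():
    return make_fixture("ring20")


@pytest.fixture(scope="session")
def ring20_crowders():
    return make_fixture("ring20+crowders")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
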