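import numpy as np
import pytest

from ferromir.motifscan import ide1_model, ide2_model


@pytest.fixture(scope="session")
def ide1():
    return ide1_model()


@pytest.fixture(scope="session")
def ide2():
    return ide2_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_seq(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))
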