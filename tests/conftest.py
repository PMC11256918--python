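import numpy as np
import pytest

from rnadesign.folding import (
    external_engine,
    has_external_engine,
    nussinov_engine,
)
from rnadesign.protocols import riboswitch_space


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def nussinov():
    return nussinov_engine()


@pytest.fixture(scope="session")
def mfe_engine():
    if not has_external_engine():
        pytest.skip("ViennaRNA python bindings not installed")
    return external_engine("MFE")


@pytest.fixture(scope="session")
def ribospace():
    return riboswitch_space()


def random_sequence(rng, n):
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=n)])
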