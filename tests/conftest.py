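import numpy as np
import pytest

from ticycle import gauss_legendre_schedule, load_table1


@pytest.fixture(scope="session")
def schedule12():
    return gauss_legendre_schedule(12)


@pytest.fixture(scope="session")
def table1_records():
    return load_table1()


@pytest.fixture()
def rng():
    return np.random.default_rng(20220609)
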