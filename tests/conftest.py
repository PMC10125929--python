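import numpy as np
import pytest

from lamterm import seqio


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def table2():
    return seqio.load_fixture_table("table2")


@pytest.fixture(scope="session")
def table3():
    return seqio.load_fixture_table("table3")


@pytest.fixture(scope="session")
def table4():
    return seqio.load_fixture_table("table4")
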