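import pytest

import greyshap as gs


@pytest.fixture(scope="session")
def table1():
    """Observed annual fatality series, 2002-2011."""
    return gs.load_fixture("table1")


@pytest.fixture(scope="session")
def table3():
    """Six-covariate exposure panel, 2002-2011."""
    return gs.load_fixture("table3")


@pytest.fixture(scope="session")
def table9():
    """Hold-out covariate panel, 2012-2013."""
    return gs.load_fixture("table9")


@pytest.fixture(scope="session")
def verhulst_fit(table1):
    return gs.grey_verhulst.fit(table1)


@pytest.fixture(scope="session")
def ols_fit(table3, table1):
    return gs.fit_ols(table3, table1)


@pytest.fixture(scope="session")
def bundle():
    """Full end-to-end reproduction bundle (computed once per session)."""
    return gs.reproduce_paper()
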