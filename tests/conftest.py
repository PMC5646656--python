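import pytest

from karyodist import load_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def table1(fixtures):
    return fixtures.table1


@pytest.fixture(scope="session")
def table2(fixtures):
    """Measured karyotypes keyed by species."""
    return {k.species: k for k in fixtures.table2}


@pytest.fixture(scope="session")
def table3(fixtures):
    return fixtures.table3
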