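import pytest
from hypothesis import settings

import freesrf as F

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tables():
    return F.load_tables()


@pytest.fixture(scope="session")
def table(tables):
    return tables[0]


@pytest.fixture(scope="session")
def water(tables):
    return tables[1]


@pytest.fixture(scope="session")
def recoverin(table):
    fx = F.load_fixture("recoverin")
    return F.MolecularSpecies.from_sequence(fx.sequence, table, label="recoverin")


@pytest.fixture(scope="session")
def caii(table):
    fx = F.load_fixture("caii")
    return F.MolecularSpecies.from_sequence(fx.sequence, table, label="caii")


@pytest.fixture(scope="session")
def calcium(table):
    return F.MolecularSpecies.from_ion("Ca2+", table)


@pytest.fixture(scope="session")
def benzenesulfonamide(table):
    return F.MolecularSpecies.from_formula("C6H7NO2S", table)
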