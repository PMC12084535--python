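import pytest

from edsepsis.cohort import CohortSpec, generate_cohort
from edsepsis.ddx import load_default_tables


@pytest.fixture(scope="session")
def catalog_table():
    return load_default_tables()


@pytest.fixture(scope="session")
def catalog(catalog_table):
    return catalog_table[0]


@pytest.fixture(scope="session")
def table(catalog_table):
    return catalog_table[1]


@pytest.fixture(scope="session")
def small_cohort(catalog, table):
    """200 encounters, noise-free notes, fixed seed; shared across tests."""
    spec = CohortSpec(n_encounters=200, septic_fraction=0.2, seed=11)
    return generate_cohort(spec, catalog, table)
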