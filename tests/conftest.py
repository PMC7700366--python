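import pytest
from hypothesis import settings

import aarspan as ap

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return ap.load_gene_registry()


@pytest.fixture(scope="session")
def cancer_table():
    return ap.load_cancer_table()


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded small-scenario cohort shared across tests (read-only)."""
    return ap.generate_cohort(ap.default_config("small"))


@pytest.fixture(scope="session")
def paper_cohort():
    """Seeded paper_like cohort: 10 cancers, 43 genes, planted archetypes."""
    return ap.generate_cohort(ap.default_config("paper_like"))
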