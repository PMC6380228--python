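import pytest

from metaqc import (
    CorpusConfig,
    Repository,
    bundled_term_index,
    generate_corpus,
    load_bundled_registry,
)


@pytest.fixture(scope="session")
def ncbi_registry():
    return load_bundled_registry(Repository.NCBI)


@pytest.fixture(scope="session")
def ebi_registry():
    return load_bundled_registry(Repository.EBI)


@pytest.fixture(scope="session")
def term_index():
    return bundled_term_index()


@pytest.fixture(scope="session")
def small_ncbi_corpus():
    """A 200-record NCBI-profile corpus with its ground-truth ledger."""
    return generate_corpus(CorpusConfig(n_records=200, seed=42))


@pytest.fixture(scope="session")
def small_ebi_corpus():
    """A 150-record EBI-profile corpus with its ground-truth ledger."""
    return generate_corpus(CorpusConfig.for_repository(Repository.EBI, n_records=150, seed=7))
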