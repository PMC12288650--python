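import pytest

from assay2mol.chem_pool import full_pool
from assay2mol.synthetic_corpus import CorpusSpec, make_corpus


@pytest.fixture(scope="session")
def pool() -> list[str]:
    return list(full_pool())


@pytest.fixture(scope="session")
def small_corpus():
    """A 20-assay, 3-family synthetic corpus shared across read-only tests."""
    spec = CorpusSpec(
        n_assays=20,
        n_families=3,
        actives_fraction=0.3,
        table_size_range=(8, 24),
        counterscreen_fraction=0.2,
        seed=11,
    )
    return make_corpus(spec)


@pytest.fixture(scope="session")
def corpus_records(small_corpus):
    return small_corpus[0]


@pytest.fixture(scope="session")
def corpus_manifest(small_corpus):
    return small_corpus[1]


@pytest.fixture(scope="session")
def corpus_map(corpus_records):
    return {r.aid: r for r in corpus_records}
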