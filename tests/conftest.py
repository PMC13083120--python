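import dataclasses

import pytest

from mrira import (
    GeneratorConfig,
    build_default_schema,
    generate_corpus,
    normalize_document,
    perturb_document,
    worked_example,
)


@pytest.fixture(scope="session")
def schema():
    return build_default_schema()


@pytest.fixture()
def worked_doc():
    return worked_example()


@pytest.fixture()
def worked_doc_normalized(schema):
    return normalize_document(schema, worked_example())


@pytest.fixture(scope="session")
def small_corpus():
    """A fixed small synthetic corpus shared across tests (gold only)."""
    return generate_corpus(GeneratorConfig(seed=42, n_reports=20))


def make_pairs(corpus, pconfig, seed_base=10_000):
    """Pair each gold document with its perturbed counterpart, one derived
    seed per document."""
    pairs = []
    for i, (doc, _harm) in enumerate(corpus):
        cfg = dataclasses.replace(pconfig, seed=seed_base + i)
        pairs.append((doc, perturb_document(doc, cfg)))
    return pairs
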