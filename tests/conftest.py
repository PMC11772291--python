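import numpy as np
import pytest

from entner import (
    CorpusSpec,
    LabelScheme,
    Vocab,
    generate_corpus,
)
from entner.experiments import notes_to_sentences


@pytest.fixture(scope="session")
def scheme() -> LabelScheme:
    return LabelScheme()


@pytest.fixture(scope="session")
def small_corpus():
    """30 notes with an unlabeled tail; shared read-only across tests."""
    return generate_corpus(CorpusSpec(n_notes=30, seed=7, unlabeled_fraction=0.2))


@pytest.fixture(scope="session")
def sentences(small_corpus):
    return notes_to_sentences(small_corpus)


@pytest.fixture(scope="session")
def vocab(sentences, scheme) -> Vocab:
    return Vocab.build(sentences, scheme)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
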