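import numpy as np
import pytest

from epipair.corpus import SequenceRecord, tokenize
from epipair.embedding import TrainConfig, build_vocabulary, train

BASES = np.array(list("ACGT"))


def random_record(rng, length, rec_id="SEQ", role="enhancer"):
    return SequenceRecord(id=rec_id, role=role, seq="".join(rng.choice(BASES, size=length)))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_corpus(rng):
    """Ten random 120-bp enhancer sequences tokenised with k=3."""
    records = [random_record(rng, 120, f"ENHANCER_{i}") for i in range(10)]
    sentences = [tokenize(r, 3, 1) for r in records]
    return records, sentences


@pytest.fixture
def tiny_model(tiny_corpus):
    _, sentences = tiny_corpus
    config = TrainConfig(k=3, s=1, m=3, d=8, epochs=3, seed=7)
    return train(sentences, config)
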