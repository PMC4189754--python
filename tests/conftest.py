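import numpy as np
import pytest

from comodule.annotation_io import corpus_from_counts
from comodule.synthetic_data import SyntheticSpec, generate_corpus


def make_corpus(counts_by_sample, cap=10):
    """Shorthand: corpus from [(sample_id, {family: count}), ...]."""
    return corpus_from_counts(counts_by_sample, cap=cap)


@pytest.fixture(scope="session")
def small_synthetic():
    """A reduced synthetic corpus for unit tests (fast to fit)."""
    spec = SyntheticSpec(
        n_positive=20,
        n_negative=30,
        n_unlabeled=20,
        vocab_size=60,
        n_topics_true=5,
        planted_sizes=(8, 6),
        background_module_size=10,
        doc_length_mean=60.0,
        seed=42,
    )
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def block_corpus():
    """Two disjoint word blocks that co-occur only within their block."""
    rng = np.random.default_rng(0)
    block_a = [f"A{i}" for i in range(6)]
    block_b = [f"B{i}" for i in range(6)]
    docs = []
    for d in range(30):
        block = block_a if d % 2 == 0 else block_b
        words = rng.choice(block, size=20)
        counts = {}
        for w in words:
            counts[w] = counts.get(w, 0) + 1
        docs.append((f"doc{d:02d}", counts))
    return make_corpus(docs)
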