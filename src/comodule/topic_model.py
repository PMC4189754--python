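"""Latent Dirichlet allocation by collapsed Gibbs sampling, and module extraction.

A fitted model holds ``phi`` (T x V topic-word distributions) and ``theta``
(N x T document-topic distributions), each the average of posterior-mean
estimates over the collected Gibbs samples.  Thresholding a topic's word
distribution at a cutoff C yields a discrete candidate functional module:
the set of families with probability at least C in that topic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from comodule.annotation_io import AnnotationCorpus

DEFAULT_TOPICS = 400
DEFAULT_BETA = 0.01
DEFAULT_BURN_IN = 2000
DEFAULT_N_SAMPLES = 50
DEFAULT_SAMPLE_LAG = 10
DEFAULT_MODULE_CUTOFF = 0.01


def default_alpha(n_topics: int) -> float:
    """Document-topic Dirichlet concentration: 50/T."""
    return 50.0 / n_topics


@dataclass(frozen=True)
class LdaConfig:
    """Sampler hyperparameters. ``alpha=None`` means the 50/T default."""

    n_topics: int = DEFAULT_TOPICS
    alpha: float | None = None
    beta: float = DEFAULT_BETA
    burn_in: int = DEFAULT_BURN_IN
    n_samples: int = DEFAULT_N_SAMPLES
    sample_lag: int = DEFAULT_SAMPLE_LAG
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 2:
            raise ValueError(f"n_topics must be >= 2, got {self.n_topics}")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.sample_lag < 1:
            raise ValueError("sample_lag must be >= 1")

    @property
    def effective_alpha(self) -> float:
        return self.alpha if self.alpha is not None else default_alpha(self.n_topics)

    def with_seed(self, seed: int) -> "LdaConfig":
        return replace(self, seed=seed)


def scaled_down_config(n_topics: int = 20, seed: int = 0, **kwargs) -> LdaConfig:
    """Reduced-cost settings for tests and desk-scale experiments."""
    defaults = dict(n_topics=n_topics, burn_in=200, n_samples=10, sample_lag=10, seed=seed)
    defaults.update(kwargs)
    return LdaConfig(**defaults)


def corpus_fingerprint(corpus: AnnotationCorpus) -> str:
    """Stable hash of the corpus contents, stored on fitted models."""
    h = hashlib.sha256()
    h.update("\x1f".join(corpus.vocabulary).encode())
    for doc in corpus.documents:
        h.update(doc.sample_id.encode())
        for fam, c in doc.counts.items():
            h.update(f"{fam}={c}".encode())
    return h.hexdigest()[:16]


@dataclass
class TopicModel:
    """A fitted topic model tied to the corpus it was estimated from."""

    phi: np.ndarray  # (T, V), rows sum to 1
    theta: np.ndarray  # (N, T), rows sum to 1
    config: LdaConfig
    vocabulary: list[str]
    sample_ids: list[str]
    corpus_ref: str

    def __post_init__(self) -> None:
        if self.phi.shape != (self.config.n_topics, len(self.vocabulary)):
            raise ValueError("phi shape mismatch")
        if self.theta.shape != (len(self.sample_ids), self.config.n_topics):
            raise ValueError("theta shape mismatch")

    @property
    def n_topics(self) -> int:
        return self.config.n_topics


@dataclass(frozen=True)
class FamilyModule:
    """A discrete candidate module: families with topic probability >= cutoff."""

    topic_index: int
    families: frozenset[str]
    cutoff: float

    def __len__(self) -> int:
        return len(self.families)


def fit_lda(corpus: AnnotationCorpus, config: LdaConfig) -> TopicModel:
    """Fit the model by collapsed Gibbs sampling; deterministic given seed.

    Tokens are word instances: a family count of ``c`` in a document
    contributes ``c`` tokens.  After ``burn_in`` sweeps, ``n_samples``
    states are collected every ``sample_lag`` sweeps and the posterior-mean
    phi/theta estimates of those states are averaged.
    """
    if corpus.n_documents < 1:
        raise ValueError("corpus is empty")
    if corpus.n_families < 1:
        raise ValueError("corpus vocabulary is empty")

    fam_index = corpus.family_index()
    doc_ids: list[int] = []
    word_ids: list[int] = []
    for d, doc in enumerate(corpus.documents):
        for fam, c in doc.counts.items():
            w = fam_index[fam]
            doc_ids.extend([d] * c)
            word_ids.extend([w] * c)
    if not doc_ids:
        raise ValueError("corpus contains no tokens")

    from comodule._gibbs import gibbs_sample

    phi, theta = gibbs_sample(
        np.asarray(doc_ids, dtype=np.int64),
        np.asarray(word_ids, dtype=np.int64),
        corpus.n_documents,
        corpus.n_families,
        config.n_topics,
        config.effective_alpha,
        config.beta,
        config.burn_in,
        config.n_samples,
        config.sample_lag,
        config.seed,
    )
    return TopicModel(
        phi=phi,
        theta=theta,
        config=config,
        vocabulary=list(corpus.vocabulary),
        sample_ids=corpus.sample_ids,
        corpus_ref=corpus_fingerprint(corpus),
    )


def extract_modules(model: TopicModel, cutoff: float = DEFAULT_MODULE_CUTOFF) -> list[FamilyModule]:
    """Threshold each topic distribution into a discrete family module."""
    if not 0 < cutoff < 1:
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    vocab = np.asarray(model.vocabulary, dtype=object)
    modules = []
    for t in range(model.n_topics):
        members = vocab[model.phi[t] >= cutoff]
        modules.append(
            FamilyModule(topic_index=t, families=frozenset(members), cutoff=cutoff)
        )
    return modules


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: TopicModel, path: str | Path) -> None:
    """Serialize a model to a JSON bundle (text-only, lossless float repr)."""
    payload = {
        "config": {
            "n_topics": model.config.n_topics,
            "alpha": model.config.alpha,
            "beta": model.config.beta,
            "burn_in": model.config.burn_in,
            "n_samples": model.config.n_samples,
            "sample_lag": model.config.sample_lag,
            "seed": model.config.seed,
        },
        "vocabulary": model.vocabulary,
        "sample_ids": model.sample_ids,
        "corpus_ref": model.corpus_ref,
        "phi": [[float(x) for x in row] for row in model.phi],
        "theta": [[float(x) for x in row] for row in model.theta],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path) -> TopicModel:
    with open(path) as fh:
        payload = json.load(fh)
    return TopicModel(
        phi=np.asarray(payload["phi"], dtype=float),
        theta=np.asarray(payload["theta"], dtype=float),
        config=LdaConfig(**payload["config"]),
        vocabulary=payload["vocabulary"],
        sample_ids=payload["sample_ids"],
        corpus_ref=payload["corpus_ref"],
    )


def export_modules_tsv(model: TopicModel, modules: list[FamilyModule], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("topic_index\tfamily_id\tphi\n")
        fam_index = {f: i for i, f in enumerate(model.vocabulary)}
        for mod in modules:
            for fam in sorted(mod.families):
                fh.write(f"{mod.topic_index}\t{fam}\t{model.phi[mod.topic_index, fam_index[fam]]:.6g}\n")
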