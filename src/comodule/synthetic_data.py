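"""Synthetic corpora, labels and gene tables with known ground truth.

Documents are drawn from the forward generative process of the topic model:
per document a topic mixture is sampled from a Dirichlet prior, tokens are
drawn topic-then-word, and token counts are capped like real annotation
counts.  Phenotype-positive documents multiply the prior mass of the planted
phenotype-associated topics by an enrichment factor; with enrichment 1,
positive and negative documents are exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from comodule.annotation_io import (
    AnnotationCorpus,
    DEFAULT_COUNT_CAP,
    DocumentRecord,
    PhenotypeTable,
)
from comodule.gene_clusters import GeneRecord

DEFAULT_PLANTED_SIZES = (18, 23, 13)  # phenotype-module sizes


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic corpus generator.

    ``alpha_background`` is the Dirichlet concentration of the non-planted
    topics; ``alpha_phenotype`` the base concentration of the planted
    phenotype topics, multiplied by ``enrichment`` in positive documents.
    """

    n_positive: int = 38
    n_negative: int = 82
    n_unlabeled: int = 120
    vocab_size: int = 300
    n_topics_true: int = 12
    planted_sizes: tuple[int, ...] = DEFAULT_PLANTED_SIZES
    background_module_size: int = 25
    doc_length_mean: float = 120.0
    alpha_background: float = 0.5
    alpha_phenotype: float = 0.002
    enrichment: float = 1500.0
    presence_prob: float = 0.85
    unlabeled_presence_prob: float = 0.5
    unlabeled_positive_fraction: float = 0.5
    word_noise: float = 0.02
    cap: int = DEFAULT_COUNT_CAP
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        if len(self.planted_sizes) > self.n_topics_true:
            raise ValueError("more planted modules than topics")
        if sum(self.planted_sizes) > self.vocab_size:
            raise ValueError("planted modules larger than the vocabulary")


@dataclass
class GroundTruth:
    planted_modules: list[frozenset[str]]
    associations: list[str]  # "positive-enriched" | "background"
    labels: dict[str, str]
    unlabeled_positive_like: set[str] = field(default_factory=set)


def _family_names(vocab_size: int) -> list[str]:
    return [f"FAM{i:04d}" for i in range(vocab_size)]


def generate_corpus(spec: SyntheticSpec) -> tuple[AnnotationCorpus, PhenotypeTable, GroundTruth]:
    """Run the generative process forward; deterministic given ``spec.seed``.

    Returns the capped-count corpus, the phenotype table (positives,
    negatives, unknowns) and the ground truth (planted family sets and the
    latent positive-likeness of unlabeled documents).
    """
    rng = np.random.default_rng(spec.seed)
    vocab = _family_names(spec.vocab_size)
    V, T = spec.vocab_size, spec.n_topics_true
    n_planted = len(spec.planted_sizes)

    # planted phenotype modules: disjoint family blocks at the front of the
    # vocabulary; background topics draw random family sets from the rest
    planted: list[frozenset[str]] = []
    offset = 0
    for size in spec.planted_sizes:
        planted.append(frozenset(vocab[offset : offset + size]))
        offset += size
    rest = np.arange(offset, V)

    phi_true = np.full((T, V), 0.0)
    for t in range(n_planted):
        idx = [vocab.index(f) for f in planted[t]]
        phi_true[t, idx] = 1.0 / len(idx)
    for t in range(n_planted, T):
        size = min(spec.background_module_size, rest.size)
        members = rng.choice(rest, size=size, replace=False)
        phi_true[t, members] = 1.0 / size
    # word noise: mix with the uniform distribution
    phi_true = (1 - spec.word_noise) * phi_true + spec.word_noise / V

    alpha = np.full(T, spec.alpha_background)
    alpha[:n_planted] = spec.alpha_phenotype

    labels: dict[str, str] = {}
    positive_like: set[str] = set()
    documents: list[DocumentRecord] = []

    def make_doc(sample_id: str, positive_like_doc: bool, presence: float) -> DocumentRecord:
        alpha_doc = alpha.copy()
        if positive_like_doc:
            # each phenotype module is carried independently, so the planted
            # topics do not co-occur perfectly (which would merge them)
            present = rng.random(n_planted) < presence
            alpha_doc[:n_planted][present] *= spec.enrichment
        theta = rng.dirichlet(alpha_doc)
        length = max(1, rng.poisson(spec.doc_length_mean))
        topics = rng.choice(T, size=length, p=theta)
        words = np.empty(length, dtype=int)
        for i, t in enumerate(topics):
            words[i] = rng.choice(V, p=phi_true[t])
        raw = np.bincount(words, minlength=V)
        counts = {
            vocab[w]: min(int(c), spec.cap) for w, c in enumerate(raw) if c > 0
        }
        return DocumentRecord(sample_id=sample_id, counts=counts)

    for i in range(spec.n_positive):
        sid = f"pos{i:03d}"
        documents.append(make_doc(sid, True, spec.presence_prob))
        labels[sid] = "positive"
    for i in range(spec.n_negative):
        sid = f"neg{i:03d}"
        documents.append(make_doc(sid, False, 0.0))
        labels[sid] = "negative"
    for i in range(spec.n_unlabeled):
        sid = f"unk{i:03d}"
        like_positive = bool(rng.random() < spec.unlabeled_positive_fraction)
        documents.append(make_doc(sid, like_positive, spec.unlabeled_presence_prob))
        labels[sid] = "unknown"
        if like_positive:
            positive_like.add(sid)

    corpus = AnnotationCorpus(documents=documents, vocabulary=list(vocab))
    table = PhenotypeTable(labels=labels)
    truth = GroundTruth(
        planted_modules=planted,
        associations=["positive-enriched"] * n_planted,
        labels=dict(labels),
        unlabeled_positive_like=positive_like,
    )
    return corpus, table, truth


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------

@dataclass
class GeneTableTruth:
    planted_spans: list[tuple[str, str, int, int]]  # sample, replicon, start, end
    decoy_replicons: list[str]


def generate_gene_table(
    module_families: frozenset[str] | set[str],
    n_planted: int = 5,
    n_decoys: int = 5,
    sample_id: str = "genome1",
    max_gap: int = 2000,
    min_genes: int = 4,
    seed: int = 0,
) -> tuple[list[GeneRecord], GeneTableTruth]:
    """Plant gene clusters satisfying the detection criteria, plus decoys.

    Each planted cluster sits on its own replicon and satisfies the gap,
    size and distinct-family criteria by construction.  Decoys violate
    exactly one criterion each (an oversized gap, too few genes, or a single
    distinct family).  Ground truth lists the planted spans.
    """
    rng = np.random.default_rng(seed)
    fams = sorted(module_families)
    if len(fams) < 2:
        raise ValueError("need at least 2 module families")

    records: list[GeneRecord] = []
    truth = GeneTableTruth(planted_spans=[], decoy_replicons=[])
    gene_no = 0

    def add_chain(replicon: str, n_genes: int, gaps: list[int], family_pool: list[str]) -> tuple[int, int]:
        nonlocal gene_no
        pos = int(rng.integers(1, 5000))
        first = pos
        for i in range(n_genes):
            length = int(rng.integers(300, 3000))
            fam = family_pool[i % len(family_pool)]
            records.append(
                GeneRecord(
                    sample_id=sample_id,
                    replicon_id=replicon,
                    gene_id=f"g{gene_no:05d}",
                    start=pos,
                    end=pos + length - 1,
                    strand="+" if rng.random() < 0.5 else "-",
                    families=frozenset({fam}),
                )
            )
            gene_no += 1
            if i < n_genes - 1:
                pos = pos + length + gaps[i]  # next.start - prev.end - 1 == gaps[i]
        return first, records[-1].end

    for k in range(n_planted):
        replicon = f"planted_rep{k}"
        n_genes = int(rng.integers(min_genes, min_genes + 5))
        gaps = [int(rng.integers(0, max_gap + 1)) for _ in range(n_genes - 1)]
        pool = list(rng.permutation(fams))[: max(2, min(len(fams), n_genes))]
        span = add_chain(replicon, n_genes, gaps, pool)
        truth.planted_spans.append((sample_id, replicon, span[0], span[1]))

    decoy_kinds = ["big_gap", "too_few", "one_family"]
    for k in range(n_decoys):
        replicon = f"decoy_rep{k}"
        kind = decoy_kinds[k % len(decoy_kinds)]
        if kind == "big_gap":
            n_genes = min_genes
            gaps = [int(rng.integers(0, max_gap + 1)) for _ in range(n_genes - 1)]
            gaps[(n_genes - 1) // 2] = int(rng.integers(max_gap + 500, max_gap + 3000))
            add_chain(replicon, n_genes, gaps, list(fams))
        elif kind == "too_few":
            n_genes = min_genes - 1
            gaps = [int(rng.integers(0, max_gap + 1)) for _ in range(n_genes - 1)]
            add_chain(replicon, n_genes, gaps, list(fams))
        else:  # one distinct family
            n_genes = min_genes
            gaps = [int(rng.integers(0, max_gap + 1)) for _ in range(n_genes - 1)]
            add_chain(replicon, n_genes, gaps, [fams[0]])
        truth.decoy_replicons.append(replicon)
    return records, truth
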