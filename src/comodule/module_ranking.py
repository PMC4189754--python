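"""Phenotype association ranking of candidate modules.

Each module gets a completeness weight per sample (the percentage of the
module's families annotated in the sample), an F_beta-optimal classification
threshold on those weights, and a rank by F score.  beta defaults to 0.5:
recall weighs half as strongly as precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from comodule.annotation_io import AnnotationCorpus, PhenotypeTable
from comodule.topic_model import FamilyModule

logger = logging.getLogger(__name__)

DEFAULT_F_BETA = 0.5


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else 0.0

    @property
    def recall(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else 0.0


@dataclass
class ModuleWeightMatrix:
    """N x T completeness weights in percent, with row/column identities."""

    W: np.ndarray
    sample_ids: list[str]
    topic_indices: list[int]

    def __post_init__(self) -> None:
        if self.W.shape != (len(self.sample_ids), len(self.topic_indices)):
            raise ValueError("weight matrix shape mismatch")

    def column(self, topic_index: int) -> np.ndarray:
        return self.W[:, self.topic_indices.index(topic_index)]


@dataclass(frozen=True)
class RankedModule:
    module: FamilyModule
    threshold_gamma: float
    f_score: float
    confusion: ConfusionCounts
    rank: int


def completeness_weights(
    modules: Sequence[FamilyModule], corpus: AnnotationCorpus
) -> ModuleWeightMatrix:
    """weight_t(d) = |M_t ∩ d| / |M_t| x 100, per document and module.

    Membership of a family in a document means count >= 1.  Columns for
    empty modules are all zero.
    """
    doc_sets = corpus.document_family_sets()
    W = np.zeros((corpus.n_documents, len(modules)))
    warned_empty = False
    for j, mod in enumerate(modules):
        size = len(mod.families)
        if size == 0:
            if not warned_empty:
                logger.info("one or more empty modules: weights set to 0")
                warned_empty = True
            continue
        for i, fams in enumerate(doc_sets):
            W[i, j] = len(mod.families & fams) * 100.0 / size
    return ModuleWeightMatrix(
        W=W,
        sample_ids=corpus.sample_ids,
        topic_indices=[m.topic_index for m in modules],
    )


def f_measure(confusion: ConfusionCounts, beta: float = DEFAULT_F_BETA) -> float:
    """F_beta from a confusion matrix; degenerate ratios are defined as 0."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    return f_measure_pr(confusion.precision, confusion.recall, beta)


def f_measure_pr(precision: float, recall: float, beta: float = DEFAULT_F_BETA) -> float:
    """F_beta = (1 + beta^2) P R / (beta^2 P + R); 0 when P = R = 0."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    denom = beta * beta * precision + recall
    if denom == 0:
        return 0.0
    return (1 + beta * beta) * precision * recall / denom


def _confusion_at(
    weights: np.ndarray, is_positive: np.ndarray, gamma: float
) -> ConfusionCounts:
    pred = weights >= gamma
    return ConfusionCounts(
        TP=int(np.sum(pred & is_positive)),
        FP=int(np.sum(pred & ~is_positive)),
        FN=int(np.sum(~pred & is_positive)),
        TN=int(np.sum(~pred & ~is_positive)),
    )


def optimize_threshold(
    weights: np.ndarray,
    is_positive: np.ndarray,
    beta: float = DEFAULT_F_BETA,
) -> tuple[float, ConfusionCounts, float]:
    """Exhaustively choose the weight threshold maximizing F_beta.

    ``weights`` and ``is_positive`` are aligned arrays over the labeled
    samples.  Candidate thresholds are the distinct observed weights plus a
    sentinel above the maximum (the all-negative classifier).  The classifier
    is ``weight >= gamma -> positive``.  Ties in F are broken toward the
    largest (most stringent) gamma.
    """
    weights = np.asarray(weights, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    if weights.shape != is_positive.shape:
        raise ValueError("weights and labels must align")
    n_pos = int(is_positive.sum())
    n_neg = int((~is_positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative labeled sample")

    candidates = np.unique(weights)
    sentinel = candidates[-1] + 1.0
    best_gamma = sentinel
    best_conf = _confusion_at(weights, is_positive, sentinel)
    best_f = f_measure(best_conf, beta)
    # scan from large to small so equal-F ties keep the largest gamma
    for gamma in candidates[::-1]:
        conf = _confusion_at(weights, is_positive, gamma)
        f = f_measure(conf, beta)
        if f > best_f:
            best_f, best_gamma, best_conf = f, float(gamma), conf
    return best_gamma, best_conf, best_f


def labeled_arrays(
    weight_matrix: ModuleWeightMatrix, labels: PhenotypeTable
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Select rows of the weight matrix for labeled samples.

    Returns (weights submatrix, boolean positive mask, labeled sample ids),
    preserving corpus document order.
    """
    rows, mask, ids = [], [], []
    for i, sid in enumerate(weight_matrix.sample_ids):
        label = labels.labels.get(sid, "unknown")
        if label == "unknown":
            continue
        rows.append(i)
        mask.append(label == "positive")
        ids.append(sid)
    if not rows:
        raise ValueError("no labeled samples present in the corpus")
    return weight_matrix.W[rows, :], np.asarray(mask, dtype=bool), ids


def rank_modules(
    modules: Sequence[FamilyModule],
    weight_matrix: ModuleWeightMatrix,
    labels: PhenotypeTable,
    beta: float = DEFAULT_F_BETA,
) -> list[RankedModule]:
    """Optimize a threshold per module and sort by F score (descending).

    Equal-F ties are resolved by topic index (stable sort) for determinism.
    """
    W_lab, is_pos, _ = labeled_arrays(weight_matrix, labels)
    scored = []
    for j, mod in enumerate(modules):
        gamma, conf, f = optimize_threshold(W_lab[:, j], is_pos, beta)
        scored.append((mod, gamma, conf, f))
    order = sorted(range(len(scored)), key=lambda j: (-scored[j][3], scored[j][0].topic_index))
    ranked = []
    for rank, j in enumerate(order, 1):
        mod, gamma, conf, f = scored[j]
        ranked.append(
            RankedModule(module=mod, threshold_gamma=gamma, f_score=f, confusion=conf, rank=rank)
        )
    return ranked


def export_ranking_tsv(ranking: Sequence[RankedModule], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\ttopic_index\tf_score\tgamma\tTP\tFP\tFN\tTN\tsize\n")
        for r in ranking:
            c = r.confusion
            fh.write(
                f"{r.rank}\t{r.module.topic_index}\t{r.f_score:.6f}\t{r.threshold_gamma:.4f}"
                f"\t{c.TP}\t{c.FP}\t{c.FN}\t{c.TN}\t{len(r.module)}\n"
            )


def export_weights_tsv(weight_matrix: ModuleWeightMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(f"m{t}" for t in weight_matrix.topic_indices) + "\n")
        for i, sid in enumerate(weight_matrix.sample_ids):
            row = "\t".join(f"{x:.4f}" for x in weight_matrix.W[i])
            fh.write(f"{sid}\t{row}\n")
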