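"""Generalization-performance estimates for module-based phenotype classifiers.

Leave-one-out and repeated 10-fold cross-validation both re-optimize the
completeness-weight threshold on the training part and predict each held-out
sample exactly once per scheme.  Exact binomial (Clopper-Pearson) intervals
quantify the uncertainty of the cross-validation accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist

from comodule.module_ranking import (
    ConfusionCounts,
    DEFAULT_F_BETA,
    f_measure,
    optimize_threshold,
)

logger = logging.getLogger(__name__)

DEFAULT_CV_FOLDS = 10
DEFAULT_CV_REPEATS = 10


@dataclass
class EvaluationReport:
    """Per-module evaluation summary plus per-sample held-out predictions."""

    module_id: str
    n_labeled: int
    loo_recall: float
    loo_precision: float
    loo_f: float
    loo_confusion: ConfusionCounts
    cv_accuracy_mean: float
    cv_macro_accuracy: float
    cv_ci_95: tuple[float, float]
    loo_predictions: dict[str, int] = field(default_factory=dict)


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval, in percent.

    lower = invBeta(alpha/2; k, n-k+1) (0 when k = 0);
    upper = invBeta(1-alpha/2; k+1, n-k) (1 when k = n).
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0 < conf < 1:
        raise ValueError("conf must be in (0, 1)")
    alpha = 1.0 - conf
    low = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return low * 100.0, high * 100.0


def _fit_or_majority(
    weights: np.ndarray, is_positive: np.ndarray, beta: float
) -> tuple[float, bool]:
    """Optimize a threshold; degenerate one-class folds fall back to the
    majority-class constant predictor.  Returns (gamma, constant_mode)."""
    n_pos = int(is_positive.sum())
    n_neg = int(is_positive.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        logger.debug("one-class training fold: predicting the majority class")
        if n_pos >= n_neg:
            return -np.inf, True  # weight >= -inf -> always positive
        return np.inf, True  # never positive
    gamma, _, _ = optimize_threshold(weights, is_positive, beta)
    return gamma, False


def loo_evaluate(
    weights: np.ndarray,
    is_positive: np.ndarray,
    beta: float = DEFAULT_F_BETA,
    sample_ids: list[str] | None = None,
) -> tuple[float, float, float, ConfusionCounts, dict[str, int]]:
    """Leave-one-out evaluation of one module's weight column.

    For every labeled sample the threshold is re-optimized on the remaining
    labeled samples and the held-out sample is predicted by
    ``weight >= gamma``.  Returns (recall, precision, F_beta, confusion,
    per-sample predictions).
    """
    weights = np.asarray(weights, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    n = weights.size
    if int(is_positive.sum()) < 2 or int((~is_positive).sum()) < 2:
        raise ValueError("need at least 2 labeled samples per class for LOO")
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]

    predictions: dict[str, int] = {}
    tp = fp = fn = tn = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        gamma, _ = _fit_or_majority(weights[mask], is_positive[mask], beta)
        pred = bool(weights[i] >= gamma)
        mask[i] = True
        predictions[sample_ids[i]] = int(pred)
        if pred and is_positive[i]:
            tp += 1
        elif pred:
            fp += 1
        elif is_positive[i]:
            fn += 1
        else:
            tn += 1
    conf = ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)
    return conf.recall, conf.precision, f_measure(conf, beta), conf, predictions


def cv_evaluate(
    weights: np.ndarray,
    is_positive: np.ndarray,
    beta: float = DEFAULT_F_BETA,
    folds: int = DEFAULT_CV_FOLDS,
    repeats: int = DEFAULT_CV_REPEATS,
    seed: int = 0,
    stratified: bool = False,
) -> tuple[float, float, tuple[float, float]]:
    """Repeated k-fold cross-validation of one module's weight column.

    Per repeat the labeled samples are randomly partitioned into ``folds``
    folds (plain random by default); per fold the threshold is optimized on
    the remainder and the held-out samples are predicted.  Returns
    (mean accuracy over repeats, macro-accuracy from pooled predictions,
    Clopper-Pearson 95% interval on round(mean_accuracy * n) of n).
    All quantities are fractions except the interval, which is in percent.
    """
    weights = np.asarray(weights, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    n = weights.size
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > n:
        raise ValueError("more folds than labeled samples")

    rng = np.random.default_rng(seed)
    repeat_seeds = rng.integers(0, 2**31 - 1, size=repeats)

    accuracies = []
    pooled_tp = pooled_fp = pooled_fn = pooled_tn = 0
    for rep in range(repeats):
        rep_rng = np.random.default_rng(int(repeat_seeds[rep]))
        if stratified:
            pos_idx = rep_rng.permutation(np.flatnonzero(is_positive))
            neg_idx = rep_rng.permutation(np.flatnonzero(~is_positive))
            fold_of = np.empty(n, dtype=int)
            fold_of[pos_idx] = np.arange(pos_idx.size) % folds
            fold_of[neg_idx] = np.arange(neg_idx.size) % folds
        else:
            perm = rep_rng.permutation(n)
            fold_of = np.empty(n, dtype=int)
            fold_of[perm] = np.arange(n) % folds
        correct = 0
        for fold in range(folds):
            test = fold_of == fold
            if not test.any():
                continue
            gamma, _ = _fit_or_majority(weights[~test], is_positive[~test], beta)
            pred = weights[test] >= gamma
            truth = is_positive[test]
            correct += int(np.sum(pred == truth))
            pooled_tp += int(np.sum(pred & truth))
            pooled_fp += int(np.sum(pred & ~truth))
            pooled_fn += int(np.sum(~pred & truth))
            pooled_tn += int(np.sum(~pred & ~truth))
        accuracies.append(correct / n)

    accuracy_mean = float(np.mean(accuracies))
    tpr = pooled_tp / (pooled_tp + pooled_fn) if pooled_tp + pooled_fn else 0.0
    tnr = pooled_tn / (pooled_tn + pooled_fp) if pooled_tn + pooled_fp else 0.0
    macro = (tpr + tnr) / 2.0
    ci = clopper_pearson(round(accuracy_mean * n), n)
    return accuracy_mean, macro, ci


def evaluate_module(
    weights: np.ndarray,
    is_positive: np.ndarray,
    module_id: str = "C1",
    beta: float = DEFAULT_F_BETA,
    folds: int = DEFAULT_CV_FOLDS,
    repeats: int = DEFAULT_CV_REPEATS,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> EvaluationReport:
    """Run both LOO and repeated CV for one module weight column."""
    recall, precision, f, conf, preds = loo_evaluate(
        weights, is_positive, beta, sample_ids=sample_ids
    )
    acc, macro, ci = cv_evaluate(
        weights, is_positive, beta, folds=folds, repeats=repeats, seed=seed
    )
    return EvaluationReport(
        module_id=module_id,
        n_labeled=int(np.asarray(weights).size),
        loo_recall=recall,
        loo_precision=precision,
        loo_f=f,
        loo_confusion=conf,
        cv_accuracy_mean=acc,
        cv_macro_accuracy=macro,
        cv_ci_95=ci,
        loo_predictions=preds,
    )


def export_report_tsv(reports: list[EvaluationReport], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "module_id\tn_labeled\tloo_recall\tloo_precision\tloo_f\t"
            "cv_accuracy\tcv_macro_accuracy\tci_low\tci_high\n"
        )
        for r in reports:
            fh.write(
                f"{r.module_id}\t{r.n_labeled}\t{r.loo_recall:.4f}\t{r.loo_precision:.4f}"
                f"\t{r.loo_f:.4f}\t{r.cv_accuracy_mean:.4f}\t{r.cv_macro_accuracy:.4f}"
                f"\t{r.cv_ci_95[0]:.2f}\t{r.cv_ci_95[1]:.2f}\n"
            )
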