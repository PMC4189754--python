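"""End-to-end orchestration: repeated fits -> ranking -> consensus -> evaluation.

Shared by the command-line interface and the test suite.  Runs are fitted
sequentially with per-run seeds derived from one master seed, so a parallel
executor could reproduce any single run independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from comodule.annotation_io import AnnotationCorpus, PhenotypeTable
from comodule.consensus import (
    ConsensusModule,
    DEFAULT_D_MAX,
    DEFAULT_MIN_RUNS_FRACTION,
    DEFAULT_N_RUNS,
    DEFAULT_QUORUM,
    DEFAULT_TOP_K,
    RunCollection,
    RunResult,
    consensus_modules_from_runs,
)
from comodule.evaluation import (
    DEFAULT_CV_FOLDS,
    DEFAULT_CV_REPEATS,
    EvaluationReport,
    evaluate_module,
)
from comodule.module_ranking import (
    DEFAULT_F_BETA,
    completeness_weights,
    labeled_arrays,
    optimize_threshold,
    rank_modules,
)
from comodule.phenotype_prediction import PredictionRecord, predict_occurrences
from comodule.topic_model import (
    DEFAULT_MODULE_CUTOFF,
    LdaConfig,
    extract_modules,
    fit_lda,
)

logger = logging.getLogger(__name__)


def derive_run_seeds(master_seed: int, n_runs: int) -> list[int]:
    """Deterministic per-run seeds from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_runs)]


def fit_run(
    corpus: AnnotationCorpus,
    labels: PhenotypeTable,
    config: LdaConfig,
    cutoff: float = DEFAULT_MODULE_CUTOFF,
    beta_f: float = DEFAULT_F_BETA,
) -> RunResult:
    """One complete run: fit, extract modules, rank by phenotype association."""
    model = fit_lda(corpus, config)
    modules = extract_modules(model, cutoff)
    weights = completeness_weights(modules, corpus)
    ranking = rank_modules(modules, weights, labels, beta_f)
    return RunResult(model=model, modules=modules, ranking=ranking)


def fit_runs(
    corpus: AnnotationCorpus,
    labels: PhenotypeTable,
    config: LdaConfig,
    n_runs: int = DEFAULT_N_RUNS,
    master_seed: int = 0,
    cutoff: float = DEFAULT_MODULE_CUTOFF,
    beta_f: float = DEFAULT_F_BETA,
) -> RunCollection:
    runs = []
    for i, seed in enumerate(derive_run_seeds(master_seed, n_runs)):
        logger.info("fitting run %d/%d (seed=%d)", i + 1, n_runs, seed)
        runs.append(fit_run(corpus, labels, config.with_seed(seed), cutoff, beta_f))
    return RunCollection(runs=runs)


@dataclass
class PipelineResult:
    collection: RunCollection
    consensus_modules: list[ConsensusModule]
    gammas: dict[str, float]
    reports: list[EvaluationReport]
    predictions: list[PredictionRecord] = field(default_factory=list)


def run_pipeline(
    corpus: AnnotationCorpus,
    labels: PhenotypeTable,
    config: LdaConfig,
    n_runs: int = DEFAULT_N_RUNS,
    master_seed: int = 0,
    cutoff: float = DEFAULT_MODULE_CUTOFF,
    beta_f: float = DEFAULT_F_BETA,
    distance: str = "jaccard",
    d_max: float = DEFAULT_D_MAX,
    top_k: int = DEFAULT_TOP_K,
    quorum: int = DEFAULT_QUORUM,
    min_runs_fraction: float = DEFAULT_MIN_RUNS_FRACTION,
    cv_folds: int = DEFAULT_CV_FOLDS,
    cv_repeats: int = DEFAULT_CV_REPEATS,
    predict_unlabeled: bool = True,
) -> PipelineResult:
    """Full pipeline on one corpus with labels.

    Consensus modules get production thresholds optimized on the full
    learning set; LOO / CV evaluation quantifies generalization; unlabeled
    samples receive occurrence predictions.
    """
    collection = fit_runs(corpus, labels, config, n_runs, master_seed, cutoff, beta_f)
    consensus = consensus_modules_from_runs(
        collection,
        distance=distance,
        d_max=d_max,
        top_k=top_k,
        quorum=quorum,
        min_runs_fraction=min_runs_fraction,
    )

    doc_sets = corpus.document_family_sets()
    gammas: dict[str, float] = {}
    reports: list[EvaluationReport] = []
    eval_seeds = derive_run_seeds(master_seed + 1, max(1, len(consensus)))
    for i, mod in enumerate(consensus):
        w = np.array(
            [
                (len(mod.families & fams) * 100.0 / len(mod.families) if mod.families else 0.0)
                for fams in doc_sets
            ]
        )
        from comodule.module_ranking import ModuleWeightMatrix

        wm = ModuleWeightMatrix(W=w[:, None], sample_ids=corpus.sample_ids, topic_indices=[0])
        W_lab, is_pos, lab_ids = labeled_arrays(wm, labels)
        gamma, _, _ = optimize_threshold(W_lab[:, 0], is_pos, beta_f)
        gammas[mod.consensus_id] = gamma
        reports.append(
            evaluate_module(
                W_lab[:, 0],
                is_pos,
                module_id=mod.consensus_id,
                beta=beta_f,
                folds=cv_folds,
                repeats=cv_repeats,
                seed=eval_seeds[i],
                sample_ids=lab_ids,
            )
        )

    predictions: list[PredictionRecord] = []
    if predict_unlabeled and consensus:
        unlabeled = [
            s for s in corpus.sample_ids if labels.labels.get(s, "unknown") == "unknown"
        ]
        if unlabeled:
            predictions = predict_occurrences(
                corpus,
                {m.consensus_id: m.families for m in consensus},
                gammas,
                sample_ids=unlabeled,
            )
    return PipelineResult(
        collection=collection,
        consensus_modules=consensus,
        gammas=gammas,
        reports=reports,
        predictions=predictions,
    )
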