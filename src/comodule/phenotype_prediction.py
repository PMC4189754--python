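"""Module-occurrence prediction and the saprophyte family-count rule."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from comodule.annotation_io import AnnotationCorpus, DocumentRecord

CELLULASE_FAMILIES = frozenset(
    {"GH5", "GH6", "GH8", "GH9", "GH12", "GH44", "GH45", "GH48", "GH74", "GH124"}
)
HEMI_PECTINASE_FAMILIES = frozenset(
    {
        "GH10", "GH11", "GH26", "GH28", "GH30", "GH43", "GH53", "GH67", "GH78",
        "PL1", "PL2", "PL9", "PL10", "PL11", "PL22",
    }
)


@dataclass(frozen=True)
class PredictionRecord:
    sample_id: str
    module_id: str
    weight: float  # percent
    gamma: float  # percent
    predicted: int  # 1 iff weight >= gamma

    def __post_init__(self) -> None:
        if self.predicted != int(self.weight >= self.gamma):
            raise ValueError("predicted flag inconsistent with weight/gamma")


@dataclass(frozen=True)
class SaprophyteRule:
    """At least ``min_cellulases`` cellulase families and ``min_hemi``
    hemicellulase/pectinase families, counted as distinct families."""

    cellulase_families: frozenset[str] = CELLULASE_FAMILIES
    hemi_pectinase_families: frozenset[str] = HEMI_PECTINASE_FAMILIES
    min_cellulases: int = 1
    min_hemi: int = 3


def module_weight(families: frozenset[str] | set[str], document_families: Iterable[str]) -> float:
    """Completeness of one family set in one document, in percent."""
    if not families:
        return 0.0
    present = set(document_families)
    return len(set(families) & present) * 100.0 / len(families)


def predict_occurrences(
    corpus: AnnotationCorpus,
    module_families: Mapping[str, frozenset[str] | set[str]],
    gammas: Mapping[str, float],
    sample_ids: Sequence[str] | None = None,
) -> list[PredictionRecord]:
    """Predict presence of each module in each (selected) sample.

    ``gammas`` holds the production thresholds (percent) optimized on the
    full learning set; the rule is ``weight >= gamma -> present``, with the
    boundary inclusive.  Unknown module ids in ``gammas`` are an error.
    """
    unknown = set(gammas) - set(module_families)
    if unknown:
        raise KeyError(f"thresholds for unknown module ids: {sorted(unknown)}")
    wanted = set(sample_ids) if sample_ids is not None else None
    records = []
    for doc in corpus.documents:
        if wanted is not None and doc.sample_id not in wanted:
            continue
        fams = doc.families
        for module_id, gamma in gammas.items():
            w = module_weight(module_families[module_id], fams)
            records.append(
                PredictionRecord(
                    sample_id=doc.sample_id,
                    module_id=module_id,
                    weight=w,
                    gamma=float(gamma),
                    predicted=int(w >= gamma),
                )
            )
    return records


def classify_saprophyte(
    document: DocumentRecord, rule: SaprophyteRule = SaprophyteRule()
) -> bool:
    """Apply the fixed family-list rule to one document."""
    fams = document.families
    n_cel = len(fams & rule.cellulase_families)
    n_hemi = len(fams & rule.hemi_pectinase_families)
    return n_cel >= rule.min_cellulases and n_hemi >= rule.min_hemi


def co_assignment_matrix(
    records: Sequence[PredictionRecord],
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Summarize joint module assignments across samples.

    Returns (module ids, counts matrix J with J[i, j] = number of samples
    predicted positive for both modules i and j, fraction matrix F with
    F[i, j] = J[i, j] / J[i, i], 0 when module i has no assignments).
    """
    module_ids = sorted({r.module_id for r in records})
    idx = {m: i for i, m in enumerate(module_ids)}
    by_sample: dict[str, set[str]] = {}
    for r in records:
        if r.predicted:
            by_sample.setdefault(r.sample_id, set()).add(r.module_id)
    J = np.zeros((len(module_ids), len(module_ids)), dtype=int)
    for assigned in by_sample.values():
        for a in assigned:
            for b in assigned:
                J[idx[a], idx[b]] += 1
    diag = np.diag(J).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(diag[:, None] > 0, J / diag[:, None], 0.0)
    return module_ids, J, F


def export_predictions_tsv(records: Sequence[PredictionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tmodule_id\tweight\tgamma\tpredicted\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.module_id}\t{r.weight:.4f}\t{r.gamma:.4f}\t{r.predicted}\n")


def export_saprophytes_tsv(corpus: AnnotationCorpus, path, rule: SaprophyteRule = SaprophyteRule()) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tsaprophyte\n")
        for doc in corpus.documents:
            fh.write(f"{doc.sample_id}\t{int(classify_saprophyte(doc, rule))}\n")
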