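"""Read, filter and normalize protein-family annotations into a corpus.

Annotation sources are either pre-made TSV tables
(``sample_id<TAB>protein_id<TAB>family_id[<TAB>evalue<TAB>bitscore<TAB>db<TAB>model_len<TAB>ga]``)
or raw HMMER3 ``--domtblout`` files that are filtered by e-value / bit-score
criteria before counting.  Documents are bags of protein-family identifiers:
for every sample the number of distinct annotated proteins per family is
counted and truncated at a cap (default 10).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

DEFAULT_EVALUE = 1e-2
MIN_BITSCORE = 25.0
LARGE_FAMILY_EVALUE = 1e-4
LARGE_FAMILY_LEN = 100
DEFAULT_COUNT_CAP = 10

_LABEL_ALIASES = {
    "positive": "positive",
    "pos": "positive",
    "+": "positive",
    "1": "positive",
    "true": "positive",
    "yes": "positive",
    "negative": "negative",
    "neg": "negative",
    "-": "negative",
    "−": "negative",  # unicode minus
    "0": "negative",
    "false": "negative",
    "no": "negative",
    "unknown": "unknown",
    "?": "unknown",
    "na": "unknown",
    "nan": "unknown",
    "": "unknown",
}


class ParseError(ValueError):
    """Raised when an input record cannot be interpreted."""


@dataclass(frozen=True)
class HmmerHit:
    """A single profile-HMM match of a protein against a family model."""

    protein_id: str
    family_id: str
    evalue: float
    bitscore: float
    family_db: str = "pfam"  # {"pfam", "dbcan"}
    model_length: int = 0
    gathering_threshold: float | None = None

    def __post_init__(self) -> None:
        if not self.family_id:
            raise ParseError("family_id must be nonempty")
        if self.evalue <= 0:
            raise ParseError(
                f"non-positive e-value {self.evalue!r} for protein {self.protein_id!r}"
            )
        if self.family_db not in ("pfam", "dbcan"):
            raise ParseError(f"unknown family_db {self.family_db!r}")


@dataclass(frozen=True)
class DocumentRecord:
    """One sample's bag of family counts (each count already capped)."""

    sample_id: str
    counts: Mapping[str, int]
    source_kind: str = "genome"  # {"genome", "metagenome_bin"}

    @property
    def families(self) -> frozenset[str]:
        return frozenset(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class AnnotationCorpus:
    """An ordered document collection with an ordered family vocabulary."""

    documents: list[DocumentRecord]
    vocabulary: list[str]

    def __post_init__(self) -> None:
        vocab = set(self.vocabulary)
        seen: set[str] = set()
        for doc in self.documents:
            if doc.sample_id in seen:
                raise ValueError(f"duplicate sample_id {doc.sample_id!r}")
            seen.add(doc.sample_id)
            missing = set(doc.counts) - vocab
            if missing:
                raise ValueError(
                    f"families {sorted(missing)} of sample {doc.sample_id!r} "
                    "missing from vocabulary"
                )

    @property
    def n_documents(self) -> int:
        return len(self.documents)

    @property
    def n_families(self) -> int:
        return len(self.vocabulary)

    @property
    def sample_ids(self) -> list[str]:
        return [d.sample_id for d in self.documents]

    def family_index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.vocabulary)}

    def document_family_sets(self) -> list[frozenset[str]]:
        return [d.families for d in self.documents]

    def total_tokens(self) -> int:
        """Total token count seen by the Gibbs sampler (sum of all counts)."""
        return sum(d.total for d in self.documents)


@dataclass
class PhenotypeTable:
    """Mapping of sample ids to phenotype labels."""

    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {"positive", "negative", "unknown"}
        if bad:
            raise ValueError(f"invalid labels: {sorted(bad)}")

    def labeled_ids(self) -> list[str]:
        return [s for s, l in self.labels.items() if l != "unknown"]

    def positives(self) -> set[str]:
        return {s for s, l in self.labels.items() if l == "positive"}

    def negatives(self) -> set[str]:
        return {s for s, l in self.labels.items() if l == "negative"}


# ---------------------------------------------------------------------------
# HMMER hit filtering
# ---------------------------------------------------------------------------

def filter_hmmer_hits(
    hits: Iterable[HmmerHit],
    default_evalue: float = DEFAULT_EVALUE,
    min_bitscore: float = MIN_BITSCORE,
    large_family_evalue: float = LARGE_FAMILY_EVALUE,
    large_family_len: int = LARGE_FAMILY_LEN,
) -> list[HmmerHit]:
    """Apply the annotation acceptance criteria to raw HMMER hits.

    A hit is kept iff its bit score is at least ``min_bitscore``, its e-value
    is at most the applicable threshold, and -- for pfam hits that carry a
    gathering threshold -- the bit score also satisfies the gathering
    threshold when that is stricter than the default.  The applicable e-value
    threshold is ``large_family_evalue`` for dbcan hits whose profile is
    longer than ``large_family_len`` amino acids, else ``default_evalue``.
    Multiple hits per protein (to different families) are all retained.
    """
    kept: list[HmmerHit] = []
    for hit in hits:
        if hit.bitscore < min_bitscore:
            continue
        threshold = default_evalue
        if hit.family_db == "dbcan" and hit.model_length > large_family_len:
            threshold = large_family_evalue
        if hit.evalue > threshold:
            continue
        if hit.family_db == "pfam" and hit.gathering_threshold is not None:
            if hit.bitscore < max(min_bitscore, hit.gathering_threshold):
                continue
        kept.append(hit)
    return kept


def parse_domtblout(path: str | Path, family_db: str = "pfam") -> list[HmmerHit]:
    """Parse a HMMER3 ``--domtblout`` file into hits.

    Uses the standard whitespace-separated 22+ column layout; full-sequence
    e-value (col 7) and bit score (col 8) are used, and the profile length is
    taken from column 6 ("qlen").  The target name (col 1) is the protein,
    the query name (col 4) the family model.
    """
    hits: list[HmmerHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 22:
                raise ParseError(f"{path}:{lineno}: expected >=22 columns, got {len(parts)}")
            try:
                evalue = float(parts[6])
                bitscore = float(parts[7])
                qlen = int(parts[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            family_id = parts[3]
            # strip a Pfam accession version suffix if the accession column
            # is informative and the name is generic
            accession = parts[4]
            if family_db == "pfam" and accession not in ("-", ""):
                family_id = accession.split(".")[0]
            if evalue <= 0:
                raise ParseError(f"{path}:{lineno}: non-positive e-value {evalue}")
            hits.append(
                HmmerHit(
                    protein_id=parts[0],
                    family_id=family_id,
                    evalue=evalue,
                    bitscore=bitscore,
                    family_db=family_db,
                    model_length=qlen,
                )
            )
    return hits


def read_annotation_table(path: str | Path) -> list[tuple[str, HmmerHit]]:
    """Read an annotation TSV into (sample_id, hit) pairs.

    Columns: ``sample_id  protein_id  family_id  [evalue  bitscore  db
    model_len  ga]``.  Missing optional columns default to values that pass
    every filter, so pre-filtered tables can be used directly.
    """
    rows: list[tuple[str, HmmerHit]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        if ncol < 3:
            raise ParseError(f"{path}: need at least 3 columns, got {ncol}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: need at least 3 fields")
            sample_id, protein_id, family_id = parts[0], parts[1], parts[2]
            evalue = float(parts[3]) if len(parts) > 3 and parts[3] else 1e-30
            bitscore = float(parts[4]) if len(parts) > 4 and parts[4] else 1e6
            db = parts[5] if len(parts) > 5 and parts[5] else "pfam"
            model_len = int(parts[6]) if len(parts) > 6 and parts[6] else 0
            ga = float(parts[7]) if len(parts) > 7 and parts[7] else None
            if evalue <= 0:
                raise ParseError(f"{path}:{lineno}: non-positive e-value {evalue}")
            rows.append(
                (
                    sample_id,
                    HmmerHit(
                        protein_id=protein_id,
                        family_id=family_id,
                        evalue=evalue,
                        bitscore=bitscore,
                        family_db=db,
                        model_length=model_len,
                        gathering_threshold=ga,
                    ),
                )
            )
    return rows


# ---------------------------------------------------------------------------
# Corpus construction
# ---------------------------------------------------------------------------

def build_corpus(
    annotations: Mapping[str, Iterable[HmmerHit]] | Sequence[tuple[str, Iterable[HmmerHit]]],
    cap: int = DEFAULT_COUNT_CAP,
    source_kinds: Mapping[str, str] | None = None,
    count_domains: bool = False,
) -> AnnotationCorpus:
    """Turn filtered annotations grouped by sample into a corpus.

    Per sample, the number of distinct proteins annotated with each family is
    counted (``count_domains=True`` switches to counting every hit, i.e.
    domain-level counting) and each count is truncated at ``cap``.  The
    vocabulary is the lexicographically sorted union of retained families;
    document order follows input order.  Samples with zero annotations are
    retained as empty documents with a warning.
    """
    if cap < 1:
        raise ValueError(f"cap must be >= 1, got {cap}")
    if isinstance(annotations, Mapping):
        items = list(annotations.items())
    else:
        items = list(annotations)
    source_kinds = source_kinds or {}

    documents: list[DocumentRecord] = []
    vocab: set[str] = set()
    for sample_id, hits in items:
        if count_domains:
            raw: dict[str, int] = {}
            for h in hits:
                raw[h.family_id] = raw.get(h.family_id, 0) + 1
        else:
            proteins: dict[str, set[str]] = {}
            for h in hits:
                proteins.setdefault(h.family_id, set()).add(h.protein_id)
            raw = {fam: len(p) for fam, p in proteins.items()}
        counts = {fam: min(c, cap) for fam, c in sorted(raw.items())}
        if not counts:
            warnings.warn(f"sample {sample_id!r} has no annotations; kept as empty document")
        vocab.update(counts)
        documents.append(
            DocumentRecord(
                sample_id=sample_id,
                counts=counts,
                source_kind=source_kinds.get(sample_id, "genome"),
            )
        )
    return AnnotationCorpus(documents=documents, vocabulary=sorted(vocab))


def corpus_from_counts(
    counts_by_sample: Sequence[tuple[str, Mapping[str, int]]],
    cap: int = DEFAULT_COUNT_CAP,
    vocabulary: Sequence[str] | None = None,
) -> AnnotationCorpus:
    """Build a corpus directly from per-sample family count mappings."""
    documents = []
    vocab: set[str] = set()
    for sample_id, counts in counts_by_sample:
        capped = {f: min(int(c), cap) for f, c in sorted(counts.items()) if c >= 1}
        vocab.update(capped)
        documents.append(DocumentRecord(sample_id=sample_id, counts=capped))
    if vocabulary is None:
        vocabulary = sorted(vocab)
    return AnnotationCorpus(documents=documents, vocabulary=list(vocabulary))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_corpus(corpus: AnnotationCorpus, path: str | Path) -> None:
    """Write a corpus as a count TSV plus a JSON sidecar with ordering.

    ``path`` receives TSV rows ``sample_id  family_id  count``; the sidecar
    ``<path>.json`` stores the vocabulary order, document order and source
    kinds so that ``read_corpus(write_corpus(c)) == c`` exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample_id\tfamily_id\tcount\n")
        for doc in corpus.documents:
            for fam, c in doc.counts.items():
                fh.write(f"{doc.sample_id}\t{fam}\t{c}\n")
    sidecar = {
        "vocabulary": corpus.vocabulary,
        "documents": [d.sample_id for d in corpus.documents],
        "source_kinds": {d.sample_id: d.source_kind for d in corpus.documents},
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_corpus(path: str | Path) -> AnnotationCorpus:
    """Read a corpus written by :func:`write_corpus`."""
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    counts: dict[str, dict[str, int]] = {s: {} for s in sidecar["documents"]}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sample_id"):
            raise ParseError(f"{path}: missing header")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            sample_id, fam, c = line.rstrip("\n").split("\t")
            counts[sample_id][fam] = int(c)
    documents = [
        DocumentRecord(
            sample_id=s,
            counts=counts[s],
            source_kind=sidecar["source_kinds"].get(s, "genome"),
        )
        for s in sidecar["documents"]
    ]
    return AnnotationCorpus(documents=documents, vocabulary=sidecar["vocabulary"])


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype label TSV (``sample_id<TAB>label``, with header).

    Labels are case-insensitive; the aliases ``+``/``-``/``?`` (and a few
    common spellings) are accepted.  Duplicate sample ids and unknown label
    tokens are errors.
    """
    labels: dict[str, str] = {}
    with open(path) as fh:
        fh.readline()  # header
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields")
            sample_id, token = parts[0], parts[1]
            if sample_id in labels:
                raise ParseError(f"{path}:{lineno}: duplicate sample_id {sample_id!r}")
            key = token.strip().lower()
            if key not in _LABEL_ALIASES:
                raise ParseError(f"{path}:{lineno}: unknown label {token!r}")
            labels[sample_id] = _LABEL_ALIASES[key]
    return PhenotypeTable(labels=labels)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tphenotype\n")
        for sample_id, label in table.labels.items():
            fh.write(f"{sample_id}\t{label}\n")
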