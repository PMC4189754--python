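"""Gene-cluster detection for module-annotated genes on replicons.

A cluster is a maximal chain of neighboring genes that carry at least one
family of a given consensus module, with intergenic distances of at most
``max_gap`` (default 2000 bp) between consecutive genes, at least
``min_genes`` (default 4) genes, and at least ``min_distinct_families``
(default 2) distinct module families.  Coordinates are 1-based inclusive;
the intergenic distance between genes a < b is max(0, b.start - a.end - 1).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

DEFAULT_MAX_GAP = 2000
DEFAULT_MIN_GENES = 4
DEFAULT_MIN_DISTINCT_FAMILIES = 2


@dataclass(frozen=True)
class GeneRecord:
    sample_id: str
    replicon_id: str
    gene_id: str
    start: int
    end: int
    strand: str = "unknown"  # stored, unused
    families: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"malformed coordinates for gene {self.gene_id!r}: "
                f"start={self.start}, end={self.end}"
            )


@dataclass
class GeneCluster:
    sample_id: str
    replicon_id: str
    module_id: str  # or "distinct" after merging
    genes: list[str]
    span: tuple[int, int]
    gaps: list[int]
    distinct_families: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


def intergenic_distance(a: GeneRecord, b: GeneRecord) -> int:
    """Distance in bp between two genes, 0 when they overlap or abut."""
    first, second = (a, b) if a.start <= b.start else (b, a)
    return max(0, second.start - first.end - 1)


def detect_clusters(
    genes: Iterable[GeneRecord],
    module_families: frozenset[str] | set[str],
    module_id: str = "C1",
    max_gap: int = DEFAULT_MAX_GAP,
    min_genes: int = DEFAULT_MIN_GENES,
    min_distinct_families: int = DEFAULT_MIN_DISTINCT_FAMILIES,
    strict_neighbors: bool = False,
) -> list[GeneCluster]:
    """Find clusters of neighboring genes annotated with module families.

    Only genes carrying at least one module family are considered; maximal
    chains of such genes with consecutive intergenic distances <= ``max_gap``
    are kept when they have >= ``min_genes`` genes and >=
    ``min_distinct_families`` distinct module families.  Intervening
    unannotated genes do not break a chain unless ``strict_neighbors`` is
    set, in which case chain members must also be adjacent in the full gene
    order of the replicon.
    """
    module_families = frozenset(module_families)
    by_replicon: dict[tuple[str, str], list[GeneRecord]] = defaultdict(list)
    for g in genes:
        by_replicon[(g.sample_id, g.replicon_id)].append(g)

    clusters: list[GeneCluster] = []
    for (sample_id, replicon_id), replicon_genes in sorted(by_replicon.items()):
        ordered = sorted(replicon_genes, key=lambda g: (g.start, g.end, g.gene_id))
        annotated = [
            (pos, g) for pos, g in enumerate(ordered) if g.families & module_families
        ]
        chain: list[tuple[int, GeneRecord]] = []
        for item in annotated:
            if not chain:
                chain = [item]
                continue
            prev_pos, prev_gene = chain[-1]
            pos, gene = item
            ok = intergenic_distance(prev_gene, gene) <= max_gap
            if strict_neighbors:
                ok = ok and pos == prev_pos + 1
            if ok:
                chain.append(item)
            else:
                clusters.extend(
                    _emit(chain, sample_id, replicon_id, module_id, module_families,
                          min_genes, min_distinct_families)
                )
                chain = [item]
        clusters.extend(
            _emit(chain, sample_id, replicon_id, module_id, module_families,
                  min_genes, min_distinct_families)
        )
    return clusters


def _emit(
    chain: list[tuple[int, GeneRecord]],
    sample_id: str,
    replicon_id: str,
    module_id: str,
    module_families: frozenset[str],
    min_genes: int,
    min_distinct_families: int,
) -> list[GeneCluster]:
    if len(chain) < min_genes:
        return []
    genes = [g for _, g in chain]
    distinct = frozenset().union(*(g.families & module_families for g in genes))
    if len(distinct) < min_distinct_families:
        return []
    gaps = [intergenic_distance(a, b) for a, b in zip(genes, genes[1:])]
    return [
        GeneCluster(
            sample_id=sample_id,
            replicon_id=replicon_id,
            module_id=module_id,
            genes=[g.gene_id for g in genes],
            span=(min(g.start for g in genes), max(g.end for g in genes)),
            gaps=gaps,
            distinct_families=distinct,
        )
    ]


def merge_distinct(clusters: Sequence[GeneCluster]) -> list[GeneCluster]:
    """Union clusters (across modules) whose spans overlap on one replicon.

    Output spans are pairwise non-overlapping; gene lists and family sets
    are unioned, gaps are recomputed from the merged span ordering and the
    module id becomes ``distinct``.
    """
    by_replicon: dict[tuple[str, str], list[GeneCluster]] = defaultdict(list)
    for c in clusters:
        by_replicon[(c.sample_id, c.replicon_id)].append(c)

    merged: list[GeneCluster] = []
    for (sample_id, replicon_id), group in sorted(by_replicon.items()):
        group = sorted(group, key=lambda c: c.span)
        current: list[GeneCluster] = [group[0]]
        lo, hi = group[0].span
        for c in group[1:]:
            if c.span[0] <= hi:  # overlapping (or touching) spans
                current.append(c)
                hi = max(hi, c.span[1])
            else:
                merged.append(_union(current, sample_id, replicon_id, (lo, hi)))
                current, (lo, hi) = [c], c.span
        merged.append(_union(current, sample_id, replicon_id, (lo, hi)))
    return merged


def _union(
    group: list[GeneCluster], sample_id: str, replicon_id: str, span: tuple[int, int]
) -> GeneCluster:
    if len(group) == 1:
        c = group[0]
        return GeneCluster(
            sample_id=sample_id,
            replicon_id=replicon_id,
            module_id="distinct",
            genes=list(c.genes),
            span=c.span,
            gaps=list(c.gaps),
            distinct_families=c.distinct_families,
        )
    genes = sorted({g for c in group for g in c.genes})
    families = frozenset().union(*(c.distinct_families for c in group))
    gaps = [g for c in group for g in c.gaps]
    return GeneCluster(
        sample_id=sample_id,
        replicon_id=replicon_id,
        module_id="distinct",
        genes=genes,
        span=span,
        gaps=gaps,
        distinct_families=families,
    )


def cluster_stats(
    clusters: Sequence[GeneCluster], module_families: frozenset[str] | set[str]
) -> tuple[float | None, float | None]:
    """(mean intergenic distance over all gaps, % of module families covered).

    Both are ``None`` when there are no clusters (no gaps / no coverage to
    report).
    """
    gaps = [g for c in clusters for g in c.gaps]
    if not clusters:
        return None, None
    mean_gap = sum(gaps) / len(gaps) if gaps else None
    module_families = frozenset(module_families)
    covered = frozenset().union(*(c.distinct_families for c in clusters)) & module_families
    coverage = len(covered) / len(module_families) * 100.0 if module_families else None
    return mean_gap, coverage


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_gff3_genes(
    path: str | Path,
    sample_id: str,
    family_attribute: str = "families",
    family_table: Mapping[str, Iterable[str]] | None = None,
    feature_types: tuple[str, ...] = ("gene", "CDS"),
) -> list[GeneRecord]:
    """Read gene features from a GFF3 file.

    Family annotations come from a comma-separated attribute (default key
    ``families``) or from ``family_table`` mapping gene ids to family ids;
    the table takes precedence when both are present.
    """
    records: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype not in feature_types:
                continue
            attributes = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attributes.get("ID", f"{seqid}:{start}-{end}")
            if gene_id in seen:
                continue  # gene + CDS rows for the same feature
            seen.add(gene_id)
            if family_table is not None and gene_id in family_table:
                families = frozenset(family_table[gene_id])
            else:
                raw = attributes.get(family_attribute, "")
                families = frozenset(f for f in raw.split(",") if f)
            records.append(
                GeneRecord(
                    sample_id=sample_id,
                    replicon_id=seqid,
                    gene_id=gene_id,
                    start=int(start),
                    end=int(end),
                    strand=strand if strand in "+-" else "unknown",
                    families=families,
                )
            )
    return records


def export_clusters_tsv(clusters: Sequence[GeneCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\treplicon_id\tmodule_id\tn_genes\tstart\tend\tgenes\tfamilies\tgaps\n")
        for c in clusters:
            fh.write(
                f"{c.sample_id}\t{c.replicon_id}\t{c.module_id}\t{len(c)}\t{c.span[0]}"
                f"\t{c.span[1]}\t{','.join(c.genes)}\t{','.join(sorted(c.distinct_families))}"
                f"\t{','.join(map(str, c.gaps))}\n"
            )


def export_clusters_bed(clusters: Sequence[GeneCluster], path: str | Path) -> None:
    """BED export: 0-based half-open (start-1, end) conversion."""
    with open(path, "w") as fh:
        for c in clusters:
            name = f"{c.sample_id}|{c.module_id}|{len(c)}genes"
            fh.write(f"{c.replicon_id}\t{c.span[0] - 1}\t{c.span[1]}\t{name}\n")
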