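"""Cross-run module stabilization: matching, cliques, consensus sets.

MCMC topic inference varies between runs, so the pipeline is repeated
(default 18 runs) and modules are tracked across runs: pairwise distances
(Jaccard on discrete modules, or symmetrized KL on topic distributions) feed
a Hungarian assignment per run pair; matched pairs among each run's
top-ranked modules become graph edges; maximal cliques spanning enough runs
become consensus modules containing every family that reaches a quorum of
the clique's member modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from comodule.module_ranking import RankedModule
from comodule.topic_model import FamilyModule, TopicModel

DEFAULT_N_RUNS = 18
DEFAULT_TOP_K = 15
DEFAULT_D_MAX = 0.7
DEFAULT_QUORUM = 9
DEFAULT_MIN_RUNS_FRACTION = 0.75


def default_min_runs(n_runs: int, fraction: float = DEFAULT_MIN_RUNS_FRACTION) -> int:
    """Minimum distinct runs a stable clique must span: ceil(fraction * R)."""
    return math.ceil(fraction * n_runs)


@dataclass
class RunResult:
    """One LDA run: fitted model, extracted modules, phenotype ranking."""

    model: TopicModel
    modules: list[FamilyModule]
    ranking: list[RankedModule]

    def top_topic_indices(self, k: int) -> set[int]:
        return {r.module.topic_index for r in self.ranking[:k]}


@dataclass
class RunCollection:
    runs: list[RunResult]

    def __post_init__(self) -> None:
        refs = {r.model.corpus_ref for r in self.runs}
        if len(refs) > 1:
            raise ValueError("all runs must share the same corpus")

    def __len__(self) -> int:
        return len(self.runs)


@dataclass
class ModuleGraph:
    """Nodes are (run_index, topic_index); edges join matched similar modules."""

    graph: nx.Graph
    distance: str
    d_max: float
    top_k: int

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges


@dataclass
class ConsensusModule:
    """Quorum family set derived from one stable cross-run clique."""

    consensus_id: str
    members: frozenset[tuple[int, int]]
    families: frozenset[str]
    sub_quorum_families: frozenset[str]
    quorum: int
    min_runs: int
    family_support: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.families)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def jaccard_distance(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """1 - |A∩B| / |A∪B|; the distance between two empty sets is 0."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return 1.0 - len(set(a) & set(b)) / union


def sym_kl_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Symmetrized KL divergence (natural log): (KL(p||q) + KL(q||p)) / 2.

    Both arguments must be strictly positive distributions; the
    beta-smoothed phi estimates of a fitted model always are.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have equal length")
    if np.any(p <= 0) or np.any(q <= 0):
        raise ValueError("distributions must be strictly positive")
    log_ratio = np.log(p / q)
    return float(0.5 * np.sum(p * log_ratio) + 0.5 * np.sum(q * -log_ratio))


# ---------------------------------------------------------------------------
# Matching and cliques
# ---------------------------------------------------------------------------

def hungarian_mapping(D: np.ndarray) -> dict[int, int]:
    """Minimal-cost perfect matching of a square distance matrix.

    Returns the bijection row topic -> column topic.  Backed by
    scipy's linear_sum_assignment (Jonker-Volgenant); the returned matching
    attains the brute-force optimum.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"distance matrix must be square, got shape {D.shape}")
    if not np.all(np.isfinite(D)) or np.any(D < 0):
        raise ValueError("distance matrix must be finite and non-negative")
    rows, cols = linear_sum_assignment(D)
    return {int(r): int(c) for r, c in zip(rows, cols)}


def _pair_distance_matrix(run_a: RunResult, run_b: RunResult, distance: str) -> np.ndarray:
    T = len(run_a.modules)
    D = np.empty((T, T))
    if distance == "jaccard":
        for i, ma in enumerate(run_a.modules):
            for j, mb in enumerate(run_b.modules):
                D[i, j] = jaccard_distance(ma.families, mb.families)
    elif distance == "sym_kl":
        pa, pb = run_a.model.phi, run_b.model.phi
        # vectorized symmetric KL over all topic pairs
        log_a, log_b = np.log(pa), np.log(pb)
        ent_a = np.sum(pa * log_a, axis=1)
        ent_b = np.sum(pb * log_b, axis=1)
        cross_ab = pa @ log_b.T  # sum_w p_a log p_b
        cross_ba = pb @ log_a.T
        D = 0.5 * (ent_a[:, None] - cross_ab) + 0.5 * (ent_b[None, :] - cross_ba.T)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    return D


def build_module_graph(
    collection: RunCollection,
    distance: str = "jaccard",
    d_max: float = DEFAULT_D_MAX,
    top_k: int = DEFAULT_TOP_K,
    filter_before_matching: bool = False,
) -> ModuleGraph:
    """Match modules across every run pair and keep close, high-ranked pairs.

    For each run pair the full T x T distance matrix is computed and
    Hungarian-matched; an edge (run_a, t_a) -- (run_b, t_b) is added when
    both endpoints are in their runs' top-``top_k`` ranked modules and the
    pair's distance is at most ``d_max``.  With ``filter_before_matching``
    the assignment itself is restricted to the top-k submatrices.
    """
    if len(collection) < 2:
        raise ValueError("need at least 2 runs")
    if d_max <= 0:
        raise ValueError("d_max must be positive")

    G = nx.Graph()
    top_sets = [run.top_topic_indices(top_k) for run in collection.runs]
    for r, top in enumerate(top_sets):
        for t in top:
            G.add_node((r, t))

    for ra, rb in combinations(range(len(collection)), 2):
        run_a, run_b = collection.runs[ra], collection.runs[rb]
        if filter_before_matching:
            idx_a = sorted(top_sets[ra])
            idx_b = sorted(top_sets[rb])
            if len(idx_a) != len(idx_b):
                k = min(len(idx_a), len(idx_b))
                idx_a, idx_b = idx_a[:k], idx_b[:k]
            D_full = _pair_distance_matrix(run_a, run_b, distance)
            D = D_full[np.ix_(idx_a, idx_b)]
            mapping = hungarian_mapping(D)
            pairs = [(idx_a[i], idx_b[j], D[i, j]) for i, j in mapping.items()]
        else:
            D = _pair_distance_matrix(run_a, run_b, distance)
            mapping = hungarian_mapping(D)
            pairs = [(i, j, D[i, j]) for i, j in mapping.items()]
        for ta, tb, d in pairs:
            if d <= d_max and ta in top_sets[ra] and tb in top_sets[rb]:
                G.add_edge((ra, ta), (rb, tb), distance=float(d))
    return ModuleGraph(graph=G, distance=distance, d_max=d_max, top_k=top_k)


def _mean_internal_distance(graph: nx.Graph, clique: Sequence[tuple[int, int]]) -> float:
    dists = [
        graph.edges[u, v]["distance"]
        for u, v in combinations(clique, 2)
        if graph.has_edge(u, v)
    ]
    return float(np.mean(dists)) if dists else 0.0


def find_stable_cliques(
    module_graph: ModuleGraph, min_runs: int
) -> list[frozenset[tuple[int, int]]]:
    """Maximal cliques spanning at least ``min_runs`` distinct runs.

    Cliques come from Bron-Kerbosch enumeration with pivoting (networkx
    ``find_cliques``).  Because the graph has no intra-run edges, a clique
    holds at most one module per run.  Overlapping retained cliques are
    resolved greedily: larger cliques win, ties by smaller mean internal
    distance, then lexicographic node order for determinism.
    """
    G = module_graph.graph
    retained = [
        frozenset(c)
        for c in nx.find_cliques(G)
        if len({node[0] for node in c}) >= min_runs
    ]
    retained.sort(
        key=lambda c: (-len(c), _mean_internal_distance(G, sorted(c)), sorted(c))
    )
    chosen: list[frozenset[tuple[int, int]]] = []
    used: set[tuple[int, int]] = set()
    for clique in retained:
        if clique & used:
            continue
        chosen.append(clique)
        used |= clique
    return chosen


def build_consensus(
    clique: frozenset[tuple[int, int]] | Sequence[tuple[int, int]],
    collection: RunCollection,
    quorum: int = DEFAULT_QUORUM,
    min_runs: int | None = None,
    consensus_id: str = "C1",
) -> ConsensusModule:
    """Aggregate a clique's member modules into a consensus family set.

    The consensus contains every family occurring in at least ``quorum`` of
    the member modules; families below quorum are reported separately.
    """
    members = frozenset(clique)
    if quorum > len(members):
        raise ValueError(f"quorum {quorum} exceeds clique size {len(members)}")
    if min_runs is None:
        min_runs = default_min_runs(len(collection))

    support: dict[str, int] = {}
    for run_idx, topic_idx in members:
        module = collection.runs[run_idx].modules[topic_idx]
        if module.topic_index != topic_idx:  # modules may be reordered
            module = next(
                m for m in collection.runs[run_idx].modules if m.topic_index == topic_idx
            )
        for fam in module.families:
            support[fam] = support.get(fam, 0) + 1

    families = frozenset(f for f, c in support.items() if c >= quorum)
    sub = frozenset(f for f, c in support.items() if 0 < c < quorum)
    return ConsensusModule(
        consensus_id=consensus_id,
        members=members,
        families=families,
        sub_quorum_families=sub,
        quorum=quorum,
        min_runs=min_runs,
        family_support=support,
    )


def consensus_modules_from_runs(
    collection: RunCollection,
    distance: str = "jaccard",
    d_max: float = DEFAULT_D_MAX,
    top_k: int = DEFAULT_TOP_K,
    quorum: int = DEFAULT_QUORUM,
    min_runs_fraction: float = DEFAULT_MIN_RUNS_FRACTION,
) -> list[ConsensusModule]:
    """Full consensus stage: graph -> stable cliques -> consensus modules.

    Returned modules are ordered by the mean rank of their member modules
    (best first) and labeled C1, C2, ...
    """
    min_runs = default_min_runs(len(collection), min_runs_fraction)
    graph = build_module_graph(collection, distance=distance, d_max=d_max, top_k=top_k)
    cliques = find_stable_cliques(graph, min_runs)

    rank_of: list[dict[int, int]] = [
        {r.module.topic_index: r.rank for r in run.ranking} for run in collection.runs
    ]

    def mean_rank(clique: frozenset[tuple[int, int]]) -> float:
        return float(np.mean([rank_of[r][t] for r, t in clique]))

    cliques = sorted(cliques, key=lambda c: (mean_rank(c), sorted(c)))
    return [
        build_consensus(c, collection, quorum=quorum, min_runs=min_runs, consensus_id=f"C{i}")
        for i, c in enumerate(cliques, 1)
    ]


def export_consensus_tsv(modules: Sequence[ConsensusModule], path) -> None:
    with open(path, "w") as fh:
        fh.write("consensus_id\tfamily_id\tn_member_modules\tin_consensus\n")
        for mod in modules:
            for fam in sorted(mod.family_support):
                flag = 1 if fam in mod.families else 0
                fh.write(f"{mod.consensus_id}\t{fam}\t{mod.family_support[fam]}\t{flag}\n")
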