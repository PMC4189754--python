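import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comodule.annotation_io import PhenotypeTable, corpus_from_counts
from comodule.consensus import (
    ModuleGraph,
    RunCollection,
    RunResult,
    build_consensus,
    build_module_graph,
    default_min_runs,
    find_stable_cliques,
    hungarian_mapping,
    jaccard_distance,
    sym_kl_distance,
)
from comodule.module_ranking import completeness_weights, rank_modules
from comodule.topic_model import FamilyModule, LdaConfig, TopicModel


class TestJaccard:
    def test_identical_sets(self):
        assert jaccard_distance({"a", "b"}, {"a", "b"}) == 0.0

    def test_disjoint_sets(self):
        assert jaccard_distance({"a"}, {"b"}) == 1.0

    def test_partial_overlap(self):
        # |{b,c}| / |{a,b,c,d}| = 2/4
        assert jaccard_distance({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(0.5)

    def test_both_empty(self):
        assert jaccard_distance(set(), set()) == 0.0

    @given(
        a=st.sets(st.integers(0, 10)),
        b=st.sets(st.integers(0, 10)),
        c=st.sets(st.integers(0, 10)),
    )
    @settings(max_examples=200, deadline=None)
    def test_metric_properties(self, a, b, c):
        a, b, c = ({str(x) for x in s} for s in (a, b, c))
        dab = jaccard_distance(a, b)
        assert 0.0 <= dab <= 1.0
        assert dab == jaccard_distance(b, a)
        assert jaccard_distance(a, a) == 0.0
        # Jaccard distance satisfies the triangle inequality
        assert dab <= jaccard_distance(a, c) + jaccard_distance(c, b) + 1e-12


class TestSymKl:
    def test_identical_distributions_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert sym_kl_distance(p, p) == pytest.approx(0.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(5))
        q = rng.dirichlet(np.ones(5))
        assert sym_kl_distance(p, q) == pytest.approx(sym_kl_distance(q, p))

    def test_hand_computed_value(self):
        p = np.array([0.9, 0.1])
        q = np.array([0.1, 0.9])
        assert sym_kl_distance(p, q) == pytest.approx(0.8 * math.log(9.0))

    def test_zero_entry_rejected(self):
        with pytest.raises(ValueError):
            sym_kl_distance(np.array([1.0, 0.0]), np.array([0.5, 0.5]))

    def test_ordering_agrees_with_jaccard_on_obvious_cases(self):
        ident = sym_kl_distance(np.array([0.5, 0.5, 1e-6]), np.array([0.5, 0.5, 1e-6]))
        overlap = sym_kl_distance(np.array([0.5, 0.5, 1e-6]), np.array([1e-6, 0.5, 0.5]))
        disjoint = sym_kl_distance(
            np.array([0.5, 0.5, 1e-6, 1e-6]), np.array([1e-6, 1e-6, 0.5, 0.5])
        )
        assert ident < overlap < disjoint


def brute_force_assignment(D):
    n = D.shape[0]
    best_cost, best_perm = math.inf, None
    for perm in itertools.permutations(range(n)):
        cost = sum(D[i, perm[i]] for i in range(n))
        if cost < best_cost:
            best_cost, best_perm = cost, perm
    return best_cost, best_perm


class TestHungarian:
    def test_simple_diagonal(self):
        D = np.array([[1.0, 2.0], [2.0, 1.0]])
        assert hungarian_mapping(D) == {0: 0, 1: 1}

    def test_recovers_permutation(self):
        rng = np.random.default_rng(4)
        perm = rng.permutation(5)
        D = np.ones((5, 5))
        D[np.arange(5), perm] = 0.0
        mapping = hungarian_mapping(D)
        assert mapping == {i: int(perm[i]) for i in range(5)}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_6x6(self, seed):
        rng = np.random.default_rng(seed)
        D = rng.uniform(0, 1, (6, 6))
        mapping = hungarian_mapping(D)
        cost = sum(D[i, j] for i, j in mapping.items())
        oracle_cost, _ = brute_force_assignment(D)
        assert cost == pytest.approx(oracle_cost)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            hungarian_mapping(np.ones((2, 3)))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            hungarian_mapping(np.array([[-1.0, 0.0], [0.0, 1.0]]))


def _run_from_modules(family_sets, corpus, labels):
    """Build a RunResult whose modules are the given family sets."""
    T = len(family_sets)
    V = len(corpus.vocabulary)
    fam_index = {f: i for i, f in enumerate(corpus.vocabulary)}
    phi = np.full((T, V), 1e-9)
    for t, fams in enumerate(family_sets):
        for f in fams:
            phi[t, fam_index[f]] = 1.0
    phi /= phi.sum(axis=1, keepdims=True)
    model = TopicModel(
        phi=phi,
        theta=np.full((corpus.n_documents, T), 1.0 / T),
        config=LdaConfig(n_topics=T, burn_in=0, n_samples=1, sample_lag=1),
        vocabulary=list(corpus.vocabulary),
        sample_ids=corpus.sample_ids,
        corpus_ref="shared",
    )
    modules = [
        FamilyModule(topic_index=t, families=frozenset(fams), cutoff=0.01)
        for t, fams in enumerate(family_sets)
    ]
    weights = completeness_weights(modules, corpus)
    ranking = rank_modules(modules, weights, labels, 0.5)
    return RunResult(model=model, modules=modules, ranking=ranking)


@pytest.fixture
def three_run_collection():
    corpus = corpus_from_counts(
        [
            ("p1", {"A": 1, "B": 1}),
            ("p2", {"A": 1, "B": 1}),
            ("n1", {"X": 1}),
            ("n2", {"Y": 1, "Z": 1}),
        ]
    )
    labels = PhenotypeTable(
        labels={"p1": "positive", "p2": "positive", "n1": "negative", "n2": "negative"}
    )
    shared = {"A", "B"}
    runs = [
        _run_from_modules([shared, {"X"}], corpus, labels),
        _run_from_modules([{"Y", "Z"}, shared], corpus, labels),
        _run_from_modules([shared, {"X", "Y"}], corpus, labels),
    ]
    return RunCollection(runs=runs)


class TestModuleGraph:
    def test_identical_runs_fully_matched(self, three_run_collection):
        coll = RunCollection(runs=[three_run_collection.runs[0]] * 2)
        g = build_module_graph(coll, d_max=1.0, top_k=2)
        assert g.graph.number_of_edges() == 2  # one per matched topic pair

    def test_d_max_zero_like_threshold(self, three_run_collection):
        g = build_module_graph(three_run_collection, d_max=1e-9, top_k=2)
        # only the identical shared module pairs survive
        for u, v, data in g.graph.edges(data=True):
            assert data["distance"] == pytest.approx(0.0)

    def test_shared_module_forms_triangle(self, three_run_collection):
        g = build_module_graph(three_run_collection, d_max=0.7, top_k=2)
        shared_nodes = [(0, 0), (1, 1), (2, 0)]
        for u, v in itertools.combinations(shared_nodes, 2):
            assert g.graph.has_edge(u, v)

    def test_no_intra_run_edges(self, three_run_collection):
        g = build_module_graph(three_run_collection, d_max=1.0, top_k=2)
        for (ra, _), (rb, _) in g.graph.edges():
            assert ra != rb

    def test_fewer_than_two_runs_rejected(self, three_run_collection):
        with pytest.raises(ValueError):
            build_module_graph(RunCollection(runs=three_run_collection.runs[:1]))

    def test_sym_kl_distance_mode(self, three_run_collection):
        g = build_module_graph(three_run_collection, distance="sym_kl", d_max=50.0, top_k=2)
        shared_nodes = [(0, 0), (1, 1), (2, 0)]
        for u, v in itertools.combinations(shared_nodes, 2):
            assert g.graph.has_edge(u, v)


def brute_force_maximal_cliques(G):
    nodes = list(G.nodes)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if all(G.has_edge(u, v) for u, v in itertools.combinations(subset, 2)):
                cliques.append(frozenset(subset))
    return {c for c in cliques if not any(c < other for other in cliques)}


class TestStableCliques:
    def graph_of(self, edges, nodes=()):
        G = nx.Graph()
        G.add_nodes_from(nodes)
        for u, v in edges:
            G.add_edge(u, v, distance=0.5)
        return ModuleGraph(graph=G, distance="jaccard", d_max=0.7, top_k=15)

    def test_triangle_clique(self):
        g = self.graph_of([((0, 0), (1, 0)), ((1, 0), (2, 0)), ((0, 0), (2, 0))])
        cliques = find_stable_cliques(g, min_runs=3)
        assert cliques == [frozenset({(0, 0), (1, 0), (2, 0)})]

    def test_max_clique_too_small(self):
        g = self.graph_of([((0, 0), (1, 0)), ((1, 1), (2, 0))])
        assert find_stable_cliques(g, min_runs=3) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_maximal_cliques_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_nodes = 12
        nodes = [(i % 4, i // 4) for i in range(n_nodes)]  # 4 runs x 3 topics
        G = nx.Graph()
        G.add_nodes_from(nodes)
        for u, v in itertools.combinations(nodes, 2):
            if u[0] != v[0] and rng.random() < 0.4:
                G.add_edge(u, v, distance=rng.random())
        assert {frozenset(c) for c in nx.find_cliques(G)} == brute_force_maximal_cliques(G)

    def test_overlap_resolution_keeps_larger(self):
        # K4 over runs 0..3 shares node (0,0) with a K3; the K4 wins
        k4 = [(0, 0), (1, 0), (2, 0), (3, 0)]
        k3_extra = [(1, 5), (2, 5)]
        edges = list(itertools.combinations(k4, 2))
        edges += [((0, 0), k3_extra[0]), ((0, 0), k3_extra[1]), (k3_extra[0], k3_extra[1])]
        g = self.graph_of(edges)
        cliques = find_stable_cliques(g, min_runs=3)
        assert frozenset(k4) in cliques
        assert frozenset([(0, 0), *k3_extra]) not in cliques


class TestBuildConsensus:
    def test_quorum_counting(self, three_run_collection):
        clique = frozenset({(0, 0), (1, 1), (2, 0)})
        mod = build_consensus(clique, three_run_collection, quorum=2)
        assert mod.families == {"A", "B"}
        assert mod.sub_quorum_families == frozenset()

    def test_sub_quorum_reported(self, three_run_collection):
        clique = frozenset({(0, 1), (2, 1)})  # {X} and {X, Y}
        mod = build_consensus(clique, three_run_collection, quorum=2)
        assert mod.families == {"X"}
        assert mod.sub_quorum_families == {"Y"}

    def test_quorum_one_is_union(self, three_run_collection):
        clique = frozenset({(0, 1), (2, 1)})
        mod = build_consensus(clique, three_run_collection, quorum=1)
        assert mod.families == {"X", "Y"}

    def test_identical_modules_consensus_equals_module(self, three_run_collection):
        clique = frozenset({(0, 0), (1, 1), (2, 0)})
        mod = build_consensus(clique, three_run_collection, quorum=3)
        assert mod.families == {"A", "B"}

    def test_quorum_exceeding_clique_rejected(self, three_run_collection):
        with pytest.raises(ValueError):
            build_consensus(frozenset({(0, 0), (1, 1)}), three_run_collection, quorum=3)

    def test_monotone_in_quorum(self, three_run_collection):
        clique = frozenset({(0, 0), (1, 1), (2, 0), (2, 1)})
        prev = None
        for q in range(1, 5):
            fams = build_consensus(clique, three_run_collection, quorum=q).families
            if prev is not None:
                assert fams <= prev
            prev = fams


class TestMinRuns:
    def test_paper_shape(self):
        assert default_min_runs(18) == 14

    @pytest.mark.parametrize("r,expected", [(4, 3), (8, 6), (12, 9), (20, 15)])
    def test_ceil_rule(self, r, expected):
        assert default_min_runs(r) == expected
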