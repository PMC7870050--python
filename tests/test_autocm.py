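"""Auto-CM training, similarity sources, MST and the regular-graph overlay."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from fracturetwist.autocm import (SimilarityMatrix, autocm_similarity,
                                  build_map, map_report,
                                  maximally_regular_graph,
                                  minimum_spanning_tree, pp_similarity,
                                  similarity_to_distance, train_autocm)
from fracturetwist.cohort import generate_cohort
from fracturetwist.model import SemanticMap
from conftest import make_planted_spec, random_distance_matrix


def brute_force_mst_weight(d: np.ndarray) -> float:
    """Minimum total weight over all labelled spanning trees (enumeration)."""
    n = d.shape[0]
    nodes = range(n)
    best = np.inf
    for edges in itertools.combinations(itertools.combinations(nodes, 2), n - 1):
        g = nx.Graph(edges)
        if g.number_of_nodes() == n and nx.is_connected(g):
            w = sum(d[u, v] for u, v in edges)
            best = min(best, w)
    return best


@pytest.fixture(scope="module")
def random_matrix():
    rng = np.random.default_rng(0)
    frame = pd.DataFrame(rng.random((60, 8)),
                         columns=[f"c{i}" for i in range(8)])
    frame["dup"] = frame["c0"]
    frame["comp"] = 1.0 - frame["c1"]
    return frame


class TestTrainAutoCM:
    def test_duplicated_columns_rank_top(self, random_matrix):
        w = train_autocm(random_matrix, epochs=50)
        S = autocm_similarity(w).values
        names = list(random_matrix.columns)
        s_dup = S[names.index("c0"), names.index("dup")]
        off = S[~np.eye(len(S), dtype=bool)]
        assert (off < s_dup).mean() >= 0.95  # top 5% of off-diagonal entries

    def test_complement_pair_below_median(self, random_matrix):
        w = train_autocm(random_matrix, epochs=50)
        S = autocm_similarity(w).values
        names = list(random_matrix.columns)
        s_comp = S[names.index("c1"), names.index("comp")]
        off = S[~np.eye(len(S), dtype=bool)]
        assert s_comp < np.median(off)

    def test_weights_bounded_by_contraction_parameter(self, random_matrix):
        w = train_autocm(random_matrix, C=5.0, epochs=30)
        assert w.W.min() >= 0.0 and w.W.max() <= 5.0 + 1e-9
        assert w.v.min() >= 0.0 and w.v.max() <= 5.0 + 1e-9

    def test_deterministic(self, random_matrix):
        a = train_autocm(random_matrix, epochs=20)
        b = train_autocm(random_matrix, epochs=20)
        np.testing.assert_array_equal(a.W, b.W)

    def test_invalid_contraction_rejected(self, random_matrix):
        with pytest.raises(ValueError, match="C"):
            train_autocm(random_matrix, C=-1.0)

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError, match="0, 1"):
            train_autocm(pd.DataFrame({"a": [0.5, 2.0], "b": [0.1, 0.2]}))


class TestPPSimilarity:
    def test_identical_binary_columns_score_one(self):
        frame = pd.DataFrame({"a": [1.0, 0, 1, 0], "b": [1.0, 0, 1, 0]})
        S = pp_similarity(frame)
        assert S.values[0, 1] == 1.0

    def test_complementary_binary_columns_score_zero(self):
        frame = pd.DataFrame({"a": [1.0, 0, 1, 0], "b": [0.0, 1, 0, 1]})
        assert pp_similarity(frame).values[0, 1] == 0.0

    def test_half_concordant_pair(self):
        frame = pd.DataFrame({"u": [1.0, 1, 0, 0], "x": [1.0, 0, 1, 0]})
        assert pp_similarity(frame).values[0, 1] == 0.5  # c = d = 2

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pp_similarity(pd.DataFrame())


class TestDistanceAndMST:
    def test_most_similar_pair_attains_distance_zero(self):
        rng = np.random.default_rng(1)
        s = rng.random((5, 5))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 1.0)
        S = SimilarityMatrix(node_names=list("abcde"), values=s, source="autocm")
        d = similarity_to_distance(S)
        off = ~np.eye(5, dtype=bool)
        assert d[off].min() == 0.0

    def test_distance_reverses_similarity_order(self):
        s = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.5], [0.2, 0.5, 1.0]])
        S = SimilarityMatrix(node_names=list("abc"), values=s, source="autocm")
        d = similarity_to_distance(S)
        assert d[0, 1] < d[1, 2] < d[0, 2]

    def test_known_four_node_instance(self):
        # optimum verified by enumerating all 16 labelled spanning trees of K4
        d = np.zeros((4, 4))
        pairs = {(0, 1): 1, (0, 2): 4, (0, 3): 3, (1, 2): 2, (1, 3): 5, (2, 3): 6}
        for (i, j), w in pairs.items():
            d[i, j] = d[j, i] = w
        tree = minimum_spanning_tree(d, ["1", "2", "3", "4"])
        assert sorted(tree) == [("1", "2"), ("1", "4"), ("2", "3")]
        assert brute_force_mst_weight(d) == 6

    def test_tree_shape_invariants(self):
        rng = np.random.default_rng(2)
        d = random_distance_matrix(rng, 9)
        names = [f"n{i}" for i in range(9)]
        tree = minimum_spanning_tree(d, names)
        g = nx.Graph(tree)
        assert len(tree) == 8
        assert nx.is_connected(g) and nx.is_tree(g)

    def test_matches_enumeration_oracle_on_random_instances(self):
        # exact equivalence with brute-force spanning-tree enumeration
        rng = np.random.default_rng(3)
        for _ in range(100):
            d = random_distance_matrix(rng, 5)
            names = [f"n{i}" for i in range(5)]
            tree = minimum_spanning_tree(d, names)
            idx = {nm: i for i, nm in enumerate(names)}
            w = sum(d[idx[u], idx[v]] for u, v in tree)
            assert w == pytest.approx(brute_force_mst_weight(d), abs=1e-12)

    def test_mst_on_distance_equals_max_spanning_tree_on_similarity(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            s = rng.random((5, 5))
            s = (s + s.T) / 2
            np.fill_diagonal(s, 1.0)
            names = list("abcde")
            S = SimilarityMatrix(node_names=names, values=s, source="autocm")
            tree = minimum_spanning_tree(similarity_to_distance(S), names)
            g = nx.Graph()
            idx = {nm: i for i, nm in enumerate(names)}
            for i, u in enumerate(names):
                for v in names[i + 1:]:
                    g.add_edge(u, v, weight=s[idx[u], idx[v]])
            max_tree = nx.maximum_spanning_edges(g, data=False)
            assert {tuple(sorted(e)) for e in tree} == {tuple(sorted(e))
                                                        for e in max_tree}

    def test_non_finite_distance_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            minimum_spanning_tree(d, list("abc"))


class TestMaximallyRegularGraph:
    def _clique_similarity(self):
        names = list("ABCDEF")
        S = np.zeros((6, 6))
        weak = iter(np.linspace(0.05, 0.35, 15))
        clique = {("A", "B"): 0.95, ("A", "C"): 0.96, ("A", "D"): 0.97,
                  ("B", "C"): 0.98, ("B", "D"): 0.94, ("C", "D"): 0.93}
        for i, u in enumerate(names):
            for j in range(i + 1, 6):
                s = clique.get((u, names[j]), next(weak))
                S[i, j] = S[j, i] = s
        np.fill_diagonal(S, 1.0)
        return SimilarityMatrix(node_names=names, values=S, source="autocm")

    def test_zero_extra_budget_returns_tree(self):
        S = self._clique_similarity()
        tree = minimum_spanning_tree(similarity_to_distance(S), S.node_names)
        g = maximally_regular_graph(tree, S, max_extra=0)
        assert g.extra_edges == []
        assert sorted(g.graph.edges()) == sorted(tree)

    def test_planted_clique_loop_is_closed(self):
        # exhaustive H over all k (the regularity trace) must pick an
        # augmentation that closes a cycle inside the planted 4-clique
        S = self._clique_similarity()
        tree = minimum_spanning_tree(similarity_to_distance(S), S.node_names)
        g = maximally_regular_graph(tree, S, max_extra=5)
        assert len(g.extra_edges) >= 1
        clique_nodes = set("ABCD")
        assert all(set(e) <= clique_nodes for e in g.extra_edges)
        cycles = nx.cycle_basis(g.graph)
        assert any(set(c) <= clique_nodes for c in cycles)
        # the greedy trace is exhaustive over k and the winner maximises H
        ks, hs = zip(*g.regularity_trace)
        assert max(hs) == hs[len(g.extra_edges)]

    def test_extra_edges_disjoint_from_tree_and_sorted(self):
        S = self._clique_similarity()
        tree = minimum_spanning_tree(similarity_to_distance(S), S.node_names)
        g = maximally_regular_graph(tree, S, max_extra=5)
        idx = {nm: i for i, nm in enumerate(S.node_names)}
        assert not (set(g.extra_edges) & set(map(tuple, tree)))
        sims = [S.values[idx[u], idx[v]] for u, v in g.extra_edges]
        assert sims == sorted(sims, reverse=True)


@pytest.fixture(scope="module")
def fitted_map():
    table = generate_cohort(make_planted_spec(), n_total=120, seed=6)
    return SemanticMap(table, epochs=30, max_extra=4).fit()


class TestMapReport:
    def test_outcome_nodes_have_neighbours(self, fitted_map):
        rep = fitted_map.outcome_report()
        assert len(rep["further fracture"]) >= 1
        assert len(rep["no further fracture"]) >= 1

    def test_labels_carry_high_low_suffixes(self, fitted_map):
        roles = nx.get_node_attributes(fitted_map.graph.graph, "role")
        highs = [n for n, r in roles.items() if r == "variable-high"]
        lows = [n for n, r in roles.items() if r == "variable-low"]
        assert len(highs) == 13 and len(lows) == 13
        assert all(n.endswith(" high") for n in highs)

    def test_report_deterministic_after_serialisation(self, fitted_map, tmp_path):
        import json

        from fracturetwist.autocm import ConnectivityGraph

        p = tmp_path / "graph.json"
        fitted_map.graph.to_json(p)
        payload = json.loads(p.read_text())
        g = nx.Graph()
        for node in payload["nodes"]:
            g.add_node(node["name"], role=node["role"])
        for e in payload["edges"]:
            g.add_edge(e["u"], e["v"], weight=e["weight"], kind=e["kind"])
        rebuilt = ConnectivityGraph(
            graph=g,
            tree_edges=[tuple(sorted((e["u"], e["v"]))) for e in payload["edges"]
                        if e["kind"] == "tree"],
            extra_edges=[tuple(sorted((e["u"], e["v"]))) for e in payload["edges"]
                         if e["kind"] == "extra"],
        )
        assert map_report(rebuilt) == fitted_map.outcome_report()

    def test_missing_outcome_nodes_rejected(self):
        from fracturetwist.autocm import ConnectivityGraph

        g = nx.Graph([("a", "b")])
        with pytest.raises(ValueError, match="outcome"):
            map_report(ConnectivityGraph(graph=g, tree_edges=[("a", "b")],
                                         extra_edges=[]))

    def test_shifted_variable_high_node_near_fracture_node(self):
        # a ≥1.5-SD shifted variable's "high" node should sit within graph
        # distance 2 of the further-fracture node in most seeded runs
        hits = 0
        runs = 6
        for seed in range(runs):
            table = generate_cohort(make_planted_spec(shift_idx=(2,)), 150,
                                    seed=seed)
            res = SemanticMap(table, epochs=30, max_extra=4).fit()
            dist = nx.shortest_path_length(res.graph.graph, "further fracture")
            if dist.get("V2 high", 99) <= 2:
                hits += 1
        assert hits >= int(0.8 * runs)
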