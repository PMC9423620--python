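"""Centrality measures against closed forms and brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from carank import MEASURES, compute_centrality, mnc_score
from carank.centrality import spectral_radius


def _str_graph(g):
    return nx.relabel_nodes(g, {v: str(v) for v in g.nodes})


# ---------------------------------------------------------------- oracles


def brute_betweenness(g):
    """Pair-by-pair shortest-path counting on tiny graphs."""
    nodes = list(g.nodes)
    score = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        paths = []
        try:
            length = nx.shortest_path_length(g, s, t)
        except nx.NetworkXNoPath:
            continue
        for path in nx.all_simple_paths(g, s, t, cutoff=length):
            if len(path) - 1 == length:
                paths.append(path)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            score[v] += through / len(paths)
    return score


def brute_closeness(g):
    """Component-scaled closeness from explicit BFS distances."""
    n = len(g)
    out = {}
    for v in g.nodes:
        dists = nx.single_source_shortest_path_length(g, v)
        reach = len(dists) - 1
        if reach == 0:
            out[v] = 0.0
            continue
        total = sum(dists.values())
        out[v] = (reach / total) * (reach / (n - 1))
    return out


def katz_series(g, alpha, tol=1e-10):
    nodes = list(g.nodes)
    A = nx.to_numpy_array(g, nodelist=nodes)
    term = np.ones(len(nodes))
    acc = np.zeros(len(nodes))
    for _ in range(10000):
        term = alpha * (A @ term)
        acc += term
        if np.abs(term).max() < tol:
            break
    return dict(zip(nodes, acc))


def pagerank_power_iteration(g, damping, tol=1e-12):
    nodes = list(g.nodes)
    n = len(nodes)
    A = nx.to_numpy_array(g, nodelist=nodes)
    deg = A.sum(axis=1)
    P = A / deg[:, None]
    x = np.full(n, 1.0 / n)
    for _ in range(100000):
        x_new = (1 - damping) / n + damping * (P.T @ x)
        if np.abs(x_new - x).max() < tol:
            return dict(zip(nodes, x_new))
        x = x_new
    raise RuntimeError("power iteration did not converge")


# ---------------------------------------------------------------- tests


class TestClosedForms:
    def test_star_degree(self):
        g = _str_graph(nx.star_graph(4))
        scores = compute_centrality(g, "degree")
        assert scores["0"] == 4
        assert all(scores[str(i)] == 1 for i in range(1, 5))

    def test_path_betweenness_symmetry(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        scores = compute_centrality(g, "betweenness")
        assert scores["b"] > scores["a"] == scores["c"]

    @pytest.mark.parametrize("measure", MEASURES)
    def test_complete_graph_uniform(self, measure):
        g = _str_graph(nx.complete_graph(5))
        scores = compute_centrality(g, measure)
        vals = list(scores.scores.values())
        assert np.allclose(vals, vals[0])

    def test_two_triangle_bridge_pagerank(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")])
        scores = compute_centrality(g, "pagerank", pagerank_damping=0.85)
        oracle = pagerank_power_iteration(g, 0.85)
        assert np.isclose(sum(scores.scores.values()), 1.0, atol=1e-6)
        for v in g.nodes:
            assert scores[v] == pytest.approx(oracle[v], abs=1e-4)
        top_two = sorted(g.nodes, key=lambda v: -scores[v])[:2]
        assert set(top_two) == {"c", "d"}


class TestMNC:
    def test_isolated_node(self):
        g = nx.Graph()
        g.add_node("x")
        assert mnc_score(g, "x") == 0

    @pytest.mark.parametrize("k", [1, 3, 6])
    def test_star_center(self, k):
        g = _str_graph(nx.star_graph(k))
        assert mnc_score(g, "0") == 1

    def test_triangle(self):
        g = _str_graph(nx.complete_graph(3))
        assert all(mnc_score(g, v) == 2 for v in g.nodes)

    def test_bounded_by_degree(self):
        g = _str_graph(nx.gnp_random_graph(30, 0.2, seed=4))
        for v in g.nodes:
            assert 0 <= mnc_score(g, v) <= g.degree(v)

    def test_split_neighborhood(self):
        # center sees two components among its neighbors: an edge and a point
        g = nx.Graph([("c", "a"), ("c", "b"), ("a", "b"), ("c", "z")])
        assert mnc_score(g, "c") == 2


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(6))
    def test_betweenness_and_closeness_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        g = _str_graph(nx.gnp_random_graph(n, 0.45, seed=seed))
        if g.number_of_edges() == 0:
            g.add_edge("0", "1")
        bet = compute_centrality(g, "betweenness")
        clo = compute_centrality(g, "closeness")
        bet_oracle = brute_betweenness(g)
        clo_oracle = brute_closeness(g)
        for v in g.nodes:
            assert bet[v] == pytest.approx(bet_oracle[v], abs=1e-9)
            assert clo[v] == pytest.approx(clo_oracle[v], abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_katz_matches_series(self, seed):
        g = _str_graph(nx.gnp_random_graph(8, 0.4, seed=seed))
        if g.number_of_edges() == 0:
            g.add_edge("0", "1")
        alpha = 0.5 / spectral_radius(g)
        scores = compute_centrality(g, "katz", katz_alpha=alpha)
        oracle = katz_series(g, alpha)
        for v in g.nodes:
            assert scores[v] == pytest.approx(oracle[v], abs=1e-8)


class TestInvariantsAndErrors:
    def test_automorphism_preserves_score_multiset(self):
        g = _str_graph(nx.cycle_graph(6))
        relabeled = nx.relabel_nodes(g, {v: str((int(v) + 2) % 6) for v in g.nodes})
        for measure in MEASURES:
            a = sorted(compute_centrality(g, measure).scores.values())
            b = sorted(compute_centrality(relabeled, measure).scores.values())
            assert np.allclose(a, b)

    def test_unknown_measure_lists_valid_ids(self, toy):
        graph, _ = toy
        with pytest.raises(ValueError, match="degree"):
            compute_centrality(graph, "eigenvector")

    def test_divergent_katz_alpha_rejected(self, toy):
        graph, _ = toy
        bad = 1.1 / spectral_radius(graph)
        with pytest.raises(ValueError, match="diverge"):
            compute_centrality(graph, "katz", katz_alpha=bad)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            compute_centrality(nx.Graph(), "degree")

    def test_scores_cover_all_nodes_and_are_finite(self, toy):
        graph, _ = toy
        for measure in MEASURES:
            scores = compute_centrality(graph, measure)
            assert set(scores.scores) == set(graph.nodes)
            assert np.isfinite(list(scores.scores.values())).all()
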