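"""SIR simulator against closed forms and exact enumeration."""

import networkx as nx
import numpy as np
import pytest

from carank import (
    SIRParams,
    compute_centrality,
    delta_r,
    epidemic_threshold,
    simulate_sir,
)


def _path3():
    return nx.Graph([("a", "b"), ("b", "c")])


class TestEpidemicThreshold:
    def test_regular_graph_closed_form(self):
        g = nx.relabel_nodes(nx.cycle_graph(10), str)  # 2-regular
        assert epidemic_threshold(g) == pytest.approx(1.0)
        g4 = nx.relabel_nodes(nx.circulant_graph(12, [1, 2]), str)  # 4-regular
        assert epidemic_threshold(g4) == pytest.approx(1 / 3)

    def test_star_moments(self):
        n = 8
        g = nx.relabel_nodes(nx.star_graph(n - 1), str)
        # degrees: one n-1 hub, n-1 leaves of degree 1
        assert epidemic_threshold(g) == pytest.approx(2 / (n - 2))

    def test_triangle(self):
        assert epidemic_threshold(nx.relabel_nodes(nx.complete_graph(3), str)) == pytest.approx(1.0)

    def test_matching_graph_undefined(self):
        g = nx.Graph([("a", "b"), ("c", "d")])  # 1-regular: <k^2> == <k>
        with pytest.raises(ValueError):
            epidemic_threshold(g)


class TestSimulateClosedForms:
    def test_zero_transmission_recovers_only_seeds(self, two_cliques_bridge):
        g, _ = two_cliques_bridge
        res = simulate_sir(g, ["0", "5"], SIRParams(infection_prob=0.0, runs=40, rng_seed=1))
        assert (res.per_run_recovered == 2).all()

    def test_certain_transmission_sweeps_connected_graph(self, toy):
        g, _ = toy
        res = simulate_sir(g, ["5"], SIRParams(infection_prob=1.0, recovery_prob=1.0, runs=20, rng_seed=2))
        assert (res.per_run_recovered == g.number_of_nodes()).all()
        # deterministic BFS wave: duration bounded by eccentricity + 1
        assert res.steps.max() <= nx.eccentricity(g, "5") + 1

    def test_seeding_everything_recovers_everything(self, toy):
        g, _ = toy
        res = simulate_sir(g, list(g.nodes), SIRParams(infection_prob=0.3, runs=10, rng_seed=3))
        assert (res.per_run_recovered == g.number_of_nodes()).all()

    def test_recovered_counts_bounded(self, toy):
        g, _ = toy
        res = simulate_sir(g, ["5", "13"], SIRParams(infection_prob=0.2, runs=200, rng_seed=4))
        assert (res.per_run_recovered >= 2).all()
        assert (res.per_run_recovered <= g.number_of_nodes()).all()

    def test_empty_seed_set_rejected(self, toy):
        g, _ = toy
        with pytest.raises(ValueError):
            simulate_sir(g, [], SIRParams(infection_prob=0.5))

    def test_unknown_seed_rejected(self, toy):
        g, _ = toy
        with pytest.raises(ValueError, match="ghost"):
            simulate_sir(g, ["ghost"], SIRParams(infection_prob=0.5))


class TestDistributionExactness:
    def test_three_node_path_enumeration(self):
        # seed = center, lambda = 1/2, recovery 1: center infects each leaf
        # independently, then recovers; outcome 1 + Binomial(2, 1/2).
        runs = 100_000
        res = simulate_sir(_path3(), ["b"], SIRParams(infection_prob=0.5, recovery_prob=1.0,
                                                      runs=runs, rng_seed=11))
        exact = {1: 0.25, 2: 0.5, 3: 0.25}
        for size, p in exact.items():
            freq = float(np.mean(res.per_run_recovered == size))
            se = np.sqrt(p * (1 - p) / runs)
            assert abs(freq - p) < 3 * se, f"size {size}: {freq} vs {p}"

    def test_reproducibility_bitwise(self, toy):
        g, _ = toy
        p = SIRParams(infection_prob=0.3, recovery_prob=0.7, runs=50, rng_seed=21)
        a = simulate_sir(g, ["5"], p)
        b = simulate_sir(g, ["5"], p)
        assert (a.per_run_recovered == b.per_run_recovered).all()
        assert (a.steps == b.steps).all()

    def test_run_prefix_stable_under_run_count(self, toy):
        # run i depends only on (seed, i), not on how many runs were asked for
        g, _ = toy
        a = simulate_sir(g, ["5"], SIRParams(infection_prob=0.3, runs=10, rng_seed=7))
        b = simulate_sir(g, ["5"], SIRParams(infection_prob=0.3, runs=25, rng_seed=7))
        assert (a.per_run_recovered == b.per_run_recovered[:10]).all()

    def test_outbreak_size_monotone_in_lambda(self):
        g = nx.relabel_nodes(nx.gnp_random_graph(50, 0.12, seed=3), str)
        runs = 10_000
        means, dists = [], []
        for lam in (0.05, 0.15, 0.35, 0.7):
            res = simulate_sir(g, ["0"], SIRParams(infection_prob=lam, runs=runs, rng_seed=31))
            means.append(res.final_recovered)
            dists.append(res.per_run_recovered)
        assert means == sorted(means)
        # first-order stochastic dominance between successive lambdas
        grid = np.arange(1, 51)
        for lo, hi in zip(dists, dists[1:]):
            cdf_lo = np.searchsorted(np.sort(lo), grid, side="right") / runs
            cdf_hi = np.searchsorted(np.sort(hi), grid, side="right") / runs
            assert (cdf_hi <= cdf_lo + 0.02).all()


class TestDeltaR:
    def test_identical_seed_sets_give_zero(self, toy):
        g, _ = toy
        from carank import Partition

        single = Partition(dict.fromkeys(g.nodes, "all"))
        deg = compute_centrality(g, "degree")
        res = delta_r(g, deg, single, 0.2, SIRParams(infection_prob=0.4, runs=100), rng_seed=5)
        assert res.percent == 0.0

    def test_saturated_epidemic_gives_zero(self, toy):
        g, part = toy
        deg = compute_centrality(g, "degree")
        res = delta_r(g, deg, part, 0.15, SIRParams(infection_prob=1.0, recovery_prob=1.0, runs=50),
                      rng_seed=6)
        assert res.percent == pytest.approx(0.0)

    def test_full_fraction_gives_zero(self, toy):
        g, part = toy
        deg = compute_centrality(g, "degree")
        res = delta_r(g, deg, part, 1.0, SIRParams(infection_prob=0.3, runs=30), rng_seed=7)
        assert res.percent == pytest.approx(0.0)

    def test_unbalanced_cliques_bridge_positive(self):
        # a 5-clique and a triangle joined by one edge: both top-degree nodes
        # sit in the 5-clique, so descending order never seeds the triangle
        # while the community-aware scheme always does — its outbreaks win
        g = nx.Graph()
        for i in range(5):
            for j in range(i + 1, 5):
                g.add_edge(f"a{i}", f"a{j}")
        g.add_edges_from([("b0", "b1"), ("b1", "b2"), ("b0", "b2"), ("a0", "b0")])
        from carank import Partition

        part = Partition({f"a{i}": "A" for i in range(5)} | {f"b{i}": "B" for i in range(3)})
        deg = compute_centrality(g, "degree")
        res = delta_r(g, deg, part, 0.25, SIRParams(infection_prob=0.5, recovery_prob=1.0, runs=10_000),
                      rng_seed=8)
        assert res.percent > 0

    def test_fraction_bounds(self, toy):
        g, part = toy
        deg = compute_centrality(g, "degree")
        with pytest.raises(ValueError):
            delta_r(g, deg, part, 0.0, SIRParams(infection_prob=0.3), rng_seed=0)
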