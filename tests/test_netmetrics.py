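"""Graph metrics against hand enumerations and independent oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thetanet.connectivity import ConnectivityMatrix
from thetanet.netmetrics import (
    BinaryGraph,
    binarize,
    char_path_length,
    clustering_coefficient,
    compute_metrics,
    global_efficiency,
    local_efficiency,
    median_threshold,
    shortest_path_lengths,
    small_worldness,
    surrogate_ensemble,
)


def graph_from_edges(n, edges):
    a = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        a[i, j] = a[j, i] = True
    return BinaryGraph(adjacency=a)


def complete_graph(n):
    return BinaryGraph(adjacency=~np.eye(n, dtype=bool))


def random_graph(n, p, seed):
    g = nx.gnp_random_graph(n, p, seed=seed)
    return BinaryGraph(adjacency=nx.to_numpy_array(g, dtype=bool)), g


# -- independent brute-force oracles -----------------------------------------

def floyd_warshall_oracle(adj):
    n = adj.shape[0]
    d = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                d[i, j] = min(d[i, j], d[i, k] + d[k, j])
    return d


def clustering_oracle(adj):
    n = adj.shape[0]
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        tri = sum(adj[u, v] for u, v in itertools.combinations(nbrs, 2))
        vals.append(2.0 * tri / (k * (k - 1)))
    return float(np.mean(vals))


def local_efficiency_oracle(adj):
    n = adj.shape[0]
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            vals.append(0.0)
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        d = floyd_warshall_oracle(sub)
        m = len(nbrs)
        acc = sum(
            1.0 / d[u, v]
            for u in range(m) for v in range(m)
            if u != v and np.isfinite(d[u, v])
        )
        vals.append(acc / (m * (m - 1)))
    return float(np.mean(vals))


# -- hand-enumerable fixtures -------------------------------------------------

class TestHandFixtures:
    def test_complete_graph(self):
        g = complete_graph(5)
        assert char_path_length(g)[0] == 1.0
        assert global_efficiency(g) == 1.0
        per_node, mean = local_efficiency(g)
        assert np.allclose(per_node, 1.0) and mean == 1.0
        assert clustering_coefficient(g) == 1.0

    def test_three_node_path(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        d = shortest_path_lengths(g)
        assert d[0, 2] == 2
        assert char_path_length(g)[0] == pytest.approx(4 / 3)
        assert global_efficiency(g) == pytest.approx((1 + 1 + 0.5) / 3)

    def test_four_node_star(self):
        g = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        assert char_path_length(g)[0] == pytest.approx(1.5)
        per_node, mean = local_efficiency(g)
        assert np.allclose(per_node, 0.0) and mean == 0.0
        assert clustering_coefficient(g) == 0.0

    def test_triangle(self):
        g = complete_graph(3)
        per_node, _ = local_efficiency(g)
        assert np.allclose(per_node, 1.0)
        assert clustering_coefficient(g) == 1.0

    def test_disconnected_pair_conventions(self):
        g = graph_from_edges(2, [])
        assert global_efficiency(g) == 0.0
        with pytest.raises(ValueError, match="no connected pairs"):
            char_path_length(g)

    def test_unreachable_pairs_counted_and_excluded(self):
        # triangle plus isolated node: 6 ordered pairs unreachable
        g = graph_from_edges(4, [(0, 1), (1, 2), (0, 2)])
        l_val, n_unreach = char_path_length(g)
        assert l_val == 1.0
        assert n_unreach == 6


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        p = float(rng.uniform(0.2, 0.8))
        g, _ = random_graph(n, p, seed)
        d_oracle = floyd_warshall_oracle(g.adjacency)
        assert np.array_equal(shortest_path_lengths(g), d_oracle)
        assert clustering_coefficient(g) == pytest.approx(
            clustering_oracle(g.adjacency), abs=1e-12)
        assert local_efficiency(g)[1] == pytest.approx(
            local_efficiency_oracle(g.adjacency), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_networkx_on_random_graphs(self, seed):
        g, G = random_graph(10, 0.4, 100 + seed)
        assert global_efficiency(g) == pytest.approx(
            nx.global_efficiency(G), abs=1e-12)
        assert clustering_coefficient(g) == pytest.approx(
            nx.average_clustering(G), abs=1e-12)
        assert local_efficiency(g)[1] == pytest.approx(
            nx.local_efficiency(G), abs=1e-12)


class TestMedianThreshold:
    def _mat(self, values, condition=("S01", "T1", "L0")):
        return ConnectivityMatrix(values=np.asarray(values, float),
                                  channel_labels=[f"c{i}" for i in
                                                  range(len(values))],
                                  band=(4, 8), n_samples_used=100,
                                  condition=condition)

    def test_direct_median_and_strict_edges(self):
        m = self._mat([[0, 0.2, 0.4], [0.2, 0, 0.6], [0.4, 0.6, 0]])
        thr = median_threshold([m])[("S01", "T1")]
        assert thr == pytest.approx(0.4)
        g = binarize(m, thr)
        assert g.n_edges == 1  # only the 0.6 entry survives strictly

    def test_all_equal_entries_give_zero_edges(self):
        v = np.full((4, 4), 0.3)
        np.fill_diagonal(v, 0.0)
        m = self._mat(v)
        thr = median_threshold([m])[("S01", "T1")]
        g = binarize(m, thr)
        assert g.n_edges == 0

    def test_pooled_sample_size_is_pairs_times_scenarios(self, rng):
        n = 24
        mats = []
        pooled = []
        for scen in ("L0", "L1", "L2"):
            v = rng.uniform(0, 1, (n, n))
            v = 0.5 * (v + v.T)
            np.fill_diagonal(v, 0.0)
            m = self._mat(v, condition=("S01", "T1", scen))
            mats.append(m)
            pooled.append(m.upper_triangle())
        pooled = np.concatenate(pooled)
        assert pooled.size == 276 * 3
        thr = median_threshold(mats)[("S01", "T1")]
        assert thr == pytest.approx(np.median(pooled))

    def test_median_density_near_half(self, rng):
        v = rng.uniform(0, 1, (24, 24))
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0.0)
        m = self._mat(v)
        g = binarize(m, median_threshold([m])[("S01", "T1")])
        assert 0.45 <= g.density <= 0.55


class TestSurrogates:
    def test_complete_graph_is_rewiring_invariant(self):
        g = complete_graph(8)
        c_rand, l_rand = surrogate_ensemble(g, n=20, seed=0)
        assert c_rand == 1.0 and l_rand == 1.0
        gamma, lam, sigma = small_worldness(g, (c_rand, l_rand))
        assert sigma == 1.0

    def test_degree_sequence_preserved(self):
        g, _ = random_graph(24, 0.3, 7)
        from thetanet.netmetrics import _edge_swap_surrogate

        rng = np.random.default_rng(0)
        for _ in range(5):
            sur, n_swaps = _edge_swap_surrogate(g.adjacency, rng,
                                                10 * g.n_edges)
            assert n_swaps > 0
            assert np.array_equal(sur.sum(0), g.adjacency.sum(0))

    def test_star_falls_back_to_density_matched_random(self, caplog):
        g = graph_from_edges(6, [(0, j) for j in range(1, 6)])
        with caplog.at_level("WARNING"):
            c_rand, l_rand = surrogate_ensemble(g, n=10, seed=1)
        assert "falling back" in caplog.text
        assert l_rand > 0

    def test_ring_lattice_has_higher_clustering_and_length_than_random(self):
        G = nx.watts_strogatz_graph(24, 4, 0.0, seed=0)  # pure ring lattice
        g = BinaryGraph(adjacency=nx.to_numpy_array(G, dtype=bool))
        c_obs = clustering_coefficient(g)
        l_obs, _ = char_path_length(g)
        wins = 0
        for seed in range(20):
            c_r, l_r = surrogate_ensemble(g, n=5, seed=seed)
            wins += (c_r < c_obs) and (l_r < l_obs)
        assert wins >= 19

    def test_small_world_graph_exceeds_criterion(self):
        for seed in range(5):
            G = nx.watts_strogatz_graph(24, 4, 0.1, seed=seed)
            g = BinaryGraph(adjacency=nx.to_numpy_array(G, dtype=bool))
            m = compute_metrics(g, n_surrogates=50, seed=seed)
            assert m.sigma > 1.0
            assert m.sigma == pytest.approx(m.gamma / m.lam)

    def test_dense_random_graph_sigma_near_unity(self):
        sigmas = []
        for seed in range(20):
            g, _ = random_graph(24, 0.5, 300 + seed)
            m = compute_metrics(g, n_surrogates=20, seed=seed)
            sigmas.append(m.sigma)
        assert 0.8 <= np.mean(sigmas) <= 1.2

    def test_edgeless_graph_rejected(self):
        g = graph_from_edges(4, [])
        with pytest.raises(ValueError, match="edge"):
            surrogate_ensemble(g, n=5, seed=0)


class TestInvariantsAndBounds:
    @given(seed=st.integers(0, 5000))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_adding_an_edge_never_decreases_global_efficiency(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        g, _ = random_graph(n, float(rng.uniform(0.1, 0.7)), seed)
        base = global_efficiency(g)
        non_edges = [(i, j) for i in range(n) for j in range(i + 1, n)
                     if not g.adjacency[i, j]]
        if not non_edges:
            return
        i, j = non_edges[rng.integers(len(non_edges))]
        a = g.adjacency.copy()
        a[i, j] = a[j, i] = True
        assert global_efficiency(BinaryGraph(adjacency=a)) >= base - 1e-12

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_metric_bounds(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        g, _ = random_graph(n, float(rng.uniform(0.15, 0.9)), seed + 1)
        if g.n_edges == 0:
            return
        assert 0.0 <= global_efficiency(g) <= 1.0
        per_node, mean = local_efficiency(g)
        assert np.all((per_node >= 0) & (per_node <= 1))
        assert 0.0 <= clustering_coefficient(g) <= 1.0
        assert char_path_length(g)[0] >= 1.0

    def test_graph_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            BinaryGraph(adjacency=np.array([[0, 1], [0, 0]], dtype=bool))
        with pytest.raises(ValueError, match="self-loops"):
            BinaryGraph(adjacency=np.eye(3, dtype=bool))
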