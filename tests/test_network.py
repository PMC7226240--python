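"""SparCC correlations and betweenness centrality, with independent oracles.

The SparCC oracle solves the pairwise basis system t_ij ~ w_i^2 + w_j^2
directly by least squares; the betweenness oracle enumerates all simple
paths between every node pair.  Both are implemented here, independently
of the package's solvers.
"""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cementome.io import QuantMatrix, ValidationError
from cementome.network import (
    SparccParams,
    betweenness_centrality,
    build_network,
    centrality_table,
    sparcc,
    sparcc_correlations,
    variation_matrix,
)


def _frame(arr, names=None):
    arr = np.asarray(arr, dtype=float)
    names = names or [f"c{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=names, columns=[f"r{j}" for j in range(arr.shape[1])])


class TestVariationMatrix:
    def test_identical_components_zero(self):
        t = variation_matrix(_frame([[1, 2, 4], [1, 2, 4], [5, 5, 5]]), pseudocount=1e-12)
        assert t.iloc[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_hand_value(self):
        # t_ij = sample variance of log([1,2,4]/[1,1,1]) = var(0, ln2, ln4)
        #      = ln(2)^2 = 0.480453
        t = variation_matrix(_frame([[1, 2, 4], [1, 1, 1], [3, 3, 3], [2, 2, 2]]),
                             pseudocount=1e-12)
        assert t.iloc[0, 1] == pytest.approx(np.log(2.0) ** 2, abs=1e-6)

    def test_symmetric_zero_diagonal_nonnegative(self):
        rng = np.random.default_rng(0)
        t = variation_matrix(_frame(rng.lognormal(0, 1, size=(5, 20))))
        arr = t.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0.0)
        assert (arr >= 0).all()

    def test_compositional_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(3, 0.5, size=(6, 15))
        scales = rng.uniform(0.5, 10.0, size=15)
        t1 = variation_matrix(_frame(x), pseudocount=1e-12)
        t2 = variation_matrix(_frame(x * scales), pseudocount=1e-12)
        assert np.allclose(t1, t2, atol=1e-8)

    def test_needs_three_runs(self):
        with pytest.raises(ValidationError):
            variation_matrix(_frame([[1, 2], [3, 4]]))


def _lstsq_basis_oracle(t_frame):
    """Least-squares fit of t_ij = w_i^2 + w_j^2 over all pairs i<j."""
    t = t_frame.to_numpy()
    d = t.shape[0]
    pairs = list(itertools.combinations(range(d), 2))
    design = np.zeros((len(pairs), d))
    rhs = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        design[row, i] = design[row, j] = 1.0
        rhs[row] = t[i, j]
    w2, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    w = np.sqrt(np.clip(w2, 1e-12, None))
    rho = (w2[:, None] + w2[None, :] - t) / (2.0 * np.outer(w, w))
    return np.clip(rho, -1.0, 1.0)


class TestSparcc:
    def _independent_data(self, n_comp=5, n_runs=400, seed=0):
        rng = np.random.default_rng(seed)
        logs = rng.normal(5.0, 1.0, size=(n_comp, n_runs))
        comp = np.exp(logs)
        comp = comp / comp.sum(axis=0)  # closed compositions
        return _frame(comp)

    def test_oracle_equivalence_no_exclusions(self):
        for n_comp in (4, 5, 6):
            data = self._independent_data(n_comp=n_comp, seed=n_comp)
            t = variation_matrix(data, pseudocount=1e-12)
            result = sparcc_correlations(t, SparccParams(exclusion_threshold=0.9))
            assert result.excluded_pairs == []
            oracle = _lstsq_basis_oracle(t)
            assert np.allclose(result.rho.to_numpy(), oracle, atol=1e-6)

    def test_diagonal_is_one(self):
        data = self._independent_data()
        result = sparcc(data, SparccParams(pseudocount=1e-12))
        assert np.allclose(np.diag(result.rho), 1.0)

    def test_independent_components_near_zero(self):
        data = self._independent_data(n_comp=6, n_runs=1000, seed=3)
        result = sparcc(data, SparccParams(pseudocount=1e-12))
        off = result.rho.to_numpy()[~np.eye(6, dtype=bool)]
        assert np.mean(np.abs(off)) < 0.1

    def test_planted_pair_recovered(self):
        rng = np.random.default_rng(12)
        n_runs = 1000
        cov = np.eye(5)
        cov[0, 1] = cov[1, 0] = 0.8
        logs = rng.multivariate_normal([6, 6, 5, 5, 4], cov, size=n_runs).T
        comp = np.exp(logs)
        comp = comp / comp.sum(axis=0)
        result = sparcc(_frame(comp), SparccParams(pseudocount=1e-12))
        assert result.rho.iloc[0, 1] == pytest.approx(0.8, abs=0.1)
        others = [abs(result.rho.iloc[i, j]) for i in range(5) for j in range(i + 1, 5)
                  if (i, j) != (0, 1)]
        assert max(others) < 0.45

    def test_needs_four_components(self):
        t = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValidationError):
            sparcc_correlations(t)


def _naive_betweenness(graph):
    """All-pairs shortest-path enumeration over simple paths (<= 8 nodes)."""
    bnc = {n: 0.0 for n in graph.nodes}
    nodes = list(graph.nodes)
    for s, t in itertools.combinations(nodes, 2):
        paths = []
        for path in nx.all_simple_paths(graph, s, t):
            length = sum(graph[u][v].get("distance", 1.0)
                         for u, v in zip(path, path[1:]))
            paths.append((length, path))
        if not paths:
            continue
        best = min(length for length, _ in paths)
        shortest = [p for length, p in paths if length <= best + 1e-12]
        for path in shortest:
            for v in path[1:-1]:
                bnc[v] += 1.0 / len(shortest)
    return bnc


class TestBetweenness:
    def test_star_center_unnormalized(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        bnc = betweenness_centrality(g)
        assert bnc[0] == pytest.approx(6.0)  # C(4,2) pairs
        assert all(bnc[leaf] == 0.0 for leaf in range(1, 5))

    def test_path_graph(self):
        g = nx.path_graph(3)
        bnc = betweenness_centrality(g)
        assert bnc[1] == pytest.approx(1.0)
        assert bnc[0] == bnc[2] == 0.0

    def test_complete_graph_symmetric(self):
        g = nx.complete_graph(5)
        bnc = betweenness_centrality(g)
        assert len(set(round(v, 12) for v in bnc.values())) == 1

    def test_matches_naive_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(99)
        for trial in range(100):
            n = int(rng.integers(2, 9))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(0, 2**31)))
            if trial % 2:  # alternate weighted / unweighted
                for u, v in g.edges:
                    rho = float(rng.uniform(0.3, 0.95))
                    g[u][v]["weight"] = rho
                    g[u][v]["distance"] = 1.0 - rho
            ours = betweenness_centrality(g)
            naive = _naive_betweenness(g)
            for node in g.nodes:
                assert ours[node] == pytest.approx(naive[node], abs=1e-9)

    def test_isolated_node_zero(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        g.add_edge("a", "b", weight=0.9, distance=0.1)
        bnc = betweenness_centrality(g)
        assert bnc["c"] == 0.0


class TestBuildNetwork:
    def _rho(self):
        names = list("abcd")
        rho = np.array([
            [1.0, 0.9, 0.2, -0.7],
            [0.9, 1.0, 0.5, 0.1],
            [0.2, 0.5, 1.0, 0.65],
            [-0.7, 0.1, 0.65, 1.0],
        ])
        return pd.DataFrame(rho, index=names, columns=names)

    def test_threshold_one_keeps_only_perfect(self):
        g = build_network(self._rho(), 1.0)
        assert g.number_of_edges() == 0

    def test_threshold_zero_complete(self):
        g = build_network(self._rho(), 0.0)
        assert g.number_of_edges() == 6

    def test_monotone_shrinking(self):
        sizes = [build_network(self._rho(), t).number_of_edges()
                 for t in (0.0, 0.3, 0.6, 0.9)]
        assert sizes == sorted(sizes, reverse=True)

    def test_sign_kept_distance_uses_magnitude(self):
        g = build_network(self._rho(), 0.6)
        assert g["a"]["d"]["weight"] == pytest.approx(-0.7)
        assert g["a"]["d"]["distance"] == pytest.approx(0.3)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValidationError):
            build_network(self._rho(), 1.5)

    def test_centrality_table_sorted(self):
        g = build_network(self._rho(), 0.4)
        table = centrality_table(g)
        assert list(table["bnc"]) == sorted(table["bnc"], reverse=True)
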