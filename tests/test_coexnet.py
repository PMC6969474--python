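"""Correlation thresholding, binary networks and node statistics vs oracles."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from coexpreserve import (
    AdjacencyNetwork,
    ConfigurationError,
    CorrelationResult,
    DataError,
    ExpressionMatrix,
    clustering_coefficient,
    connectivity,
    correlation_pvalue,
    network_summary,
    pearson_matrix,
    threshold_adjacency,
)
from conftest import (
    clustering_by_triangle_enumeration,
    degrees_from_edge_list,
    random_adjacency,
)


def expr_from(rows: dict) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(rows).T)


def net_from_edges(n: int, edges) -> AdjacencyNetwork:
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return AdjacencyNetwork([f"G{i}" for i in range(n)], a)


class TestCorrelationPvalue:
    def test_zero_correlation_gives_p_one(self):
        assert correlation_pvalue(0.0, 9) == pytest.approx(1.0)

    def test_two_sided_symmetry_and_value(self):
        p_pos = correlation_pvalue(0.7, 9)
        p_neg = correlation_pvalue(-0.7, 9)
        assert p_pos == pytest.approx(p_neg)
        assert p_pos == pytest.approx(0.0358, abs=2e-4)

    def test_critical_r_at_nine_samples(self):
        # t = 0.667*sqrt(7/(1-0.667^2)) ~ 2.366 ~ t_{0.975,7}
        assert correlation_pvalue(0.667, 9) == pytest.approx(0.050, abs=1e-3)

    def test_perfect_correlation_p_zero(self):
        assert correlation_pvalue(1.0, 9) == 0.0
        assert correlation_pvalue(-1.0, 5) == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigurationError):
            correlation_pvalue(0.5, 2)

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.standard_normal((2, 9))
            r, p_ref = sps.pearsonr(x, y)
            assert correlation_pvalue(r, 9) == pytest.approx(p_ref, rel=1e-10)


class TestPearsonMatrix:
    def test_diagonal_and_antiperfect_pair(self):
        expr = expr_from({"G1": [1, 2, 3], "G2": [3, 2, 1]})
        res = pearson_matrix(expr)
        assert res.r[0, 0] == 1.0
        assert res.r[0, 1] == pytest.approx(-1.0)
        assert np.isnan(res.p[0, 0])

    def test_hand_computed_pearson(self):
        expr = expr_from({"G1": [1, 2, 3], "G2": [1, 2, 4]})
        assert pearson_matrix(expr).r[0, 1] == pytest.approx(0.98198, abs=1e-5)

    def test_symmetry_on_random_data(self):
        rng = np.random.default_rng(1)
        expr = ExpressionMatrix(pd.DataFrame(rng.standard_normal((12, 9))))
        res = pearson_matrix(expr)
        np.testing.assert_allclose(res.r, res.r.T)
        np.testing.assert_allclose(res.p, res.p.T)

    def test_constant_gene_excluded_with_warning(self):
        expr = expr_from({"G1": [1, 2, 3], "G2": [5, 5, 5], "G3": [2, 1, 3]})
        with pytest.warns(UserWarning, match="G2"):
            res = pearson_matrix(expr)
        assert res.gene_ids == ["G1", "G3"]

    def test_constant_gene_strict_mode_errors(self):
        expr = expr_from({"G1": [1, 2, 3], "G2": [5, 5, 5]})
        with pytest.raises(DataError, match="constant"):
            pearson_matrix(expr, strict=True)


class TestThresholdAdjacency:
    @pytest.mark.parametrize(
        "r,p,expected",
        [(0.7, 0.036, 1), (0.9, 0.06, 0), (0.4, 0.01, 0), (0.5, 0.05, 1)],
    )
    def test_rule_applications(self, r, p, expected):
        rr = np.array([[1.0, r], [r, 1.0]])
        pp = np.array([[np.nan, p], [p, np.nan]])
        net = threshold_adjacency(CorrelationResult(["G1", "G2"], rr, pp, 9))
        assert net.a[0, 1] == expected

    @pytest.mark.parametrize("kwargs", [{"r_min": -0.1}, {"r_min": 1.5}, {"p_max": 0.0}, {"p_max": 1.2}])
    def test_threshold_validation(self, kwargs):
        res = CorrelationResult(["G1"], np.ones((1, 1)), np.full((1, 1), np.nan), 9)
        with pytest.raises(ConfigurationError):
            threshold_adjacency(res, **kwargs)

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(2)
        expr = ExpressionMatrix(pd.DataFrame(rng.standard_normal((20, 9))))
        corr = pearson_matrix(expr)
        base = threshold_adjacency(corr, r_min=0.3, p_max=0.2).a
        tighter_r = threshold_adjacency(corr, r_min=0.5, p_max=0.2).a
        tighter_p = threshold_adjacency(corr, r_min=0.3, p_max=0.05).a
        assert (tighter_r <= base).all() and (tighter_p <= base).all()

    def test_paper_settings_edges_exceed_critical_r_at_n9(self):
        # at n = 9, p <= 0.05 alone forces |r| >= 0.666, so the r-criterion is redundant
        rng = np.random.default_rng(3)
        expr = ExpressionMatrix(pd.DataFrame(rng.standard_normal((40, 9))))
        corr = pearson_matrix(expr)
        net = threshold_adjacency(corr, r_min=0.5, p_max=0.05)
        ii, jj = np.nonzero(net.a)
        assert len(ii) > 0
        assert (np.abs(corr.r[ii, jj]) >= 0.666).all()


class TestNodeStatistics:
    def test_triangle_connectivity(self):
        net = net_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        assert connectivity(net).tolist() == [2, 2, 2]

    def test_star_connectivity(self):
        net = net_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        assert connectivity(net).tolist() == [3, 1, 1, 1]

    def test_empty_network(self):
        net = net_from_edges(4, [])
        assert connectivity(net).tolist() == [0, 0, 0, 0]
        assert np.isnan(clustering_coefficient(net)).all()

    def test_complete_graph_clustering_is_one(self):
        net = net_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        np.testing.assert_allclose(clustering_coefficient(net), 1.0)

    def test_path_of_three(self):
        net = net_from_edges(3, [(0, 1), (1, 2)])
        c = clustering_coefficient(net)
        assert c[1] == 0.0
        assert np.isnan(c[0]) and np.isnan(c[2])

    def test_triangle_with_pendant(self):
        # edges {1-2, 1-3, 2-3, 1-4}: node 1 has one triangle among 3 neighbors
        net = net_from_edges(4, [(0, 1), (0, 2), (1, 2), (0, 3)])
        assert clustering_coefficient(net)[0] == pytest.approx(1 / 3)

    def test_adjacency_invariants_enforced(self):
        with pytest.raises(DataError):
            AdjacencyNetwork(["G0", "G1"], np.array([[0, 1], [0, 0]]))  # asymmetric
        with pytest.raises(DataError):
            AdjacencyNetwork(["G0", "G1"], np.array([[1, 0], [0, 0]]))  # diagonal
        with pytest.raises(DataError):
            AdjacencyNetwork(["G0", "G1"], np.array([[0, 2], [2, 0]]))  # non-binary


class TestAgainstOracles:
    def test_node_stats_match_brute_force_and_networkx(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(2, 26))
            a = random_adjacency(rng, n, p=float(rng.uniform(0.05, 0.6)))
            net = AdjacencyNetwork([f"G{i}" for i in range(n)], a)
            k = connectivity(net)
            c = clustering_coefficient(net)
            np.testing.assert_array_equal(k, degrees_from_edge_list(a))
            np.testing.assert_allclose(c, clustering_by_triangle_enumeration(a), equal_nan=True)
            g = nx.from_numpy_array(a)
            nx_c = nx.clustering(g)
            for i in range(n):
                if k[i] > 1:
                    assert c[i] == pytest.approx(nx_c[i])

    def test_printed_denominator_equals_k_times_k_minus_one(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(2, 20))
            a = random_adjacency(rng, n, p=0.4).astype(np.int64)
            row = a.sum(axis=1)
            denominator = row.astype(float) ** 2 - (a**2).sum(axis=1)
            np.testing.assert_allclose(denominator, row * (row - 1))


class TestNetworkSummary:
    def test_empty(self):
        s = network_summary(net_from_edges(3, []))
        assert s["n_edges"] == 0 and s["density"] == 0.0 and s["mean_k"] == 0.0

    def test_complete_k4(self):
        s = network_summary(net_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)]))
        assert s["density"] == 1.0 and s["mean_c"] == 1.0

    def test_triangle_plus_isolate(self):
        s = network_summary(net_from_edges(4, [(0, 1), (1, 2), (0, 2)]))
        assert s["n_edges"] == 3 and s["n_isolated"] == 1 and s["mean_c"] == 1.0
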