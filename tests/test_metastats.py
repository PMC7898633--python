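"""Correlation graphs, clustering, PCA contributions and the BCa bootstrap."""

import numpy as np
import pytest

from herbimeta.metastats import (
    bca_interval,
    cluster_experiments,
    cluster_specificity,
    correlation_graph,
    fully_connected_subnetworks,
    pca_contributions,
    select_dimensions,
    top_contributing_genes,
)

from conftest import make_matrix
from oracles import bca_oracle


def pearson(x, y):
    """Textbook Pearson correlation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xd, yd = x - x.mean(), y - y.mean()
    return float((xd * yd).sum() / np.sqrt((xd**2).sum() * (yd**2).sum()))


class TestCorrelationGraph:
    def test_identical_profiles_get_edge(self):
        m = make_matrix([[1.0, 2, 3, 4], [1.0, 2, 3, 4], [4, 3, 2, 1.0]])
        g = correlation_graph(m, m.genes, r_min=0.95)
        pairs = {(a, b) for a, b, _ in g.edges}
        assert ("g0", "g1") in pairs

    def test_anticorrelation_needs_unsigned_mode(self):
        m = make_matrix([[1.0, 2, 3, 4], [4, 3, 2, 1.0]])
        signed = correlation_graph(m, m.genes, 0.95, signed=True)
        assert not signed.edges
        unsigned = correlation_graph(m, m.genes, 0.95, signed=False)
        assert len(unsigned.edges) == 1

    def test_zero_variance_genes_reported_not_linked(self):
        m = make_matrix([[1.0, 1, 1, 1], [1.0, 2, 3, 4], [2, 4, 6, 8.0]])
        g = correlation_graph(m, m.genes, 0.95)
        assert g.zero_variance == ["g0"]
        assert all("g0" not in (a, b) for a, b, _ in g.edges)

    def test_edges_match_textbook_formula_on_random_genes(self, rng):
        X = rng.normal(size=(50, 12))
        X[:25] += 3 * rng.normal(size=12)  # shared profile -> some high r
        m = make_matrix(X)
        g = correlation_graph(m, m.genes, r_min=0.8)
        expected = set()
        for i in range(50):
            for j in range(i + 1, 50):
                if pearson(X[i], X[j]) >= 0.8:
                    expected.add(tuple(sorted((f"g{i}", f"g{j}"))))
        got = {tuple(sorted((a, b))) for a, b, _ in g.edges}
        assert got == expected

    def test_missing_gene_errors(self):
        m = make_matrix(np.ones((3, 4)))
        with pytest.raises(ValueError, match="not in matrix"):
            correlation_graph(m, ["g0", "nope"])


class TestFullyConnectedSubnetworks:
    def graph(self, edges):
        from herbimeta.metastats import CorrelationGraph

        nodes = sorted({n for e in edges for n in e})
        return CorrelationGraph(nodes, {(a, b, 0.99) for a, b in edges},
                                0.95, True)

    def test_triangle_is_clique_component(self):
        _, cliques = fully_connected_subnetworks(
            self.graph([("a", "b"), ("b", "c"), ("a", "c")])
        )
        assert cliques == [{"a", "b", "c"}]

    def test_path_is_connected_but_not_clique(self):
        connected, cliques = fully_connected_subnetworks(
            self.graph([("a", "b"), ("b", "c")])
        )
        assert connected == {"a", "b", "c"}
        assert cliques == []

    def test_random_graphs_match_bruteforce_pair_check(self, rng):
        import networkx as nx

        for _ in range(20):
            g = nx.gnp_random_graph(30, 0.15,
                                    seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
            cg = self.graph(list(g.edges))
            _, cliques = fully_connected_subnetworks(cg)
            for comp in nx.connected_components(g):
                if len(comp) < 2:
                    continue
                is_clique = all(g.has_edge(u, v)
                                for u in comp for v in comp if u < v)
                assert (set(comp) in cliques) == is_clique


class TestClusterExperiments:
    def test_two_identical_groups_split_exactly(self):
        cols = np.array([[1.0] * 3 + [5.0] * 3] * 4)
        m = make_matrix(cols)
        cl = cluster_experiments(m, k=2)
        assert {cl.labels[e] for e in m.experiments[:3]} == {1}
        assert {cl.labels[e] for e in m.experiments[3:]} == {2}

    def test_k_equals_n_gives_singletons(self):
        m = make_matrix(np.arange(12.0).reshape(3, 4))
        cl = cluster_experiments(m, k=4)
        assert sorted(cl.labels.values()) == [1, 2, 3, 4]

    def test_invalid_k(self):
        m = make_matrix(np.ones((3, 4)))
        with pytest.raises(ValueError):
            cluster_experiments(m, k=0)
        with pytest.raises(ValueError):
            cluster_experiments(m, k=5)

    def test_invariant_to_gene_row_permutation(self, rng):
        X = rng.normal(size=(40, 10))
        m1 = make_matrix(X)
        perm = rng.permutation(40)
        m2 = make_matrix(X[perm], genes=[f"g{i}" for i in perm])
        c1 = cluster_experiments(m1, k=3)
        c2 = cluster_experiments(m2, k=3)
        assert c1.labels == c2.labels


class TestPCA:
    def test_contributions_sum_to_100_per_dimension(self, rng):
        m = make_matrix(rng.normal(size=(30, 6)))
        res = pca_contributions(m)
        np.testing.assert_allclose(res.gene_contrib.sum(axis=0), 100,
                                   atol=1e-6)
        np.testing.assert_allclose(res.experiment_contrib.sum(axis=0), 100,
                                   atol=1e-6)

    def test_eigenvalues_sum_to_total_variance(self, rng):
        m = make_matrix(rng.normal(size=(25, 5)))
        res = pca_contributions(m)
        assert res.eigenvalues.sum() == pytest.approx(res.total_variance,
                                                      rel=1e-9)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_matches_direct_covariance_eigendecomposition(self):
        X = np.array([[1.0, 2.0, 0.5], [2.0, 1.0, 0.0], [3.0, 4.0, 1.5],
                      [0.0, 1.0, 2.5], [1.5, 0.5, 1.0], [2.5, 3.0, 0.5]])
        m = make_matrix(X)
        res = pca_contributions(m)
        cov = np.cov(X - X.mean(axis=0), rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(res.eigenvalues, eig, atol=1e-10)
        # scores reproduce the centered data through the loadings
        np.testing.assert_allclose(
            res.gene_scores @ res.experiment_loadings.T,
            X - X.mean(axis=0), atol=1e-10,
        )

    def test_score_vectors_orthogonal(self, rng):
        m = make_matrix(rng.normal(size=(40, 8)))
        res = pca_contributions(m)
        gram = res.gene_scores.T @ res.gene_scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_scaling_constant_column_errors(self):
        X = np.ones((5, 3))
        X[:, 1] = np.arange(5)
        m = make_matrix(X)
        with pytest.raises(ValueError, match="e0"):
            pca_contributions(m, scale=True)


class TestSelectDimensions:
    def test_worked_example(self):
        from herbimeta.metastats import PCAResult

        res = PCAResult(
            eigenvalues=np.array([5.0, 3.0, 1.5, 0.5]),
            gene_scores=np.zeros((1, 4)), experiment_loadings=np.zeros((1, 4)),
            gene_contrib=np.zeros((1, 4)), experiment_contrib=np.zeros((1, 4)),
            genes=["g"], experiments=["e"], total_variance=10.0,
        )
        sel = select_dimensions(res, 0.70)
        assert sel.dims == [1, 2]
        assert sel.inflection == 2

    def test_single_dominant_dimension(self):
        from herbimeta.metastats import PCAResult

        res = PCAResult(
            eigenvalues=np.array([10.0, 0.0]),
            gene_scores=np.zeros((1, 2)), experiment_loadings=np.zeros((1, 2)),
            gene_contrib=np.zeros((1, 2)), experiment_contrib=np.zeros((1, 2)),
            genes=["g"], experiments=["e"], total_variance=10.0,
        )
        assert select_dimensions(res, 0.70).dims == [1]

    def test_eight_strong_components_select_depth_eight(self, rng):
        # build a matrix whose column-covariance spectrum has 8 dominant
        # dimensions crossing the 70% cumulative-variance mark exactly at 8
        lam = np.array([40.0, 18, 15, 13, 12, 11, 10.5, 10] + [3.0] * 16)
        G = 500
        U = np.linalg.qr(rng.normal(size=(G, 24)))[0]
        V = np.linalg.qr(rng.normal(size=(24, 24)))[0]
        X = U @ np.diag(np.sqrt(lam * (G - 1))) @ V.T
        m = make_matrix(X)
        res = pca_contributions(m)
        sel = select_dimensions(res, 0.70)
        assert sel.n_variance == 8
        assert max(sel.dims) == 8


class TestTopContributingGenes:
    def test_single_dimension_equals_contribution_order(self, rng):
        m = make_matrix(rng.normal(size=(20, 5)))
        res = pca_contributions(m)
        top = top_contributing_genes(res, [1], n=20)
        order = np.argsort(-res.gene_contrib[:, 0], kind="stable")
        assert [g for g, _ in top][:5] == [res.genes[i] for i in order[:5]]

    def test_all_genes_is_permutation(self, rng):
        m = make_matrix(rng.normal(size=(15, 4)))
        res = pca_contributions(m)
        top = top_contributing_genes(res, [1, 2], n=15)
        assert sorted(g for g, _ in top) == sorted(res.genes)

    def test_requires_dims(self, rng):
        res = pca_contributions(make_matrix(rng.normal(size=(5, 3))))
        with pytest.raises(ValueError):
            top_contributing_genes(res, [], n=3)


class TestBcaInterval:
    def test_constant_sample_degenerates(self):
        iv = bca_interval([3.0, 3.0, 3.0], B=100, seed=0)
        assert iv.degenerate
        assert iv.lower == iv.upper == 3.0

    def test_symmetric_sample_reduces_to_percentile(self):
        x = [-2.0, -1.0, 0.0, 1.0, 2.0]
        iv = bca_interval(x, B=20_000, seed=42)
        assert iv.a == pytest.approx(0.0, abs=1e-12)
        assert abs(iv.z0) < 0.05
        rng = np.random.default_rng(42)
        boot = np.sort(np.asarray(x)[rng.integers(0, 5, (20_000, 5))]
                       .mean(axis=1))
        lo, hi = np.quantile(boot, [0.025, 0.975])
        assert iv.lower == pytest.approx(lo, abs=0.1)
        assert iv.upper == pytest.approx(hi, abs=0.1)

    def test_matches_independent_oracle_on_fixed_sample(self):
        rng = np.random.default_rng(7)
        x = rng.gamma(2.0, 1.5, size=20)  # skewed: a and z0 both matter
        iv = bca_interval(x, B=10_000, alpha=0.05, seed=123)
        lo, hi, z0, a = bca_oracle(x, B=10_000, alpha=0.05, seed=123)
        assert iv.z0 == pytest.approx(z0, abs=1e-9)
        assert iv.a == pytest.approx(a, abs=1e-12)
        assert iv.lower == pytest.approx(lo, abs=1e-7)
        assert iv.upper == pytest.approx(hi, abs=1e-7)

    def test_close_to_scipy_reference(self):
        from scipy.stats import bootstrap

        rng = np.random.default_rng(3)
        x = rng.normal(1.0, 2.0, size=20)
        iv = bca_interval(x, B=10_000, seed=11)
        res = bootstrap((x,), np.mean, n_resamples=10_000, method="BCa",
                        confidence_level=0.95,
                        random_state=np.random.default_rng(99))
        assert iv.lower == pytest.approx(res.confidence_interval.low,
                                         abs=0.05)
        assert iv.upper == pytest.approx(res.confidence_interval.high,
                                         abs=0.05)

    def test_interval_nests_with_confidence_level(self):
        # same bootstrap draws: a lower-confidence interval sits inside
        rng = np.random.default_rng(5)
        x = rng.normal(size=15)
        wide = bca_interval(x, B=5_000, alpha=0.05, seed=8)
        narrow = bca_interval(x, B=5_000, alpha=0.20, seed=8)
        assert wide.lower <= narrow.lower <= narrow.upper <= wide.upper

    def test_rejects_tiny_samples(self):
        with pytest.raises(ValueError):
            bca_interval([1.0], B=10, seed=0)


class TestClusterSpecificity:
    def setup_case(self):
        lfc = np.array([
            [5.0, 5.1, 4.9, 0.1, -0.1, 0.0],   # far above the global mean
            [-1.0, 2.0, -0.5, 1.0, 0.3, -0.8],  # straddles it
        ])
        m = make_matrix(lfc)
        cl = cluster_experiments(m, k=2)
        return m, cl

    def test_flagged_above_and_straddle_not_flagged(self):
        m, _ = self.setup_case()
        from herbimeta.metastats import ClusterAssignment

        cl = ClusterAssignment(
            experiments=m.experiments,
            labels={"e0": 1, "e1": 1, "e2": 1, "e3": 2, "e4": 2, "e5": 2},
            k=2, linkage_matrix=np.zeros((0, 4)),
        )
        calls = cluster_specificity(m, ["g0", "g1"], cl, B=2_000, seed=0)
        by_key = {(c.gene_id, c.cluster): c for c in calls}
        assert by_key[("g0", 1)].flagged
        assert by_key[("g0", 1)].direction == "above"
        assert not by_key[("g1", 1)].flagged

    def test_small_cluster_rejected(self):
        m = make_matrix(np.ones((2, 3)) * np.arange(3))
        from herbimeta.metastats import ClusterAssignment

        cl = ClusterAssignment(
            experiments=m.experiments,
            labels={"e0": 1, "e1": 1, "e2": 2},
            k=2, linkage_matrix=np.zeros((0, 4)),
        )
        with pytest.raises(ValueError, match="cluster 2"):
            cluster_specificity(m, ["g0"], cl, B=100, seed=0)
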