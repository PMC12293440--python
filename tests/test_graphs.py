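import numpy as np
import pytest

from erpgraph.graphs import (
    GraphMetricSet,
    assemble_features,
    char_path_length,
    global_efficiency,
    graph_energy,
    graph_metrics,
    node_strength,
    path_length_stats,
    proportional_threshold,
    surrogate_ensemble,
    surrogate_zscore,
    transitivity,
    weighted_clustering,
)
from . import oracles


def sym(W):
    W = np.asarray(W, dtype=float)
    return np.triu(W, 1) + np.triu(W, 1).T


TRIANGLE = sym([[0, 0.5, 0.5], [0, 0, 1.0], [0, 0, 0]])
UNIT_K3 = sym([[0, 1, 1], [0, 0, 1], [0, 0, 0]])
PATH3 = sym([[0, 1, 0], [0, 0, 1], [0, 0, 0]])
UNIT_K4 = sym(np.ones((4, 4)))
STAR4 = sym([[0, 1, 1, 1], [0, 0, 0, 0], [0, 0, 0, 0], [0, 0, 0, 0]])


class TestProportionalThreshold:
    def test_exact_edge_count(self):
        rng = np.random.default_rng(0)
        W = sym(rng.random((10, 10)))
        out = proportional_threshold(W, 0.2)
        assert (np.triu(out, 1) > 0).sum() == 9  # ceil(0.2 * 45)

    def test_sparsity_one_identity(self):
        rng = np.random.default_rng(1)
        W = sym(rng.random((6, 6)))
        assert np.allclose(proportional_threshold(W, 1.0), W)

    def test_strongest_edge_survives(self):
        W = sym([[0, 0.9, 0.5], [0, 0, 0.1], [0, 0, 0]])
        out = proportional_threshold(W, 1 / 3)
        assert out[0, 1] == 0.9
        assert (np.triu(out, 1) > 0).sum() == 1

    def test_tie_break_deterministic_with_warning(self):
        W = sym(np.ones((5, 5)) * 0.4)
        with pytest.warns(UserWarning, match="degenerate"):
            a = proportional_threshold(W, 0.3)
        with pytest.warns(UserWarning):
            b = proportional_threshold(W, 0.3)
        assert np.array_equal(a, b)
        # lexicographically first pairs kept
        assert a[0, 1] > 0 and a[0, 2] > 0


class TestMetricExamples:
    def test_strength_triangle(self):
        assert np.allclose(node_strength(TRIANGLE), [1.0, 1.5, 1.5])

    def test_strength_k4(self):
        assert np.allclose(node_strength(UNIT_K4), 3.0)

    def test_clustering_unit_triangle(self):
        assert np.allclose(weighted_clustering(UNIT_K3), 1.0)

    def test_clustering_star_zero(self):
        assert np.allclose(weighted_clustering(STAR4), 0.0)

    def test_clustering_uniform_triangle_max_normalized(self):
        assert np.allclose(weighted_clustering(UNIT_K3 * 0.5), 1.0)

    def test_transitivity(self):
        assert transitivity(UNIT_K3) == pytest.approx(1.0)
        assert transitivity(PATH3) == 0.0
        assert transitivity(UNIT_K4) == pytest.approx(1.0)

    def test_path_length(self):
        assert char_path_length(UNIT_K3) == pytest.approx(1.0)
        assert char_path_length(PATH3) == pytest.approx(4.0 / 3.0)

    def test_disconnected_pairs_counted(self):
        two_edges = np.zeros((4, 4))
        two_edges[0, 1] = two_edges[1, 0] = 1.0
        two_edges[2, 3] = two_edges[3, 2] = 1.0
        L, n_disc = path_length_stats(two_edges)
        assert L == pytest.approx(1.0)
        assert n_disc == 8

    def test_no_edges_error(self):
        with pytest.raises(ValueError, match="no edges"):
            char_path_length(np.zeros((3, 3)))

    def test_efficiency(self):
        assert global_efficiency(UNIT_K4) == pytest.approx(1.0)
        assert global_efficiency(np.zeros((4, 4))) == 0.0
        assert global_efficiency(PATH3) == pytest.approx(5.0 / 6.0)

    def test_energy(self):
        k2 = np.zeros((2, 2))
        k2[0, 1] = k2[1, 0] = 1.0
        assert graph_energy(k2) == pytest.approx(2.0)
        assert graph_energy(UNIT_K3) == pytest.approx(4.0)
        assert graph_energy(np.zeros((3, 3))) == 0.0


class TestOracleEquivalence:
    def test_all_metrics_match_brute_force(self):
        """On 100 random graphs of <= 6 nodes, all six metrics agree
        with exhaustive enumeration / characteristic-polynomial
        oracles to 1e-10."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            W = oracles.random_small_graph(rng)
            assert np.allclose(node_strength(W), oracles.strength_bf(W),
                               atol=1e-10)
            assert np.allclose(weighted_clustering(W),
                               oracles.clustering_bf(W), atol=1e-10)
            assert transitivity(W) == pytest.approx(
                oracles.transitivity_bf(W), abs=1e-10
            )
            assert graph_energy(W) == pytest.approx(
                oracles.graph_energy_bf(W), abs=1e-10
            )
            assert global_efficiency(W) == pytest.approx(
                oracles.global_efficiency_bf(W), abs=1e-10
            )
            if (W > 0).any():
                L, n_disc = path_length_stats(W)
                assert L == pytest.approx(
                    oracles.char_path_length_bf(W), abs=1e-10
                )
                assert n_disc == oracles.n_disconnected_bf(W)


class TestProperties:
    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        W = oracles.random_small_graph(rng, max_nodes=6)
        n = len(W)
        perm = rng.permutation(n)
        Wp = W[np.ix_(perm, perm)]
        assert np.allclose(node_strength(Wp), node_strength(W)[perm])
        assert np.allclose(weighted_clustering(Wp),
                           weighted_clustering(W)[perm])
        for g in (transitivity, graph_energy, global_efficiency):
            assert g(Wp) == pytest.approx(g(W), abs=1e-12)

    def test_scale_behavior(self):
        rng = np.random.default_rng(8)
        W = sym(rng.random((5, 5)))
        alpha = 3.7
        assert np.allclose(node_strength(alpha * W),
                           alpha * node_strength(W))
        assert np.allclose(weighted_clustering(alpha * W),
                           weighted_clustering(W))
        assert transitivity(alpha * W) == pytest.approx(transitivity(W))
        assert graph_energy(alpha * W) == pytest.approx(
            alpha * graph_energy(W)
        )
        assert char_path_length(alpha * W) == pytest.approx(
            char_path_length(W) / alpha
        )


class TestSurrogates:
    @pytest.fixture
    def thresholded(self):
        rng = np.random.default_rng(10)
        W = sym(rng.random((12, 12)))
        return proportional_threshold(W, 0.3)

    def test_degree_sequence_and_weights_preserved(self, thresholded):
        ens = surrogate_ensemble(thresholded, n=20, seed=5)
        deg0 = np.sort((thresholded > 0).sum(axis=1))
        w0 = np.sort(thresholded[np.triu_indices(12, 1)])
        for S in ens.graphs:
            assert np.array_equal(np.sort((S > 0).sum(axis=1)), deg0)
            assert np.allclose(np.sort(S[np.triu_indices(12, 1)]), w0)
            assert np.allclose(S, S.T)
            assert np.allclose(np.diag(S), 0.0)

    def test_rewiring_changes_topology(self, thresholded):
        ens = surrogate_ensemble(thresholded, n=10, seed=6)
        changed = [
            not np.array_equal(S > 0, thresholded > 0) for S in ens.graphs
        ]
        assert all(changed)

    def test_star_falls_back_to_weight_permutation(self):
        star = np.zeros((5, 5))
        star[0, 1:] = [0.1, 0.2, 0.3, 0.4]
        star += star.T
        with pytest.warns(UserWarning, match="weight permutation"):
            ens = surrogate_ensemble(star, n=5, seed=1)
        assert ens.fallback_weight_permutation
        for S in ens.graphs:
            assert np.array_equal(S > 0, star > 0)

    def test_determinism(self, thresholded):
        a = surrogate_ensemble(thresholded, n=5, seed=9)
        b = surrogate_ensemble(thresholded, n=5, seed=9)
        for Sa, Sb in zip(a.graphs, b.graphs):
            assert np.array_equal(Sa, Sb)

    def test_modular_graph_clustering_z(self):
        """A strongly modular planted graph has clustering far from the
        degree-preserving null (|z| > 2 on the mean node)."""
        W = np.zeros((30, 30))
        rng = np.random.default_rng(11)
        for block in (range(0, 10), range(10, 20), range(20, 30)):
            for i in block:
                for j in block:
                    if i < j:
                        W[i, j] = W[j, i] = rng.uniform(0.6, 1.0)
        # sparse random inter-module edges
        for _ in range(15):
            i, j = rng.integers(0, 30, 2)
            if i != j and W[i, j] == 0:
                W[i, j] = W[j, i] = rng.uniform(0.1, 0.3)
        ens = surrogate_ensemble(W, n=100, seed=12)
        orig = graph_metrics(W)
        surr = [graph_metrics(S) for S in ens.graphs]
        z = surrogate_zscore(orig, surr)
        assert abs(z.clustering.mean()) > 2.0


class TestSurrogateZscore:
    def _const_set(self, value):
        return GraphMetricSet(
            strength=np.full(3, value), clustering=np.full(3, value),
            energy=value, efficiency=value, transitivity=value,
            path_length=value,
        )

    def test_arithmetic(self):
        orig = self._const_set(10.0)
        surr = [self._const_set(7.0), self._const_set(9.0)]
        z = surrogate_zscore(orig, surr)  # mean 8, sd sqrt(2)
        assert z.energy == pytest.approx(2.0 / np.sqrt(2.0))

    def test_equal_to_mean_gives_zero(self):
        orig = self._const_set(8.0)
        surr = [self._const_set(7.0), self._const_set(9.0)]
        z = surrogate_zscore(orig, surr)
        assert z.energy == 0.0
        assert np.allclose(z.strength, 0.0)

    def test_zero_sd_flagged_zero(self):
        orig = self._const_set(5.0)
        surr = [self._const_set(7.0), self._const_set(7.0)]
        with pytest.warns(UserWarning, match="zero surrogate"):
            z = surrogate_zscore(orig, surr)
        assert z.energy == 0.0

    def test_empty_ensemble_error(self):
        with pytest.raises(ValueError):
            surrogate_zscore(self._const_set(1.0), [])


class TestAssembleFeatures:
    def _zsets(self, n_trials, C, comps, band="delta"):
        rng = np.random.default_rng(0)
        out = {}
        for comp in comps:
            out[(comp, band)] = [
                GraphMetricSet(
                    strength=rng.standard_normal(C),
                    clustering=rng.standard_normal(C),
                    energy=0.1, efficiency=0.2, transitivity=0.3,
                    path_length=0.4, variant="zscored",
                )
                for _ in range(n_trials)
            ]
        return out

    @pytest.mark.parametrize(
        "C,comps,expected",
        [
            (30, ("N100",), 64),
            (30, ("N100", "N200", "P300"), 192),
            (62, ("N100",), 128),
        ],
    )
    def test_feature_counts(self, C, comps, expected):
        zsets = self._zsets(5, C, comps)
        channels = [f"ch{i}" for i in range(C)]
        fm = assemble_features(zsets, comps, "delta", ["A"] * 5, channels)
        assert fm.X.shape == (5, expected)
        assert len(fm.feature_names) == expected
        assert fm.feature_names[0] == "N100__delta__strength__ch0"
        assert fm.feature_names[2 * C + 3].endswith("path_length")

    def test_missing_component_error(self):
        zsets = self._zsets(3, 4, ("N100",))
        with pytest.raises(KeyError, match="P300"):
            assemble_features(zsets, ("N100", "P300"), "delta",
                              ["A"] * 3, [f"c{i}" for i in range(4)])
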