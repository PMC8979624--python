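import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_weighted_matrix
from swpnet.connectivity import AdjacencyStack, consistency_threshold
from swpnet.metrics import (
    SWP_THRESHOLD,
    average_connectivity,
    lattice_equivalent,
    metric_density_curves,
    node_strength,
    random_equivalent,
    sigma_small_worldness,
    small_world_propensity,
    swp_from_deltas,
    weighted_clustering_onnela,
    weighted_path_length,
)
from swpnet.spectral import carrier_frequencies
from swpnet.synth import BackboneSpec, generate_toy_graph

warnings.filterwarnings("ignore", message=".*path-length deviation.*")


# ---------------------------------------------------------------- oracles
def onnela_brute_force(a):
    """Exhaustive triangle enumeration of the Onnela coefficient."""
    n = a.shape[0]
    top = a.max()
    if top == 0:
        return np.zeros(n)
    w = a / top
    cs = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = nbrs.size
        if k < 2:
            continue
        total = 0.0
        for j, h in itertools.combinations(nbrs, 2):
            total += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        cs[i] = 2.0 * total / (k * (k - 1))
    return cs


def floyd_warshall_brute_force(a):
    """All-pairs shortest paths with edge length 1/weight."""
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and a[i, j] > 0:
                dist[i, j] = 1.0 / a[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


# ---------------------------------------------------------------- strength
class TestStrength:
    def test_two_node_graph(self):
        a = np.array([[0.0, 0.7], [0.7, 0.0]])
        np.testing.assert_allclose(node_strength(a), [0.7, 0.7])

    def test_all_zero_graph(self):
        np.testing.assert_allclose(node_strength(np.zeros((4, 4))), 0.0)

    def test_matches_brute_force_columns(self, random_graph6):
        a = random_graph6.weights
        expected = np.array(
            [np.mean([a[i, j] for i in range(6) if i != j]) for j in range(6)]
        )
        np.testing.assert_allclose(node_strength(a), expected, atol=1e-12)

    def test_rejects_single_node(self):
        with pytest.raises(ValueError):
            node_strength(np.zeros((1, 1)))

    def test_average_connectivity_uniform_complete(self):
        w = 0.3
        a = np.full((5, 5), w)
        np.fill_diagonal(a, 0.0)
        assert average_connectivity(a) == pytest.approx(w)

    def test_average_connectivity_identity(self, rng):
        a = random_weighted_matrix(rng, 7)
        n = 7
        expected = a.sum() / (n * (n - 1))
        assert average_connectivity(a) == pytest.approx(expected)

    def test_strength_modes(self, rng):
        a = random_weighted_matrix(rng, 5)
        np.testing.assert_allclose(node_strength(a, mode="sum"), a.sum(axis=0))
        np.testing.assert_allclose(
            node_strength(a, mode="mean_incl_diag"), a.sum(axis=0) / 5
        )


# ---------------------------------------------------------------- clustering
class TestOnnelaClustering:
    def test_equal_weight_triangle(self):
        a = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        c, mean_c = weighted_clustering_onnela(a)
        np.testing.assert_allclose(c, 1.0)
        assert mean_c == pytest.approx(1.0)

    def test_hand_computed_triangle(self, triangle_graph):
        # weights 0.2, 0.4, 0.8 -> normalized {0.25, 0.5, 1}; C = (0.125)^(1/3) = 0.5
        c, _ = weighted_clustering_onnela(triangle_graph.weights)
        np.testing.assert_allclose(c, 0.5)

    def test_tree_has_zero_clustering(self, path3_graph):
        c, mean_c = weighted_clustering_onnela(path3_graph.weights)
        np.testing.assert_allclose(c, 0.0)
        assert mean_c == 0.0

    def test_all_zero_matrix_documented(self):
        c, mean_c = weighted_clustering_onnela(np.zeros((4, 4)))
        np.testing.assert_allclose(c, 0.0)
        assert mean_c == 0.0

    def test_invariant_under_rescaling(self, rng):
        a = random_weighted_matrix(rng, 8)
        c1, _ = weighted_clustering_onnela(a)
        c2, _ = weighted_clustering_onnela(3.7 * a)
        np.testing.assert_allclose(c1, c2, atol=1e-12)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            a = random_weighted_matrix(rng, rng.integers(3, 11))
            c, _ = weighted_clustering_onnela(a)
            np.testing.assert_allclose(c, onnela_brute_force(a), atol=1e-10)


# ---------------------------------------------------------------- paths
class TestPathLength:
    def test_three_node_path(self, path3_graph):
        l_obs, unreachable = weighted_path_length(path3_graph.weights)
        assert l_obs == pytest.approx(4.0 / 3.0)
        assert unreachable == 0.0

    def test_complete_graph_weight_two(self):
        a = np.full((4, 4), 2.0)
        np.fill_diagonal(a, 0.0)
        l_obs, _ = weighted_path_length(a)
        assert l_obs == pytest.approx(0.5)

    def test_matches_floyd_warshall(self, rng):
        for _ in range(20):
            a = random_weighted_matrix(rng, 8)
            if not np.any(a > 0):
                continue
            dist = floyd_warshall_brute_force(a)
            off = ~np.eye(8, dtype=bool)
            finite = np.isfinite(dist[off])
            l_obs, unreachable = weighted_path_length(a)
            assert l_obs == pytest.approx(dist[off][finite].mean(), abs=1e-10)
            assert unreachable == pytest.approx(1.0 - finite.mean())

    def test_edgeless_graph_raises(self):
        with pytest.raises(ValueError, match="no edges"):
            weighted_path_length(np.zeros((3, 3)))


# ---------------------------------------------------------------- null models
class TestLatticeEquivalent:
    def test_weight_multiset_conserved(self, rng):
        a = random_weighted_matrix(rng, 9)
        latt = lattice_equivalent(a)
        iu = np.triu_indices(9, 1)
        np.testing.assert_allclose(
            np.sort(latt[iu][latt[iu] > 0]), np.sort(a[iu][a[iu] > 0])
        )
        assert np.count_nonzero(latt[iu]) == np.count_nonzero(a[iu])

    def test_weight_sorted_ring_is_fixed_point(self):
        # ring lattice whose strongest weights are already the most local
        n = 10
        a = np.zeros((n, n))
        for i in range(n):
            a[i, (i + 1) % n] = a[(i + 1) % n, i] = 2.0
        for i in range(n):
            a[i, (i + 2) % n] = a[(i + 2) % n, i] = 1.0
        latt = lattice_equivalent(a)
        _, c_a = weighted_clustering_onnela(a)
        _, c_l = weighted_clustering_onnela(latt)
        assert c_l == pytest.approx(c_a)

    def test_lattice_clustering_dominates_random(self, rng):
        wins = 0
        for trial in range(100):
            a = random_weighted_matrix(rng, 12, density=24 / 66)
            if not np.any(a > 0):
                continue
            _, c_obs = weighted_clustering_onnela(a)
            _, c_latt = weighted_clustering_onnela(lattice_equivalent(a))
            wins += c_latt >= c_obs
        assert wins >= 95


class TestRandomEquivalent:
    def test_complete_graph_topology_preserved(self, rng):
        n = 6
        a = random_weighted_matrix(rng, n, density=1.1)  # complete
        iu = np.triu_indices(n, 1)
        assert np.all(a[iu] > 0)
        # with a complete graph only the weights can shuffle; L_rand must
        # match a direct permutation oracle distribution
        c_rand, l_rand = random_equivalent(a, seed=3, n_reps=50)
        oracle = []
        rng2 = np.random.default_rng(99)
        for _ in range(200):
            w = np.zeros((n, n))
            w[iu] = rng2.permutation(a[iu])
            w = w + w.T
            oracle.append(weighted_path_length(w)[0])
        assert abs(l_rand - np.mean(oracle)) < 4 * np.std(oracle, ddof=1) / np.sqrt(50)

    def test_reproducible_given_seed(self, rng):
        a = random_weighted_matrix(rng, 8)
        assert random_equivalent(a, seed=5, n_reps=3) == random_equivalent(
            a, seed=5, n_reps=3
        )

    def test_weight_multiset_conserved_every_rep(self, rng):
        # single rep: reconstruct by running with n_reps=1 across seeds
        a = random_weighted_matrix(rng, 7)
        iu = np.triu_indices(7, 1)
        weights = np.sort(a[iu][a[iu] > 0])
        for seed in range(5):
            rng2 = np.random.default_rng(seed)
            pick = rng2.choice(iu[0].size, size=weights.size, replace=False)
            w = rng2.permutation(a[iu][a[iu] > 0])
            np.testing.assert_allclose(np.sort(w), weights)

    def test_rejects_zero_reps(self, rng):
        with pytest.raises(ValueError):
            random_equivalent(random_weighted_matrix(rng, 5), seed=0, n_reps=0)


# ---------------------------------------------------------------- SWP / sigma
class TestSWPFormula:
    def test_ideal_small_world(self):
        swp, _, _ = swp_from_deltas(0.0, 0.0)
        assert swp == 1.0

    def test_maximally_non_small_world(self):
        swp, _, _ = swp_from_deltas(1.0, 1.0)
        assert swp == pytest.approx(0.0)

    def test_pure_lattice(self):
        swp, _, _ = swp_from_deltas(0.0, 1.0)
        assert swp == pytest.approx(1.0 - np.sqrt(0.5))

    @settings(max_examples=200, deadline=None)
    @given(
        st.floats(-5, 5, allow_nan=False), st.floats(-5, 5, allow_nan=False)
    )
    def test_clipping_keeps_swp_in_unit_interval(self, dc, dl):
        swp, dc_c, dl_c = swp_from_deltas(dc, dl)
        assert 0.0 <= swp <= 1.0
        assert 0.0 <= dc_c <= 1.0
        assert 0.0 <= dl_c <= 1.0

    def test_result_consistency(self, rng):
        a = random_weighted_matrix(rng, 12, density=0.4)
        res = small_world_propensity(a, seed=4, n_reps=5)
        assert res.swp == pytest.approx(
            1.0 - np.sqrt(0.5 * (res.delta_c**2 + res.delta_l**2))
        )
        assert 0.0 <= res.swp <= 1.0


class TestSigma:
    def test_watts_strogatz_is_small_world(self):
        sigmas, swps = [], []
        for seed in range(20):
            g = generate_toy_graph(
                BackboneSpec(kind="watts_strogatz", n=100, k=8, p_rewire=0.1,
                             weight_low=1.0, weight_high=1.0),
                seed,
            )
            sigmas.append(sigma_small_worldness(g.weights, seed=seed, n_reps=3))
            swps.append(small_world_propensity(g.weights, seed=seed, n_reps=3).swp)
        assert np.mean(sigmas) > 1.0
        assert np.mean(swps) > SWP_THRESHOLD

    def test_erdos_renyi_sigma_near_one(self):
        sigmas = []
        for seed in range(20):
            g = generate_toy_graph(
                BackboneSpec(kind="erdos_renyi", n=100, k=8,
                             weight_low=1.0, weight_high=1.0),
                seed,
            )
            sigmas.append(sigma_small_worldness(g.weights, seed=seed, n_reps=3))
        assert abs(np.mean(sigmas) - 1.0) < 0.2

    def test_self_null_limit(self, rng):
        # a graph drawn from the random-equivalent null has sigma -> 1
        n, e = 40, 200
        iu, ju = np.triu_indices(n, 1)
        pick = rng.choice(iu.size, size=e, replace=False)
        a = np.zeros((n, n))
        a[iu[pick], ju[pick]] = rng.uniform(0.5, 1.0, size=e)
        a = a + a.T
        sigma = sigma_small_worldness(a, seed=1, n_reps=40)
        assert sigma == pytest.approx(1.0, abs=0.15)


class TestDensityCurves:
    def _toy_stack_and_sweep(self, rng, n_subj=3, n=12):
        w = np.stack(
            [
                np.stack([random_weighted_matrix(rng, n, density=0.9) for _ in range(2)])
                for _ in range(n_subj)
            ]
        )
        stack = AdjacencyStack(weights=w, grid=carrier_frequencies(1, 2, 1))
        sweep = consistency_threshold(stack, np.array([50, 100]))
        return stack, sweep

    def test_full_density_curve_finite(self, rng):
        stack, sweep = self._toy_stack_and_sweep(rng)
        curves = metric_density_curves(sweep, stack, seed=0, n_reps=2)
        assert np.all(np.isfinite(curves.swp[:, :, 1]))

    def test_subject_permutation_permutes_rows(self, rng):
        stack, sweep = self._toy_stack_and_sweep(rng)
        curves = metric_density_curves(sweep, stack, seed=0, n_reps=2)
        perm = [2, 0, 1]
        stack_p = AdjacencyStack(weights=stack.weights[perm], grid=stack.grid)
        curves_p = metric_density_curves(sweep, stack_p, seed=0, n_reps=2)
        # null seeds derive from matrix content, so rows permute exactly
        np.testing.assert_array_equal(curves_p.swp, curves.swp[perm])
        np.testing.assert_array_equal(curves_p.sigma, curves.sigma[perm])

    def test_sigma_decays_with_density_faster_than_swp(self):
        # density-bias property on a Watts-Strogatz family
        g = generate_toy_graph(
            BackboneSpec(kind="watts_strogatz", n=60, k=16, p_rewire=0.1,
                         weight_low=0.5, weight_high=1.0),
            seed=0,
        )
        base = g.weights
        rng = np.random.default_rng(0)
        # embed in noisy subjects so consistency thresholding has work to do
        w = np.stack(
            [np.stack([np.maximum(base + 0.01 * rng.standard_normal(base.shape), 0)])
             for _ in range(3)]
        )
        for s in range(3):
            w[s, 0] = np.triu(w[s, 0], 1) + np.triu(w[s, 0], 1).T
        stack = AdjacencyStack(weights=w, grid=carrier_frequencies(1, 1, 1))
        densities = np.array([40, 100])
        sweep = consistency_threshold(stack, densities)
        curves = metric_density_curves(sweep, stack, seed=0, n_reps=3)
        sigma_lo, sigma_hi = np.nanmean(curves.sigma[:, 0, :], axis=0)
        swp_lo, swp_hi = np.nanmean(curves.swp[:, 0, :], axis=0)
        rel_sigma_drop = (sigma_lo - sigma_hi) / sigma_lo
        rel_swp_change = abs(swp_lo - swp_hi) / swp_lo
        assert rel_sigma_drop > rel_swp_change
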