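import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import hintmaps as hm
from hintmaps.clustering import (
    ClusterSolution, cluster_bin, recover_singletons, weighted_average_map,
    weighted_average_structure, cluster_rmsd, gaussian_weights, bin_sigma,
    apply_solution, summarize_bin,
)
from hintmaps.map_similarity import transform_map
from hintmaps.interaction_maps import CLASSES


@pytest.fixture(scope="module")
def planted_maps():
    maps, labels = hm.build_archetype_maps(4, 25, seed=13, noise=0.5)
    tmaps = [transform_map(m) for m in maps]
    return maps, tmaps, labels


class TestClusterBin:
    def test_small_bin_single_cluster(self):
        maps, _ = hm.build_archetype_maps(3, 1, seed=1, noise=0.0)
        tm = [transform_map(m) for m in maps]
        sol = cluster_bin(tm, "ALA", seed=0)
        assert sol.k_used == 1
        assert np.all(sol.assignments == 0)

    def test_planted_partition_recovery(self, planted_maps):
        """4 archetypes × 25 noisy copies recovered with ARI ≥ 0.95."""
        _, tmaps, labels = planted_maps
        sol = cluster_bin(tmaps, "ALA", seed=11)
        ari = adjusted_rand_score(labels, sol.assignments)
        assert ari >= 0.95

    def test_deterministic_given_seed(self, planted_maps):
        _, tmaps, _ = planted_maps
        a = cluster_bin(tmaps, "ALA", seed=5).assignments
        b = cluster_bin(tmaps, "ALA", seed=5).assignments
        np.testing.assert_array_equal(a, b)

    def test_k_bounded_by_type_maximum(self, planted_maps):
        _, tmaps, _ = planted_maps
        for rtype, kmax in hm.K_MAX.items():
            sol = cluster_bin(tmaps, rtype, seed=0)
            assert sol.k_used <= kmax

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cluster_bin([], "ALA", seed=0)

    def test_exemplar_is_member(self, planted_maps):
        _, tmaps, _ = planted_maps
        sol = cluster_bin(tmaps, "ALA", seed=3)
        for c in range(sol.k_used):
            assert sol.exemplar(c) in sol.members(c)

    def test_exemplar_matches_archetype(self):
        """At modest jitter each cluster's exemplar map is near-identical to
        the archetype it was planted from."""
        from hintmaps.map_similarity import similarity
        maps, _ = hm.build_archetype_maps(4, 25, seed=13, noise=0.1)
        tmaps = [transform_map(m) for m in maps]
        arch = [transform_map(m) for m in hm.build_archetypes_only(4, seed=13)]
        sol = cluster_bin(tmaps, "ALA", seed=11)
        for c in range(sol.k_used):
            ex = sol.exemplar(c)
            best = max(similarity(tmaps[ex], a) for a in arch)
            assert best >= 0.99


class TestSingletonRecovery:
    def _solution_with_outlier(self):
        rng = np.random.default_rng(4)
        cluster_a = rng.normal(0.0, 0.05, (10, 3))
        cluster_b = rng.normal(5.0, 0.05, (10, 3))
        outlier = np.array([[20.0, 20.0, 20.0]])
        features = np.vstack([cluster_a, outlier, cluster_b])
        assignments = np.array([0] * 11 + [1] * 10)
        centroids = np.stack([features[:11].mean(axis=0),
                              features[11:].mean(axis=0)])
        return ClusterSolution(None, assignments, features, centroids, 2)

    def test_outlier_becomes_singleton(self):
        sol = recover_singletons(self._solution_with_outlier(), threshold_sd=2.0)
        assert sol.k_used == 3
        assert np.sum(sol.assignments == sol.assignments[10]) == 1

    def test_no_outliers_identity(self):
        rng = np.random.default_rng(5)
        features = rng.normal(0, 0.1, (12, 3))
        assignments = np.zeros(12, dtype=int)
        sol = ClusterSolution(None, assignments, features,
                              features.mean(axis=0, keepdims=True), 1)
        out = recover_singletons(sol, threshold_sd=6.0)
        np.testing.assert_array_equal(out.assignments, assignments)

    def test_cluster_count_bound(self):
        base = self._solution_with_outlier()
        out = recover_singletons(base, threshold_sd=2.0)
        n_singletons = sum(
            np.sum(out.assignments == c) == 1 for c in range(out.k_used))
        assert out.k_used <= base.k_used + n_singletons


class TestWeightedAverages:
    def test_single_member_identity(self):
        maps, _ = hm.build_archetype_maps(1, 1, seed=2, noise=0.0)
        avg = weighted_average_map(maps, np.array([0.0]), sigma=1.0)
        for c in CLASSES:
            np.testing.assert_allclose(avg.grids[c], maps[0].grids[c])

    def test_weight_formula_at_dmax(self):
        """With σ = d_max/8 the farthest member weighs e^(−64)."""
        d_max = 2.0
        sigma = d_max / 8.0
        w = gaussian_weights(np.array([0.0, d_max]), sigma)
        assert w[0] == 1.0
        assert w[1] == pytest.approx(np.exp(-64.0))

    def test_equal_distances_plain_mean(self):
        maps, _ = hm.build_archetype_maps(2, 1, seed=3, noise=0.0)
        avg = weighted_average_map(maps, np.array([1.3, 1.3]), sigma=0.7)
        for c in CLASSES:
            np.testing.assert_allclose(
                avg.grids[c], 0.5 * (maps[0].grids[c] + maps[1].grids[c]),
                atol=1e-12)

    def test_flat_weights_match_mean_structure(self):
        rng = np.random.default_rng(6)
        coords = [rng.normal(0, 1, (5, 3)) for _ in range(4)]
        avg = weighted_average_structure(coords, np.zeros(4), sigma=1.0)
        np.testing.assert_allclose(avg, np.mean(coords, axis=0), atol=1e-12)


class TestRMSD:
    def test_identical_members_zero(self):
        coords = [np.ones((4, 3))] * 3
        avg = weighted_average_structure(coords, np.zeros(3), 1.0)
        assert cluster_rmsd(coords, avg) == 0.0

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(9)
        coords = [rng.normal(0, 2, (6, 3)) for _ in range(5)]
        avg = rng.normal(0, 2, (6, 3))
        got = cluster_rmsd(coords, avg)
        # independent accumulation loop
        sq, n = 0.0, 0
        for c in coords:
            for i in range(6):
                d = c[i] - avg[i]
                sq += float(d @ d)
                n += 1
        assert got == pytest.approx(np.sqrt(sq / n), rel=1e-12)


class TestSummaries:
    def test_fractions_sum_to_100(self, planted_maps):
        maps, tmaps, _ = planted_maps
        sol = cluster_bin(tmaps, "ALA", seed=11)
        summaries = summarize_bin(sol, raw_maps=maps)
        assert sum(s.relative_fraction for s in summaries) == \
            pytest.approx(100.0, abs=0.1)

    def test_paired_variant_keeps_memberships(self, planted_maps):
        """Applying a solution to a paired map set (mL → mN) preserves the
        memberships and hence the relative fractions."""
        maps, tmaps, _ = planted_maps
        sol = cluster_bin(tmaps, "ALA", seed=11)
        paired = [transform_map(m.scale(0.5)) for m in maps]
        carried = apply_solution(sol, paired)
        np.testing.assert_array_equal(carried.assignments, sol.assignments)
        s0 = summarize_bin(sol, raw_maps=maps)
        s1 = summarize_bin(carried, raw_maps=maps)
        assert [s.n_members for s in s0] == [s.n_members for s in s1]
        assert [s.relative_fraction for s in s0] == \
            [s.relative_fraction for s in s1]
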