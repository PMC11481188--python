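"""Network construction, TOM, module detection, eigengenes, age screening."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cardioage import netmod, preprocess


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop reference implementation of the topological overlap."""
    n = a.shape[0]
    tom = np.eye(n)
    k = [sum(a[i, u] for u in range(n) if u != i) for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def random_grid_adjacency(rng, n):
    vals = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=(n, n))
    a = np.triu(vals, 1)
    a = a + a.T
    np.fill_diagonal(a, 1.0)
    return a


class TestSoftAdjacency:
    def test_perfect_correlation_gives_one(self):
        x = np.linspace(0, 1, 10)
        expr = pd.DataFrame([x, 2 * x + 1, -3 * x])
        adj = netmod.soft_adjacency(expr, power=12)
        np.testing.assert_allclose(adj, 1.0, atol=1e-10)

    def test_power_one_is_absolute_correlation(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(6, 20)))
        adj = netmod.soft_adjacency(expr, power=1)
        corr = np.abs(np.corrcoef(expr.to_numpy()))
        np.testing.assert_allclose(adj, corr, atol=1e-12)

    def test_power_attenuates_moderate_correlation(self):
        # |r|^12 for r = 0.5 is ~2.4e-4
        assert 0.5**12 == pytest.approx(0.000244, abs=1e-6)
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(5, 30)))
        a1 = netmod.soft_adjacency(expr, power=1)
        a12 = netmod.soft_adjacency(expr, power=12)
        off = ~np.eye(5, dtype=bool)
        assert (a12[off] <= a1[off] + 1e-12).all()

    def test_constant_row_yields_zero_adjacency(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning):
            adj = netmod.soft_adjacency(expr, power=6)
        assert adj[0, 1] == 0.0 and adj[1, 0] == 0.0
        assert adj[0, 0] == 1.0


class TestTopologicalOverlap:
    def test_identity_adjacency_maps_to_identity(self):
        np.testing.assert_allclose(netmod.topological_overlap(np.eye(5)), np.eye(5))

    def test_saturated_graph_gives_unit_overlap(self):
        a = np.ones((3, 3))
        np.testing.assert_allclose(netmod.topological_overlap(a), 1.0)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = rng.integers(2, 7)
            a = random_grid_adjacency(rng, n)
            tom = netmod.topological_overlap(a)
            np.testing.assert_allclose(tom, brute_force_tom(a), atol=1e-12)
            assert np.allclose(tom, tom.T)
            assert (tom >= 0).all() and (tom <= 1 + 1e-12).all()

    def test_asymmetric_input_rejected(self):
        a = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError):
            netmod.topological_overlap(a)


def planted_blocks(rng, sizes, n_samples=40, within=0.9):
    rows = []
    for size in sizes:
        shared = rng.normal(size=n_samples)
        lam = np.sqrt(within)
        for _ in range(size):
            noise = rng.normal(size=n_samples)
            rows.append(lam * shared + np.sqrt(1 - lam**2) * noise)
    return pd.DataFrame(rows)


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(2)
        expr = planted_blocks(rng, [40, 40])
        scaled = preprocess.scale_per_transcript(expr)
        tom = netmod.topological_overlap(netmod.soft_adjacency(scaled))
        labels = netmod.detect_modules(tom, min_module_size=30)
        truth = [0] * 40 + [1] * 40
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_small_cluster_left_unassigned(self):
        rng = np.random.default_rng(3)
        expr = planted_blocks(rng, [10])
        scaled = preprocess.scale_per_transcript(expr)
        tom = netmod.topological_overlap(netmod.soft_adjacency(scaled))
        with pytest.warns(UserWarning):
            labels = netmod.detect_modules(tom, min_module_size=30)
        assert (labels == netmod.UNASSIGNED).all()

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(4)
        expr = planted_blocks(rng, [35, 35])
        scaled = preprocess.scale_per_transcript(expr)
        tom = netmod.topological_overlap(netmod.soft_adjacency(scaled))
        labels = netmod.detect_modules(tom, min_module_size=30)
        perm = rng.permutation(70)
        tom_p = tom[np.ix_(perm, perm)]
        labels_p = netmod.detect_modules(tom_p, min_module_size=30)
        assert adjusted_rand_score(labels.to_numpy()[perm], labels_p) == 1.0


class TestModuleEigengene:
    def test_identical_rows_recover_common_profile(self):
        profile = np.array([0.0, 1.0, 4.0, 2.0, -1.0, 3.0])
        expr = preprocess.scale_per_transcript(pd.DataFrame([profile] * 5))
        eig = netmod.module_eigengene(expr, np.ones(5, dtype=bool))
        scaled_profile = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(eig, scaled_profile, atol=1e-10)

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(5)
        expr = preprocess.scale_per_transcript(pd.DataFrame(rng.normal(size=(6, 12))))
        mask = np.ones(6, dtype=bool)
        eig = netmod.module_eigengene(expr, mask)
        eig_flipped = netmod.module_eigengene(-expr, mask)
        np.testing.assert_allclose(eig_flipped, -eig, atol=1e-10)

    def test_explains_at_least_any_single_member(self):
        rng = np.random.default_rng(6)
        expr = preprocess.scale_per_transcript(pd.DataFrame(rng.normal(size=(8, 15))))
        x = expr.to_numpy()
        eig = netmod.module_eigengene(expr, np.ones(8, dtype=bool))

        def explained(v):
            vn = (v - v.mean()) / v.std()
            return sum(np.corrcoef(vn, row)[0, 1] ** 2 for row in x)

        best_member = max(explained(row) for row in x)
        assert explained(eig) >= best_member - 1e-8

    def test_singular_module_rejected(self):
        expr = pd.DataFrame(np.zeros((3, 5)))
        with pytest.raises(ValueError):
            netmod.module_eigengene(expr, np.ones(3, dtype=bool))


class TestMergeCloseModules:
    def _expr_with_modules(self, r_between, rng):
        n = 30
        base = rng.normal(size=n)
        lam = r_between
        other = lam * base + np.sqrt(1 - lam**2) * rng.normal(size=n)
        rows = [base + 0.05 * rng.normal(size=n) for _ in range(10)]
        rows += [other + 0.05 * rng.normal(size=n) for _ in range(10)]
        expr = preprocess.scale_per_transcript(pd.DataFrame(rows))
        labels = pd.Series([1] * 10 + [2] * 10, name="module_id")
        return expr, labels

    def test_similar_eigengenes_merge(self):
        expr, labels = self._expr_with_modules(0.95, np.random.default_rng(7))
        merged = netmod.merge_close_modules(expr, labels, merge_threshold=0.25)
        assert merged.nunique() == 1

    def test_distinct_eigengenes_stay_separate(self):
        expr, labels = self._expr_with_modules(0.5, np.random.default_rng(8))
        merged = netmod.merge_close_modules(expr, labels, merge_threshold=0.25)
        assert merged.nunique() == 2

    def test_merge_result_independent_of_label_permutation(self):
        rng = np.random.default_rng(9)
        n = 40
        a = rng.normal(size=n)
        b = 0.95 * a + np.sqrt(1 - 0.95**2) * rng.normal(size=n)
        c = rng.normal(size=n)
        rows = (
            [a + 0.05 * rng.normal(size=n) for _ in range(8)]
            + [b + 0.05 * rng.normal(size=n) for _ in range(8)]
            + [c + 0.05 * rng.normal(size=n) for _ in range(8)]
        )
        expr = preprocess.scale_per_transcript(pd.DataFrame(rows))
        base_labels = [1] * 8 + [2] * 8 + [3] * 8
        results = []
        for perm in [(1, 2, 3), (3, 1, 2), (2, 3, 1)]:
            labels = pd.Series([perm[m - 1] for m in base_labels], name="module_id")
            merged = netmod.merge_close_modules(expr, labels, merge_threshold=0.25)
            results.append(merged.to_numpy())
        for r in results[1:]:
            assert adjusted_rand_score(results[0], r) == 1.0


class TestAgeCorrelation:
    def test_eigengene_equal_to_age_is_significant(self):
        ages = np.linspace(8, 22, 20)
        eig = pd.DataFrame({1: (ages - ages.mean()) / ages.std()})
        stats = netmod.correlate_modules_with_age(eig, ages)
        assert stats.loc[1, "pearson_r"] == pytest.approx(1.0)
        assert bool(stats.loc[1, "significant"])

    def test_orthogonal_eigengene_not_significant(self):
        ages = np.linspace(8, 22, 20)
        centered = ages - ages.mean()
        perp = np.sin(np.arange(20) * 2.0)
        perp = perp - perp.mean()
        perp -= centered * (perp @ centered) / (centered @ centered)
        stats = netmod.correlate_modules_with_age(pd.DataFrame({1: perp}), ages)
        assert abs(stats.loc[1, "pearson_r"]) < 1e-10
        assert not bool(stats.loc[1, "significant"])

    def test_correlation_below_threshold_fails_even_if_p_small(self):
        # construct an eigengene with |r| = 0.29 exactly at large n -> tiny p
        rng = np.random.default_rng(10)
        n = 500
        ages = np.linspace(8, 22, n)
        z_age = (ages - ages.mean()) / ages.std()
        noise = rng.normal(size=n)
        noise = noise - noise.mean()
        noise -= z_age * (noise @ z_age) / (z_age @ z_age)
        noise /= noise.std()
        r = 0.29
        eig = r * z_age + np.sqrt(1 - r**2) * noise
        stats = netmod.correlate_modules_with_age(pd.DataFrame({1: eig}), ages)
        assert stats.loc[1, "pearson_r"] == pytest.approx(0.29, abs=1e-10)
        assert stats.loc[1, "p_value"] < 1e-6
        assert not bool(stats.loc[1, "significant"])

    def test_zero_variance_eigengene_flagged(self):
        ages = np.linspace(8, 22, 10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stats = netmod.correlate_modules_with_age(
                pd.DataFrame({1: np.zeros(10)}), ages
            )
        assert not bool(stats.loc[1, "significant"])
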