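"""Group statistics: TCC, component matching, cluster permutation test,
REC-period stability, repeated-measures ANOVA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from arcomp import (
    cluster_permutation_test,
    find_clusters,
    match_components,
    rec_period_stability,
    repeated_measures_anova,
    replicability_report,
    tucker_congruence,
)
from arcomp.simulate import simulate_tensor
from arcomp.parafac import parafac_als


positive_vectors = hnp.arrays(
    dtype=float,
    shape=st.integers(2, 30),
    elements=st.floats(0.01, 100.0, allow_nan=False, allow_infinity=False),
)


class TestTuckerCongruence:
    def test_self_congruence_is_one(self):
        assert tucker_congruence(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0])) == 1.0

    def test_hand_example_10_over_14(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([3.0, 2.0, 1.0])
        assert tucker_congruence(x, y) == pytest.approx(10.0 / 14.0)

    def test_orthogonal_vectors_zero(self):
        assert tucker_congruence(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            tucker_congruence(np.zeros(3), np.ones(3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            tucker_congruence(np.ones(3), np.ones(4))

    @settings(max_examples=50, deadline=None)
    @given(positive_vectors, st.floats(0.01, 50.0), st.floats(0.01, 50.0))
    def test_scale_invariance(self, x, a, b):
        y = np.flip(x) + 0.5
        assert tucker_congruence(a * x, b * y) == pytest.approx(
            tucker_congruence(x, y), abs=1e-9
        )

    @settings(max_examples=50, deadline=None)
    @given(positive_vectors)
    def test_symmetry_and_range(self, x):
        y = np.sqrt(x) + 0.1
        t1 = tucker_congruence(x, y)
        t2 = tucker_congruence(y, x)
        assert t1 == pytest.approx(t2, abs=1e-12)
        assert 0.0 <= t1 <= 1.0 + 1e-12


class TestMatchComponents:
    def test_resolves_permutation(self, rng):
        ref = rng.uniform(0.1, 1.0, size=(20, 3))
        est = ref[:, [2, 0, 1]] * np.array([0.5, 2.0, 1.3])
        perm, cong = match_components(ref, est)
        np.testing.assert_array_equal(perm, [1, 2, 0])
        np.testing.assert_allclose(cong, 1.0, atol=1e-12)

    def test_extra_estimated_components_allowed(self, rng):
        ref = rng.uniform(0.1, 1.0, size=(15, 2))
        est = np.column_stack([rng.uniform(0.1, 1.0, size=15), ref[:, 1], ref[:, 0]])
        perm, cong = match_components(ref, est)
        assert perm[0] == 2 and perm[1] == 1

    def test_too_few_estimates_rejected(self, rng):
        with pytest.raises(ValueError, match="fewer"):
            match_components(rng.random((10, 3)), rng.random((10, 2)))


class TestFindClusters:
    def chain_neighbors(self, n):
        return [
            np.array([j for j in (i - 1, i + 1) if 0 <= j < n]) for i in range(n)
        ]

    def test_two_separate_clusters_on_a_chain(self):
        vals = np.array([1.0, 5.0, 5.0, 0.0, 7.0, 0.0, 0.0])
        clusters = find_clusters(vals, 2.0, self.chain_neighbors(7))
        assert [c.tolist() for c in clusters] == [[1, 2], [4]]

    def test_empty_when_nothing_suprathreshold(self):
        vals = np.zeros(5)
        assert find_clusters(vals, 1.0, self.chain_neighbors(5)) == []

    def test_matches_scipy_connected_components_oracle(self, leadfield_small, rng):
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        grid = leadfield_small.grid
        vals = rng.standard_normal(grid.n_sources)
        thr = 0.3
        clusters = find_clusters(vals, thr, grid.neighbor_lists())
        supra = np.nonzero(vals > thr)[0]
        pairs = [
            (i, j)
            for i, j in grid.adjacency_pairs
            if vals[i] > thr and vals[j] > thr
        ]
        n_s = len(supra)
        remap = {s: k for k, s in enumerate(supra)}
        rows = [remap[i] for i, j in pairs] + [remap[j] for i, j in pairs]
        cols = [remap[j] for i, j in pairs] + [remap[i] for i, j in pairs]
        adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n_s, n_s))
        n_comp, labels = connected_components(adj, directed=False)
        assert len(clusters) == n_comp
        oracle = sorted(
            sorted(supra[k] for k in range(n_s) if labels[k] == c)
            for c in range(n_comp)
        )
        assert sorted(c.tolist() for c in clusters) == oracle


class TestClusterPermutationTest:
    def test_identical_loadings_give_no_clusters(self, leadfield_small, rng):
        load = rng.uniform(0.0, 1.0, size=(10, leadfield_small.grid.n_sources))
        res = cluster_permutation_test(load, load.copy(), leadfield_small.grid, n_perm=100, seed=0)
        assert len(res) == 2
        assert all(len(r.clusters) == 0 for r in res)

    def test_planted_difference_detected_with_correct_location(self, leadfield_small, rng):
        """A patch of elevated loading in condition A is found as a
        significant cluster overlapping the planted sources."""
        grid = leadfield_small.grid
        n_subj = 16
        base = rng.uniform(0.2, 0.4, size=(n_subj, grid.n_sources))
        loadB = base + 0.02 * rng.standard_normal(base.shape)
        loadA = base + 0.02 * rng.standard_normal(base.shape)
        center = grid.coords[0]
        d = np.linalg.norm(grid.coords - center, axis=1)
        patch = d < 2.2 * grid.r_adj
        loadA[:, patch] += 0.15
        res_ab, res_ba = cluster_permutation_test(
            loadA, loadB, grid, n_perm=500, seed=1
        )
        assert len(res_ab.clusters) >= 1
        assert res_ab.p_values[0] < 0.05
        found = set(res_ab.clusters[0].tolist())
        planted = set(np.nonzero(patch)[0].tolist())
        jaccard = len(found & planted) / len(found | planted)
        assert jaccard > 0.5
        # and the reverse contrast finds nothing significant
        assert not any(res_ba.p_values < 0.05)

    def test_seeded_determinism(self, leadfield_small, rng):
        grid = leadfield_small.grid
        a = rng.uniform(0.0, 1.0, size=(8, grid.n_sources))
        b = rng.uniform(0.0, 1.0, size=(8, grid.n_sources))
        r1 = cluster_permutation_test(a, b, grid, n_perm=200, seed=7)
        r2 = cluster_permutation_test(a, b, grid, n_perm=200, seed=7)
        for x, y in zip(r1, r2):
            np.testing.assert_array_equal(x.p_values, y.p_values)
            np.testing.assert_array_equal(x.t_map, y.t_map)

    def test_summary_and_validation(self, leadfield_small, rng):
        grid = leadfield_small.grid
        a = rng.uniform(0.0, 1.0, size=(8, grid.n_sources))
        b = rng.uniform(0.0, 1.0, size=(8, grid.n_sources))
        res = cluster_permutation_test(a, b, grid, n_perm=50, seed=0)
        assert "Cluster permutation test" in res[0].summary()
        with pytest.raises(ValueError, match="shape"):
            cluster_permutation_test(a, b[:, :-1], grid, n_perm=10)
        with pytest.raises(ValueError, match="3 subjects"):
            cluster_permutation_test(a[:2], b[:2], grid, n_perm=10)


class TestRecPeriodStability:
    def test_period_means_recovered(self):
        """Temporal loadings with known per-period levels are averaged
        back exactly."""
        tensor, gt = simulate_tensor(1, (6, 8, 12), 0.0, seed=0)
        res = parafac_als(tensor.values, 1, n_starts=2, seed=0)
        res.model.window_centers = np.arange(12) * 100 + 50
        table = rec_period_stability(res, boundaries=np.array([400, 800]))
        assert list(table.index) == ["REC1", "REC2", "REC3"]
        Cn = res.C[:, 0] / res.C[:, 0].max()
        np.testing.assert_allclose(table["component1"].to_numpy()[0], Cn[:4].mean())

    def test_empty_period_rejected(self):
        tensor, _ = simulate_tensor(1, (6, 8, 5), 0.0, seed=0)
        res = parafac_als(tensor.values, 1, n_starts=2, seed=0)
        res.model.window_centers = np.arange(5) * 100 + 550
        with pytest.raises(ValueError, match="no analysis windows"):
            rec_period_stability(res, boundaries=np.array([200, 400]))


class TestRepeatedMeasuresAnova:
    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.anova import AnovaRM
        import pandas as pd

        n, c = 12, 4
        data = rng.standard_normal((n, c)) + np.array([0.0, 0.2, 0.1, 0.4])
        F, p = repeated_measures_anova(data)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), c),
                "condition": np.tile(np.arange(c), n),
                "value": data.ravel(),
            }
        )
        fitted = AnovaRM(long, "value", "subject", within=["condition"]).fit()
        assert F == pytest.approx(float(fitted.anova_table["F Value"].iloc[0]), rel=1e-10)
        assert p == pytest.approx(float(fitted.anova_table["Pr > F"].iloc[0]), rel=1e-10)

    def test_constant_conditions_give_F_zero(self, rng):
        subj = rng.standard_normal(10)
        data = np.tile(subj[:, None], (1, 3))
        F, p = repeated_measures_anova(data)
        assert F == 0.0 and p == 1.0

    def test_validation(self):
        with pytest.raises(ValueError):
            repeated_measures_anova(np.ones((1, 3)))


class TestReplicabilityReport:
    def test_two_seeded_realizations_highly_similar(self):
        """Two noisy realizations of the same trilinear truth yield
        matched components with TCC above 0.85 in every mode."""
        rng = np.random.default_rng(0)
        true = [rng.uniform(0.1, 1.0, size=(d, 2)) for d in (20, 15, 30)]
        X0 = np.einsum("ir,jr,kr->ijk", *true)
        res = []
        for seed in (1, 2):
            r2 = np.random.default_rng(seed)
            X = np.clip(X0 + 0.03 * X0.mean() * r2.standard_normal(X0.shape), 0, None)
            res.append(parafac_als(X, 2, n_starts=4, seed=seed))
        report = replicability_report(res[0], res[1], modes=("frequency", "space", "time"))
        assert len(report) == 6
        assert report["highly_similar"].all()
        assert (report["tcc"] > 0.95).all()
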