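"""Non-negative PARAFAC, core consistency, model-order selection."""

import numpy as np
import pytest

from arcomp import Parafac, corcondia, parafac_als, select_num_components
from arcomp.stats import tucker_congruence


def random_factors(rng, shape, K):
    return [rng.uniform(0.2, 1.0, size=(d, K)) for d in shape]


def build_tensor(factors):
    return np.einsum("ir,jr,kr->ijk", *factors)


def best_match_congruences(est, true):
    """Congruence of each true column with its best-matching estimate."""
    out = []
    for k in range(true.shape[1]):
        out.append(
            max(tucker_congruence(true[:, k], est[:, j]) for j in range(est.shape[1]))
        )
    return np.array(out)


class TestFitRecovery:
    def test_noiseless_rank2_recovery(self, rng):
        true = random_factors(rng, (20, 15, 30), 2)
        X = build_tensor(true)
        res = parafac_als(X, 2, n_starts=5, seed=0, tol=1e-13, max_iter=20000)
        assert res.fit > 1 - 1e-9
        for mode in range(3):
            cc = best_match_congruences(res.factors[mode], true[mode])
            assert cc.min() > 0.999

    def test_rank1_all_ones(self):
        X = np.ones((4, 5, 6))
        res = parafac_als(X, 1, n_starts=2, seed=0)
        assert res.fit == pytest.approx(1.0, abs=1e-10)
        # rank-1 loading columns are constant up to scale
        for f in res.factors:
            assert f[:, 0].std() < 1e-8 * f[:, 0].mean()

    def test_fit_history_monotone_nondecreasing(self, rng):
        X = build_tensor(random_factors(rng, (10, 8, 12), 3))
        X += 0.05 * X.mean() * rng.random(X.shape)
        res = parafac_als(X, 3, n_starts=3, seed=1)
        assert np.all(np.diff(res.fit_history) >= -1e-12)

    def test_factors_nonnegative(self, rng):
        X = build_tensor(random_factors(rng, (10, 8, 12), 2))
        res = parafac_als(X, 2, n_starts=3, seed=2)
        for f in res.factors:
            assert f.min() >= 0

    def test_reconstruction_error_matches_injected_noise(self, rng):
        """With additive noise the residual norm approaches the noise
        norm (the model cannot explain isotropic noise)."""
        true = random_factors(rng, (15, 12, 40), 2)
        X0 = build_tensor(true)
        noise = 0.02 * X0.mean() * rng.standard_normal(X0.shape)
        X = np.clip(X0 + noise, 0, None)
        res = parafac_als(X, 2, n_starts=4, seed=3)
        assert res.residual_norm == pytest.approx(np.linalg.norm(noise), rel=0.1)

    def test_free_mode_normalization(self, rng):
        """Free non-primary modes are scaled to unit maximum; scale sits
        in the first free mode. Reconstruction is unaffected."""
        true = random_factors(rng, (9, 7, 11), 2)
        X = build_tensor(true)
        res = parafac_als(X, 2, n_starts=3, seed=4, tol=1e-13, max_iter=20000)
        np.testing.assert_allclose(res.B.max(axis=0), 1.0, rtol=1e-9)
        np.testing.assert_allclose(res.C.max(axis=0), 1.0, rtol=1e-9)
        # normalization must not change the model tensor: its residual
        # against the data equals the reported residual norm
        rec = res.reconstruct()
        assert np.linalg.norm(X - rec) == pytest.approx(res.residual_norm, rel=1e-3, abs=1e-9)
        np.testing.assert_allclose(rec, X, rtol=1e-3, atol=1e-6 * X.max())

    def test_seeded_determinism(self, rng):
        X = build_tensor(random_factors(rng, (10, 8, 12), 2))
        r1 = parafac_als(X, 2, n_starts=3, seed=42)
        r2 = parafac_als(X, 2, n_starts=3, seed=42)
        for f1, f2 in zip(r1.factors, r2.factors):
            np.testing.assert_array_equal(f1, f2)


class TestFixedModes:
    def test_fixed_modes_returned_bit_identical(self, rng):
        true = random_factors(rng, (12, 9, 14), 2)
        X = build_tensor(true)
        res = parafac_als(X, 2, fixed={0: true[0], 2: true[2]}, n_starts=2, seed=5)
        assert res.factors[0] is not true[0]  # defensive copy allowed, values exact
        np.testing.assert_array_equal(res.A, true[0])
        np.testing.assert_array_equal(res.C, true[2])
        assert res.fixed_modes == ("frequency", "time")

    def test_fixed_fit_recovers_free_mode(self, rng):
        true = random_factors(rng, (12, 9, 14), 2)
        X = build_tensor(true)
        res = parafac_als(
            X,
            2,
            fixed={"frequency": true[0], "time": true[2]},
            n_starts=2,
            seed=6,
            tol=1e-13,
            max_iter=20000,
        )
        assert res.fit > 1 - 1e-9
        cc = best_match_congruences(res.B, true[1])
        assert cc.min() > 0.9999

    def test_all_modes_fixed_rejected(self, rng):
        true = random_factors(rng, (5, 5, 5), 1)
        with pytest.raises(ValueError, match="free"):
            Parafac(build_tensor(true), 1, fixed={0: true[0], 1: true[1], 2: true[2]})

    def test_wrong_shape_fixed_rejected(self, rng):
        X = np.ones((5, 6, 7))
        with pytest.raises(ValueError, match="shape"):
            Parafac(X, 2, fixed={0: np.ones((6, 2))})

    def test_negative_fixed_rejected(self):
        X = np.ones((5, 6, 7))
        with pytest.raises(ValueError, match="non-negative"):
            Parafac(X, 1, fixed={0: -np.ones((5, 1))})


class TestValidation:
    def test_non_3way_rejected(self):
        with pytest.raises(ValueError, match="3-way"):
            Parafac(np.ones((4, 4)), 1)

    def test_substantially_negative_tensor_rejected(self):
        X = np.ones((4, 4, 4))
        X[0, 0, 0] = -2.0
        with pytest.raises(ValueError, match="negative"):
            Parafac(X, 1)

    def test_small_negative_tolerated(self):
        X = np.ones((4, 4, 4))
        X[0, 0, 0] = -0.01
        Parafac(X, 1)  # no error

    def test_bad_rank_rejected(self):
        with pytest.raises(ValueError):
            Parafac(np.ones((4, 4, 4)), 0)


class TestCorcondia:
    def test_exact_model_scores_100(self, rng):
        true = random_factors(rng, (10, 9, 11), 2)
        res = parafac_als(build_tensor(true), 2, n_starts=4, seed=7, tol=1e-13, max_iter=20000)
        assert res.corcondia == pytest.approx(100.0, abs=1e-4)

    def test_K1_is_100_by_convention(self, rng):
        X = rng.random((6, 7, 8))
        res = parafac_als(X, 1, n_starts=2, seed=8)
        assert res.corcondia == 100.0

    def test_overfactored_model_scores_low(self, rng):
        """Fitting K=3 to noisy rank-2 data drops the diagnostic well
        below the 90% acceptance band."""
        true = random_factors(rng, (15, 12, 30), 2)
        X0 = build_tensor(true)
        X = np.clip(X0 + 0.05 * X0.mean() * rng.standard_normal(X0.shape), 0, None)
        res = parafac_als(X, 3, n_starts=4, seed=9)
        assert res.corcondia < 90.0

    def test_matches_dense_normal_equations_oracle(self, rng):
        """Core from Kronecker-factored pseudo-inverses equals the core
        from the explicit vectorized least-squares problem."""
        true = random_factors(rng, (6, 5, 7), 2)
        X0 = build_tensor(true)
        X = X0 + 0.1 * X0.mean() * rng.random(X0.shape)
        res = parafac_als(X0, 2, n_starts=2, seed=10)
        A, B, C = res.factors
        Z = np.einsum("ai,bj,ck->abcijk", A, B, C).reshape(X.size, 8)
        g, *_ = np.linalg.lstsq(Z, X.ravel(), rcond=None)
        G = g.reshape(2, 2, 2)
        T = np.zeros((2, 2, 2))
        T[[0, 1], [0, 1], [0, 1]] = 1.0
        oracle = 100.0 * (1.0 - np.sum((G - T) ** 2) / 2.0)
        assert corcondia(X, res) == pytest.approx(oracle, abs=1e-8)

    def test_shape_mismatch_rejected(self, rng):
        true = random_factors(rng, (6, 5, 7), 2)
        res = parafac_als(build_tensor(true), 2, n_starts=2, seed=11)
        with pytest.raises(ValueError, match="shape"):
            corcondia(np.ones((3, 3, 3)), res)


class TestModelOrderSelection:
    def test_selects_two_on_rank2_data(self, rng):
        true = random_factors(rng, (15, 12, 30), 2)
        X0 = build_tensor(true)
        X = np.clip(X0 + 0.03 * X0.mean() * rng.standard_normal(X0.shape), 0, None)
        K, table = select_num_components(X, K_max=4, n_starts=4, seed=12)
        assert K == 2
        assert table.loc[2, "corcondia"] >= 90.0
        assert set(table.columns) >= {"fit", "corcondia", "converged", "degenerate"}

    def test_selects_one_on_rank1_data(self, rng):
        """Noisy rank-1 data: K >= 2 drops below the consistency band and
        K=1 (100% by convention) is chosen."""
        true = random_factors(rng, (10, 10, 10), 1)
        X0 = build_tensor(true)
        X = np.clip(X0 + 0.15 * X0.mean() * rng.standard_normal(X0.shape), 0, None)
        K, table = select_num_components(X, K_max=3, n_starts=3, seed=13)
        assert K == 1
        assert (table.loc[2:, "corcondia"] < 90.0).all()

    def test_return_models_consistent_with_table(self, rng):
        true = random_factors(rng, (12, 10, 20), 2)
        X = build_tensor(true)
        K, table, models = select_num_components(
            X, K_max=3, n_starts=3, seed=14, return_models=True
        )
        assert set(models) == {1, 2, 3}
        for k, res in models.items():
            assert res.K == k
            assert table.loc[k, "fit"] == res.fit


class TestResultsObject:
    def test_subset_and_summary(self, rng):
        true = random_factors(rng, (8, 7, 9), 3)
        res = parafac_als(build_tensor(true), 3, n_starts=3, seed=15)
        sub = res.subset([0, 2])
        assert sub.K == 2
        np.testing.assert_array_equal(sub.A, res.A[:, [0, 2]])
        text = res.summary()
        assert "explained variation" in text and "core consistency" in text

    def test_spectral_tensor_input_axes_and_peaks(self, rng):
        """SpectralTensor input is rearranged so A is the frequency mode."""
        from arcomp import SpectralTensor

        freqs = np.linspace(5, 15, 21)
        a = np.exp(-0.5 * ((freqs - 10.0) / 0.7) ** 2)[:, None]
        b = rng.uniform(0.2, 1.0, size=(6, 1))
        c = rng.uniform(0.2, 1.0, size=(11, 1))
        vals = np.einsum("ir,jr,kr->jik", a, b, c)  # space x freq x time
        st = SpectralTensor(
            values=vals,
            freqs=freqs,
            window_centers=np.arange(11.0),
            space_kind="channel",
            units="a.u.",
        )
        res = parafac_als(st, 1, n_starts=2, seed=16)
        assert res.A.shape == (21, 1)
        assert res.peak_frequencies()[0] == pytest.approx(10.0)
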