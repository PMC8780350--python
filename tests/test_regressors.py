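"""Regressor contracts against independent oracles: normal-equations
least squares for full-rank PLS, hand-computed distances and weights for
LW-PLS, and the dense closed-form posterior for the GP."""

import numpy as np
import pytest

from ppgbp.errors import (
    DegenerateComponentError,
    InvalidArgumentError,
    InvalidCovarianceError,
)
from ppgbp.regressors import (
    GPRModel,
    LWPLSQuery,
    gpr_fit,
    gpr_predict,
    load_model,
    lwpls_predict,
    mahalanobis_distance,
    pls_fit,
    pls_predict,
    r2_cv,
    save_model,
    similarity_weights,
)


def ols_predict(Xtr, ytr, Xq):
    A = np.column_stack([np.ones(len(ytr)), Xtr])
    beta = np.linalg.lstsq(A, ytr, rcond=None)[0]
    return np.column_stack([np.ones(len(Xq)), Xq]) @ beta


class TestPLS:
    def test_collinear_univariate_exact_fit(self):
        X = np.array([[1.0], [2.0], [3.0]])
        y = np.array([2.0, 4.0, 6.0])
        m = pls_fit(X, y, D=1)
        np.testing.assert_allclose(pls_predict(m, X), y, atol=1e-12)
        assert m.q[0] == pytest.approx(1.0)  # standardized slope
        assert pls_predict(m, np.array([4.0])) == pytest.approx(8.0)

    def test_full_rank_matches_least_squares(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + rng.normal(size=50)
        m = pls_fit(X, y, D=4)
        Xq = rng.normal(size=(20, 4))
        np.testing.assert_allclose(
            pls_predict(m, Xq), ols_predict(X, y, Xq), atol=1e-8
        )

    def test_prediction_at_training_mean_is_target_mean(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        m = pls_fit(X, y, D=2)
        assert pls_predict(m, X.mean(axis=0)) == pytest.approx(y.mean(), abs=1e-10)

    def test_orthogonal_target_degenerates(self):
        X = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])  # zero covariance with X
        with pytest.raises(DegenerateComponentError):
            pls_fit(X, y, D=1)

    def test_score_orthogonality_over_random_problems(self):
        """Successive deflated score vectors must stay pairwise orthogonal."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(25, 5))
            y = rng.normal(size=25)
            m = pls_fit(X, y, D=4)
            Z = (X - m.x_center) / m.x_scale
            T = np.empty((25, 4))
            for i in range(4):
                t = Z @ m.W[:, i]
                T[:, i] = t
                Z = Z - np.outer(t, m.Pload[:, i])
            G = T.T @ T
            norms = np.sqrt(np.diag(G))
            off = G / np.outer(norms, norms) - np.eye(4)
            assert np.max(np.abs(off)) < 1e-8

    def test_affine_input_rescaling_invariance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(40, 4))
        y = rng.normal(size=40)
        scale = np.array([10.0, 0.01, 3.0, 100.0])
        shift = np.array([5.0, -2.0, 0.0, 40.0])
        m1 = pls_fit(X, y, D=2)
        m2 = pls_fit(X * scale + shift, y, D=2)
        Xq = rng.normal(size=(10, 4))
        np.testing.assert_allclose(
            pls_predict(m2, Xq * scale + shift), pls_predict(m1, Xq), atol=1e-8
        )


class TestR2CV:
    def test_noiseless_linear_map_approaches_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 3))
        y = X @ np.array([1.0, 2.0, -1.0])
        scores = r2_cv(X, y, D_candidates=(1, 2, 3), folds=5, seed=1)
        assert scores[3] > 0.999

    def test_pure_noise_scores_at_most_zero_on_average(self):
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(40, 3))
            y = rng.normal(size=40)
            vals.append(r2_cv(X, y, D_candidates=(2,), folds=5, seed=seed)[2])
        assert np.mean(vals) < 0.05

    def test_constant_target_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        with pytest.raises(InvalidArgumentError):
            r2_cv(X, np.ones(20))

    def test_too_few_folds_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        with pytest.raises(InvalidArgumentError):
            r2_cv(X, X[:, 0], folds=1)


class TestMahalanobis:
    def test_zero_for_identical_points(self):
        S = np.eye(3)
        assert mahalanobis_distance(np.ones(3), np.ones(3), S) == 0.0

    def test_reduces_to_euclidean_under_identity(self):
        assert mahalanobis_distance(
            np.array([0.0, 0.0]), np.array([3.0, 4.0]), np.eye(2)
        ) == pytest.approx(5.0)

    def test_diagonal_covariance_scales_axes(self):
        S = np.diag([4.0, 1.0])
        d = mahalanobis_distance(np.array([2.0, 1.0]), np.array([0.0, 0.0]), S)
        assert d == pytest.approx(np.sqrt(2.0))

    def test_asymmetric_covariance_rejected(self):
        S = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(InvalidArgumentError):
            mahalanobis_distance(np.zeros(2), np.ones(2), S)

    def test_indefinite_covariance_rejected(self):
        S = np.array([[1.0, 0.0], [0.0, -0.5]])
        with pytest.raises(InvalidCovarianceError):
            mahalanobis_distance(np.zeros(2), np.ones(2), S)


class TestSimilarityWeights:
    def setup_method(self):
        self.Xt = np.array(
            [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [2.0, 2.0], [-1.0, 1.0]]
        )
        self.S = np.eye(2)

    def test_coincident_row_gets_weight_one(self):
        u = similarity_weights(self.Xt, self.Xt[1], self.S, phi=1.0)
        assert u[1] == pytest.approx(1.0)
        assert u.max() == u[1]

    def test_large_phi_limit_is_uniform(self):
        u = similarity_weights(self.Xt, np.array([5.0, 5.0]), self.S, phi=1e9)
        np.testing.assert_allclose(u, 1.0, atol=1e-6)

    def test_matches_hand_computed_exponential(self):
        xr = np.array([0.5, 0.5])
        d = np.linalg.norm(self.Xt - xr, axis=1)  # identity S -> Euclidean
        expected = np.exp(-d / d.std())
        u = similarity_weights(self.Xt, xr, self.S, phi=1.0)
        np.testing.assert_allclose(u, expected, rtol=1e-12)


class TestLWPLS:
    def test_uniform_weights_reduce_to_global_pls(self):
        """phi -> infinity flattens the similarity weights, so the local
        model must coincide with the global PLS fit."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 4))
            y = X @ rng.normal(size=4) + 0.3 * rng.normal(size=30)
            q = LWPLSQuery(Xt=X, yt=y, phi=1e7, D=2)
            m = pls_fit(X, y, D=2)
            for xr in rng.normal(size=(5, 4)):
                assert lwpls_predict(q, xr) == pytest.approx(
                    pls_predict(m, xr), abs=1e-6
                )

    def test_extreme_localization_is_nearest_neighbor(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        q = LWPLSQuery(Xt=X, yt=y, phi=1e-3, D=2)
        assert lwpls_predict(q, X[7]) == pytest.approx(y[7], abs=1e-3)

    def test_minimal_sample_count_boundary(self):
        X = np.array([[0.0, 0.0], [1.0, 0.5], [0.3, 1.0]])  # M = D + 1 = 3
        y = np.array([1.0, 2.0, 3.0])
        q = LWPLSQuery(Xt=X, yt=y, phi=1.0, D=2)
        assert np.isfinite(lwpls_predict(q, X[1]))

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidArgumentError):
            LWPLSQuery(Xt=np.zeros((2, 2)), yt=np.zeros(2), D=2)


def closed_form_gp_mean(model: GPRModel, Xq: np.ndarray) -> np.ndarray:
    """Independent dense oracle: de-standardized k*' (K + noise I)^-1 y."""
    Z = model.Xtrain
    D2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(-1)
    K = model.signal_var * np.exp(-D2 / (2 * model.rbf_scale**2))
    K = K + model.noise_level * np.eye(len(Z))
    zy = model.alpha_vec @ (K)  # recover standardized y from alpha
    Zq = (Xq - model.x_center) / model.x_scale
    D2q = ((Zq[:, None, :] - Z[None, :, :]) ** 2).sum(-1)
    Kq = model.signal_var * np.exp(-D2q / (2 * model.rbf_scale**2))
    return model.y_center + model.y_scale * (Kq @ np.linalg.solve(K, zy))


class TestGPR:
    def test_single_centered_point_predicts_zero(self):
        m = gpr_fit(np.zeros((1, 2)), np.zeros(1), optimize=False)
        assert gpr_predict(m, np.zeros(2)) == pytest.approx(0.0, abs=1e-12)

    def test_far_query_reverts_to_prior_mean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 2))
        y = 50.0 + rng.normal(size=20)
        m = gpr_fit(X, y, optimize=False)
        assert gpr_predict(m, np.full(2, 100.0)) == pytest.approx(
            m.y_center, abs=1e-6
        )

    def test_matches_dense_closed_form(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 3))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=40)
        m = gpr_fit(X, y, optimize=False)
        Xq = rng.normal(size=(10, 3))
        np.testing.assert_allclose(
            gpr_predict(m, Xq), closed_form_gp_mean(m, Xq), atol=1e-8
        )

    def test_interpolates_training_targets_as_noise_vanishes(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        m = gpr_fit(X, y, optimize=False, noise_level=1e-8)
        np.testing.assert_allclose(gpr_predict(m, X), y, atol=1e-5)

    def test_predictive_sd_grows_away_from_data(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        m = gpr_fit(X, y, optimize=False)
        _, sd_near = gpr_predict(m, X[0], return_sd=True)
        _, sd_far = gpr_predict(m, np.full(2, 50.0), return_sd=True)
        assert sd_near <= sd_far

    def test_optimization_does_not_decrease_marginal_likelihood(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 2))
        y = np.sin(2 * X[:, 0]) + 0.1 * rng.normal(size=30)
        fixed = gpr_fit(X, y, optimize=False)
        tuned = gpr_fit(X, y, optimize=True)
        assert tuned.log_marginal_likelihood >= fixed.log_marginal_likelihood - 1e-9

    def test_agrees_with_reference_library_fixed_kernel(self):
        """Cross-check against an independent GP implementation."""
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, WhiteKernel

        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 2))
        y = rng.normal(size=25)
        m = gpr_fit(X, y, optimize=False)
        Z = (X - m.x_center) / m.x_scale
        zy = (y - m.y_center) / m.y_scale
        gp = GaussianProcessRegressor(
            RBF(1.0, "fixed") + WhiteKernel(1.0, "fixed"), alpha=0.0
        ).fit(Z, zy)
        Xq = rng.normal(size=(8, 2))
        Zq = (Xq - m.x_center) / m.x_scale
        np.testing.assert_allclose(
            gpr_predict(m, Xq), m.y_center + m.y_scale * gp.predict(Zq), atol=1e-8
        )


class TestPersistence:
    def test_pls_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        m = pls_fit(X, y, D=2)
        path = tmp_path / "pls.json"
        save_model(m, path)
        m2 = load_model(path)
        Xq = rng.normal(size=(5, 3))
        np.testing.assert_array_equal(pls_predict(m, Xq), pls_predict(m2, Xq))

    def test_gpr_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        m = gpr_fit(X, y, optimize=True)
        path = tmp_path / "gpr.json"
        save_model(m, path)
        m2 = load_model(path)
        Xq = rng.normal(size=(5, 2))
        np.testing.assert_array_equal(gpr_predict(m, Xq), gpr_predict(m2, Xq))
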