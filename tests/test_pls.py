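import numpy as np
import pytest

from nirselect import (MCCVPlan, fit_pls, mccv_splits, predict, r_squared,
                       rmse, rmsecv, select_lv_mccv)


class TestFitPredict:
    def test_single_channel_equals_simple_ols(self, rng):
        x = rng.normal(size=(25, 1))
        y = 3.0 + 2.0 * x[:, 0] + rng.normal(scale=0.3, size=25)
        model = fit_pls(x, y, 1)
        slope, intercept = np.polyfit(x[:, 0], y, 1)
        np.testing.assert_allclose(predict(model, x), intercept + slope * x[:, 0],
                                   atol=1e-10)

    def test_noiseless_linear_data_recovered_exactly(self, rng):
        X = rng.normal(size=(20, 3))
        y = X @ [1.0, -2.0, 0.5]
        model = fit_pls(X, y, 3)
        assert np.max(np.abs(predict(model, X) - y)) < 1e-8

    def test_full_rank_pls_equals_multiple_ols(self, rng):
        # at n_lv = p the PLS span equals the column space: OLS predictions
        for _ in range(20):
            X = rng.normal(size=(30, 10))
            y = rng.normal(size=30)
            model = fit_pls(X, y, 10)
            A = np.column_stack([np.ones(30), X])
            beta = np.linalg.lstsq(A, y, rcond=None)[0]
            np.testing.assert_allclose(predict(model, X), A @ beta, atol=1e-8)

    def test_agrees_with_sklearn_nipals(self, rng):
        from sklearn.cross_decomposition import PLSRegression
        X = rng.normal(size=(40, 15))
        y = rng.normal(size=40)
        ours = predict(fit_pls(X, y, 5), X)
        sk = PLSRegression(n_components=5, scale=False).fit(X, y[:, None])
        np.testing.assert_allclose(ours, sk.predict(X).ravel(), atol=1e-10)

    def test_mean_spectrum_predicts_mean_response(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        model = fit_pls(X, y, 3)
        got = predict(model, model.x_mean[None, :])
        np.testing.assert_allclose(got, [y.mean()], atol=1e-12)

    def test_score_space_prediction_path_agrees(self, rng):
        # yhat via T q must equal yhat via the collapsed coefficient vector
        X = rng.normal(size=(25, 8))
        y = rng.normal(size=25)
        m = fit_pls(X, y, 4)
        Xc = X - m.x_mean
        T = Xc @ m.weights @ np.linalg.inv(m.x_loadings.T @ m.weights)
        np.testing.assert_allclose(m.y_mean + T @ m.y_loadings,
                                   predict(m, X), atol=1e-10)

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(30, 12))
        y = rng.normal(size=30)
        m = fit_pls(X, y, 6)
        T = (X - m.x_mean) @ m.weights @ np.linalg.inv(m.x_loadings.T @ m.weights)
        G = T.T @ T
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)

    def test_nlv_bound_enforced(self, rng):
        with pytest.raises(ValueError, match="n_lv"):
            fit_pls(rng.normal(size=(5, 10)), rng.normal(size=5), 5)

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pls(rng.normal(size=(10, 4)), np.ones(10), 2)

    def test_channel_count_mismatch_on_predict(self, rng):
        m = fit_pls(rng.normal(size=(10, 4)), rng.normal(size=10), 2)
        with pytest.raises(ValueError, match="channels"):
            predict(m, rng.normal(size=(3, 7)))


class TestMetrics:
    def test_rmse_examples(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0
        np.testing.assert_allclose(rmse([1, 2, 3], [1, 2, 4]), np.sqrt(1 / 3))

    def test_rmse_homogeneous(self, rng):
        y, yh = rng.normal(size=20), rng.normal(size=20)
        np.testing.assert_allclose(rmse(-2.5 * y, -2.5 * yh), 2.5 * rmse(y, yh))

    def test_rmse_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1, 2, 3])

    def test_r_squared_reference_points(self, rng):
        y = rng.normal(size=30)
        assert r_squared(y, y) == 1.0
        np.testing.assert_allclose(r_squared(y, np.full(30, y.mean())), 0.0,
                                   atol=1e-12)
        # predictor worse than the mean goes negative
        assert r_squared(y, -3 * y) < 0

    def test_r_squared_rmse_identity(self, rng):
        # 1 - R^2 == (rmse / population sd)^2 by definition
        y, yh = rng.normal(size=50), rng.normal(size=50)
        np.testing.assert_allclose(1 - r_squared(y, yh),
                                   (rmse(y, yh) / y.std()) ** 2)

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 1.0], [1.0, 2.0])


class TestRMSECV:
    PLAN = MCCVPlan(n_repeats=8, calib_fraction=0.8, seed=4)

    def test_noiseless_limit(self, rng):
        X = rng.normal(size=(20, 5))
        y = X @ [1, 2, 3, 4, 5.0]
        assert rmsecv(X, y, 5, self.PLAN) < 1e-6

    def test_reproducible(self, small_dataset):
        X, y = small_dataset
        assert rmsecv(X, y, 3, self.PLAN) == rmsecv(X, y, 3, self.PLAN)

    def test_matches_naive_loop_oracle(self, rng):
        X = rng.normal(size=(15, 8))
        y = rng.normal(size=15)
        got = rmsecv(X, y, 3, self.PLAN)
        residuals = []
        for sp in mccv_splits(15, self.PLAN):
            m = fit_pls(X[sp.train_idx], y[sp.train_idx], 3)
            residuals.extend(y[sp.test_idx] - predict(m, X[sp.test_idx]))
        np.testing.assert_allclose(got, np.sqrt(np.mean(np.square(residuals))),
                                   atol=1e-10)

    def test_invariant_to_repeat_order(self, small_dataset):
        X, y = small_dataset
        splits = mccv_splits(30, self.PLAN)
        a = rmsecv(X, y, 3, self.PLAN, splits=splits)
        b = rmsecv(X, y, 3, self.PLAN, splits=splits[::-1])
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_mask_too_small_rejected(self, small_dataset):
        X, y = small_dataset
        with pytest.raises(ValueError, match="mask"):
            rmsecv(X, y, 3, self.PLAN, mask=[0, 1])


class TestLVSelection:
    def test_recovers_constructed_rank(self, rng):
        # data with exactly 2 latent factors, noiseless: curve hits zero at
        # 2 and the parsimony tie-break keeps the smallest such count
        T = rng.normal(size=(40, 2))
        X = T @ rng.normal(size=(2, 12))
        y = T @ [1.5, -0.5]
        best, curve = select_lv_mccv(X, y, 6, MCCVPlan(10, 0.8, seed=2))
        assert best == 2
        assert curve[1] < 1e-8

    def test_max_lv_one(self, small_dataset):
        X, y = small_dataset
        best, curve = select_lv_mccv(X, y, 1, MCCVPlan(5, 0.8, seed=0))
        assert best == 1 and len(curve) == 1

    def test_infeasible_max_lv_rejected(self, small_dataset):
        X, y = small_dataset
        with pytest.raises(ValueError):
            select_lv_mccv(X, y, 13, MCCVPlan(5, 0.8, seed=0))
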