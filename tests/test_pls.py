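"""NIPALS PLS1, prediction, LOO cross-validation and metrics."""

import numpy as np
import pytest

import woodnir as wn
from woodnir.pls import PARSIMONY_REL


def ols_predictions(X, y):
    """Closed-form least-squares oracle on centred data."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    return Xc @ beta + y.mean()


class TestFitPLS1:
    def test_single_collinear_column_perfect_fit(self, rng):
        y = rng.normal(size=30)
        X = y[:, None].copy()
        m = wn.fit_pls1(X, y, 1)
        pred = wn.predict(m, X)
        assert np.max(np.abs(pred - y)) < 1e-10
        assert wn.metrics(y, pred).r2 == pytest.approx(1.0, abs=1e-12)

    def test_full_lv_equals_ols(self, rng):
        for _ in range(5):
            X = rng.normal(size=(40, 6))
            y = rng.normal(size=40)
            m = wn.fit_pls1(X, y, 6)
            assert np.max(np.abs(wn.predict(m, X) - ols_predictions(X, y))) < 1e-8

    def test_orthogonal_response_gives_zero_coefficients(self):
        # X columns constructed orthogonal to y (after centering)
        y = np.array([1.0, -1.0, 1.0, -1.0])
        X = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 0.5], [3.0, 0.5]])
        with pytest.warns(UserWarning):
            m = wn.fit_pls1(X, y, 2)
        assert np.max(np.abs(m.coef)) < 1e-10
        assert np.max(np.abs(wn.predict(m, X) - y.mean())) < 1e-10

    def test_score_orthogonality(self, rng):
        X = rng.normal(size=(30, 15))
        y = X[:, 0] + 0.5 * X[:, 3] + 0.1 * rng.normal(size=30)
        m = wn.fit_pls1(X, y, 6)
        T = m.scores
        for i in range(m.n_lv):
            for j in range(i + 1, m.n_lv):
                assert abs(T[:, i] @ T[:, j]) < 1e-8 * np.linalg.norm(T[:, i]) * np.linalg.norm(T[:, j])

    def test_coef_equals_factorization_predictions(self, rng):
        X = rng.normal(size=(25, 10))
        y = rng.normal(size=25)
        m = wn.fit_pls1(X, y, 4)
        # rebuild predictions from the T, q factorization
        via_scores = m.scores @ m.y_loadings + m.y_mean
        via_coef = wn.predict(m, X)
        assert np.max(np.abs(via_scores - via_coef)) < 1e-10

    def test_training_r2_nondecreasing_in_lv(self, rng):
        X = rng.normal(size=(30, 12))
        y = rng.normal(size=30)
        r2 = [wn.metrics(y, wn.predict(wn.fit_pls1(X, y, k), X)).r2
              for k in range(1, 9)]
        assert all(b >= a - 1e-10 for a, b in zip(r2, r2[1:]))

    def test_zero_column_leaves_model_unchanged(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        m1 = wn.fit_pls1(X, y, 3)
        X2 = np.hstack([X, np.zeros((20, 1))])
        m2 = wn.fit_pls1(X2, y, 3)
        assert np.max(np.abs(m2.coef[:5] - m1.coef)) < 1e-10
        assert abs(m2.coef[5]) < 1e-10
        assert np.max(np.abs(wn.predict(m2, X2) - wn.predict(m1, X))) < 1e-10

    def test_matches_sklearn_pls_regression(self, rng):
        # independent implementation cross-check (same NIPALS family,
        # centred, unscaled)
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(40, 20))
        y = X[:, 2] - 0.5 * X[:, 7] + 0.2 * rng.normal(size=40)
        for k in (1, 3, 5):
            ours = wn.fit_pls1(X, y, k)
            ref = PLSRegression(n_components=k, scale=False).fit(X, y)
            np.testing.assert_allclose(wn.predict(ours, X),
                                       ref.predict(X).ravel(), atol=1e-8)

    def test_zero_variance_response_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(wn.ValidationError):
            wn.fit_pls1(X, np.ones(10), 2)

    def test_excessive_lv_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        with pytest.raises(wn.ConfigError):
            wn.fit_pls1(X, y, 4)


class TestPredict:
    def test_mean_row_predicts_mean_response(self, rng):
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        m = wn.fit_pls1(X, y, 3)
        assert wn.predict(m, m.x_mean)[0] == pytest.approx(m.y_mean, abs=1e-10)

    def test_column_mismatch_rejected(self, rng):
        X = rng.normal(size=(20, 6))
        m = wn.fit_pls1(X, rng.normal(size=20), 2)
        with pytest.raises(wn.ValidationError):
            wn.predict(m, rng.normal(size=(3, 5)))


class TestLooCV:
    def test_noiseless_signal_chooses_one_lv(self, rng):
        # all columns proportional to the signal: one component is exact
        # in every leave-one-out fold
        x = rng.normal(size=15)
        X = np.outer(x, [1.0, -0.5, 2.0])
        y = 2.0 * x
        cv = wn.loo_cv(X, y, max_lv=4)
        assert cv.chosen_lv == 1
        assert cv.rmsecv_per_lv[0] < 1e-8

    def test_matches_hand_rolled_loop(self, rng):
        # independent oracle: explicit leave-one-out loop through the
        # public fit/predict API
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        max_lv = 2
        cv = wn.loo_cv(X, y, max_lv=max_lv)
        for k in range(1, max_lv + 1):
            errs = []
            for i in range(8):
                mask = np.ones(8, bool)
                mask[i] = False
                m = wn.fit_pls1(X[mask], y[mask], k)
                errs.append(wn.predict(m, X[i])[0] - y[i])
            assert np.sqrt(np.mean(np.square(errs))) == pytest.approx(
                cv.rmsecv_per_lv[k - 1], abs=1e-10)

    def test_pure_noise_keeps_model_small(self, rng):
        chosen = []
        for rep in range(10):
            r = np.random.default_rng(100 + rep)
            X = r.normal(size=(25, 40))
            y = r.normal(size=25)
            chosen.append(wn.loo_cv(X, y, max_lv=10).chosen_lv)
        assert np.median(chosen) <= 3

    def test_parsimony_rule(self, rng):
        X = rng.normal(size=(20, 8))
        y = X[:, 0] + 0.3 * rng.normal(size=20)
        cv = wn.loo_cv(X, y, max_lv=6)
        best = cv.rmsecv_per_lv.min()
        k = cv.chosen_lv
        assert cv.rmsecv_per_lv[k - 1] <= (1 + PARSIMONY_REL) * best
        assert all(cv.rmsecv_per_lv[j] > (1 + PARSIMONY_REL) * best
                   for j in range(k - 1))

    def test_max_lv_clipped_with_warning(self, rng):
        X = rng.normal(size=(6, 10))
        y = rng.normal(size=6)
        with pytest.warns(UserWarning, match="clipped"):
            cv = wn.loo_cv(X, y, max_lv=10)
        assert cv.rmsecv_per_lv.size == 4  # n - 2


class TestMetrics:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0])
        m = wn.metrics(y, y)
        assert m.r2 == 1.0 and m.rmse == 0.0

    def test_mean_predictor_r2_zero(self):
        m = wn.metrics([0.0, 1.0], [0.5, 0.5])
        assert m.r2 == pytest.approx(0.0, abs=1e-12)
        assert m.rmse == pytest.approx(0.5, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        y = rng.normal(size=50)
        y_hat = y + rng.normal(scale=0.3, size=50)
        m = wn.metrics(y, y_hat)
        rmse = np.sqrt(sum((a - b) ** 2 for a, b in zip(y, y_hat)) / 50)
        r2 = 1 - sum((a - b) ** 2 for a, b in zip(y, y_hat)) / sum((a - y.mean()) ** 2 for a in y)
        assert m.rmse == pytest.approx(rmse, abs=1e-12)
        assert m.r2 == pytest.approx(r2, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(wn.ValidationError):
            wn.metrics([1.0, 1.0], [1.0, 2.0])
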