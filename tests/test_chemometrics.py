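"""Autoscaling, PCA diagnostics, NIPALS PLS1, CV, permutations, CV-ANOVA."""

import numpy as np
import pytest
from scipy import stats

from olivescreen.chemometrics import (
    CVResult,
    autoscale_apply,
    autoscale_fit,
    cross_validate,
    cv_anova,
    hotelling_t2,
    outlier_screen,
    pca_fit,
    permutation_test,
    pls1_fit,
    pls1_predict,
    t2_limit,
)


def toy_regression(n=6, p=3, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return X, (y > np.median(y)).astype(float), y


class TestAutoscale:
    def test_two_point_standardization(self):
        pre = autoscale_fit(np.array([[1.0], [3.0]]))
        out = autoscale_apply(pre, np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(out[:, 0], [-np.sqrt(0.5), np.sqrt(0.5)],
                                   atol=1e-12)

    def test_constant_column_zeroed_scale_one(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        pre = autoscale_fit(X)
        out = autoscale_apply(pre, X)
        assert pre.column_scales[0] == 1.0
        np.testing.assert_array_equal(out[:, 0], np.zeros(5))

    def test_round_trip_identity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(10, 5, size=(8, 6))
        pre = autoscale_fit(X)
        back = pre.inverse_transform(pre.transform(X))
        np.testing.assert_allclose(back, X, atol=1e-10)

    def test_apply_uses_training_statistics_only(self):
        train = np.random.default_rng(2).normal(size=(10, 4))
        pre = autoscale_fit(train)
        new = np.random.default_rng(3).normal(100, 50, size=(5, 4))
        out = autoscale_apply(pre, new)
        np.testing.assert_allclose(
            out, (new - pre.column_means) / pre.column_scales)


class TestPcaDiagnostics:
    def test_t2_matches_brute_force_on_4x3(self):
        X = np.array([[1.0, 2.0, 0.5],
                      [2.0, 1.0, 1.5],
                      [0.5, 0.2, 2.0],
                      [1.5, 1.8, 0.1]])
        model = pca_fit(X, A=2)
        # oracle: Mahalanobis form in score space
        t = model.scores
        expected = np.array([
            sum(t[i, a] ** 2 / t[:, a].var(ddof=1) for a in range(2))
            for i in range(4)
        ])
        np.testing.assert_allclose(hotelling_t2(model.scores), expected,
                                   atol=1e-10)

    def test_subspace_data_zero_q(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 2)) @ rng.normal(size=(2, 6))
        model = pca_fit(X, A=2)
        rep = outlier_screen(model, X)
        assert np.all(rep.q < 1e-16 * 36)

    def test_scaled_row_flagged(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, size=(30, 8)) + 50
        X[3] = 50 + 20 * (X[3] - 50)
        model = pca_fit(X, A=2)
        rep = outlier_screen(model, X, confidence=0.95)
        assert rep.outlier_flags[3]

    def test_t2_limit_formula(self):
        n, A = 30, 2
        expected = (A * (n - 1) * (n + 1) / (n * (n - A))
                    * stats.f.ppf(0.95, A, n - A))
        assert t2_limit(n, A) == pytest.approx(expected)

    def test_loadings_orthonormal_evr_non_increasing(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 10))
        model = pca_fit(X, A=4)
        np.testing.assert_allclose(model.loadings.T @ model.loadings,
                                   np.eye(4), atol=1e-8)
        assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)
        assert model.explained_variance_ratio.sum() <= 1 + 1e-12


class TestPls1:
    def test_full_rank_equals_least_squares(self):
        """PLS1 with as many LVs as the rank reproduces the OLS fit."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        model = pls1_fit(X, (y > 0).astype(float), n_lv=3)
        yd = (y > 0).astype(float)
        # oracle: normal equations on the centred/scaled problem
        Xs = model.preprocessor.transform(X)
        beta, *_ = np.linalg.lstsq(Xs, yd - yd.mean(), rcond=None)
        np.testing.assert_allclose(pls1_predict(model, X),
                                   Xs @ beta + yd.mean(), atol=1e-8)

    def test_single_perfect_column(self):
        y = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0])
        X = y[:, None] * 2.0 + 3.0
        model = pls1_fit(X, y, n_lv=1)
        np.testing.assert_allclose(pls1_predict(model, X), y, atol=1e-10)

    def test_first_weight_proportional_to_xty(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 5))
        y = rng.integers(0, 2, 12).astype(float)
        model = pls1_fit(X, y, n_lv=3)
        Xs = model.preprocessor.transform(X)
        w_ref = Xs.T @ (y - y.mean())
        w_ref /= np.linalg.norm(w_ref)
        np.testing.assert_allclose(np.abs(model.weights[:, 0] @ w_ref), 1.0,
                                   atol=1e-10)

    def test_prediction_rowwise(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 4))
        y = rng.integers(0, 2, 10).astype(float)
        model = pls1_fit(X, y, n_lv=2)
        single = pls1_predict(model, X[4])
        doubled = pls1_predict(model, np.vstack([X[4], X[4]]))
        assert doubled[0] == doubled[1]
        assert doubled[0] == pytest.approx(single[0], abs=1e-12)

    def test_degenerate_dummy_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError, match="degenerate"):
            pls1_fit(X, np.ones(5), n_lv=1)

    def test_against_reference_pls_implementation(self):
        from sklearn.cross_decomposition import PLSRegression
        rng = np.random.default_rng(10)
        X = rng.normal(size=(30, 12))
        y = (X[:, 0] + 0.5 * X[:, 3] + 0.1 * rng.normal(size=30) > 0).astype(float)
        model = pls1_fit(X, y, n_lv=4)
        ref = PLSRegression(n_components=4, scale=True).fit(X, y)
        np.testing.assert_allclose(
            pls1_predict(model, X), ref.predict(X).ravel(), atol=1e-8)


class TestCrossValidate:
    def test_perfect_linear_case(self):
        y = np.array([0, 1] * 10, dtype=float)
        rng = np.random.default_rng(11)
        X = np.column_stack([y * 4 + 1, rng.normal(size=20)])
        cv = cross_validate(X, y, max_lv=2, seed=0)
        assert cv.rmsecv[cv.chosen_lv - 1] < 0.05
        assert cv.q2[cv.chosen_lv - 1] > 0.99

    def test_shuffled_labels_low_q2(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(60, 30))
        X[:30] += 2.0  # structure unrelated to the shuffled labels
        y = rng.permutation([0.0, 1.0] * 30)
        cv = cross_validate(X, y, max_lv=8, seed=1)
        assert np.all(cv.q2 < 0.4)

    def test_seed_reproducibility(self):
        X, y, _ = toy_regression(40, 6, seed=13, noise=0.5)
        cv1 = cross_validate(X, y, max_lv=4, seed=5)
        cv2 = cross_validate(X, y, max_lv=4, seed=5)
        np.testing.assert_array_equal(cv1.fold_assignment, cv2.fold_assignment)
        np.testing.assert_array_equal(cv1.oof_pv, cv2.oof_pv)

    def test_q2_rmsecv_identity(self):
        X, y, _ = toy_regression(40, 6, seed=14, noise=0.5)
        cv = cross_validate(X, y, max_lv=4, seed=2)
        tss = ((y - y.mean()) ** 2).sum()
        np.testing.assert_allclose(
            cv.q2, 1 - y.size * cv.rmsecv**2 / tss, atol=1e-12)

    def test_no_leakage_from_held_out_rows(self):
        """Rescaling a sample never changes predictions of its fold mates."""
        X, y, _ = toy_regression(40, 6, seed=15, noise=0.5)
        cv1 = cross_validate(X, y, max_lv=3, seed=3)
        target = 7
        X2 = X.copy()
        X2[target] *= 1000.0
        cv2 = cross_validate(X2, y, max_lv=3, seed=3)
        mates = (cv1.fold_assignment == cv1.fold_assignment[target])
        mates[target] = False
        np.testing.assert_array_equal(cv1.oof_pv[mates], cv2.oof_pv[mates])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="n_folds"):
            cross_validate(np.zeros((5, 2)), np.array([0, 1, 0, 1, 0.0]))


class TestPermutation:
    def test_separable_data_significant(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(40, 10))
        y = np.array([0.0] * 20 + [1.0] * 20)
        X[y == 1, :3] += 3.0
        res = permutation_test(X, y, n_lv=2, n_perm=20, seed=4)
        assert res.original_exceeds_all
        assert res.empirical_p == pytest.approx(1 / 21)

    def test_noise_data_not_significant(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(40, 10))
        y = np.array([0.0, 1.0] * 20)
        res = permutation_test(X, y, n_lv=2, n_perm=20, seed=5)
        assert res.empirical_p > 0.05

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(np.zeros((12, 2)), np.array([0.0, 1] * 6),
                             n_lv=1, n_perm=0)


class TestCvAnova:
    def _cv_with_press(self, press_at_chosen, chosen_lv, n):
        press = np.full(chosen_lv, np.nan)
        press[chosen_lv - 1] = press_at_chosen
        return CVResult(
            fold_assignment=np.zeros(n, int),
            oof_pv=np.zeros((n, chosen_lv)),
            press=press, rmsecv=np.sqrt(press / n),
            q2=np.zeros(chosen_lv), chosen_lv=chosen_lv, seed=0,
        )

    def test_model_no_better_than_mean(self):
        y = np.array([0.0, 1.0] * 8)
        ss_null = ((y - y.mean()) ** 2).sum()
        res = cv_anova(self._cv_with_press(ss_null, 1, y.size), y)
        assert res.f_stat == 0.0
        assert res.p_value == 1.0

    def test_press_to_zero_p_to_zero(self):
        y = np.array([0.0, 1.0] * 8)
        res = cv_anova(self._cv_with_press(1e-12, 1, y.size), y)
        assert res.p_value < 1e-10

    def test_hand_case_f_equals_40(self):
        # ss_null = 10, PRESS = 2, n = 23, 2 LVs -> F = ((10-2)/2)/(2/20) = 40
        a = np.sqrt(5.0)
        y = np.concatenate([[a, -a], np.zeros(21)])
        assert ((y - y.mean()) ** 2).sum() == pytest.approx(10.0)
        res = cv_anova(self._cv_with_press(2.0, 2, 23), y)
        assert res.f_stat == pytest.approx(40.0)
        assert res.df1 == 2 and res.df2 == 20
        assert res.p_value == pytest.approx(stats.f.sf(40.0, 2, 20))
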