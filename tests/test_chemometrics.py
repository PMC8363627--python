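import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from granufuse import (accuracy, autoscale_fit, fit_pca, fit_pls,
                       hotelling_t2, q2_cv, r2, rmsep, select_n_lv, vip)
from granufuse.chemometrics import PLSModel, RankError, cv_folds
from granufuse.lab_campaign import VALIDATION_RUNS


class TestAutoscale:
    def test_two_point_column_closed_form(self):
        sm = autoscale_fit(np.array([[0.0], [2.0]]))
        scaled = sm.apply(np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(scaled.ravel(),
                                   [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_training_block_centered_and_inverse_round_trip(self, rng):
        X = rng.normal(loc=5, scale=3, size=(20, 6))
        sm = autoscale_fit(X)
        Xs = sm.apply(X)
        np.testing.assert_allclose(Xs.mean(0), 0, atol=1e-12)
        np.testing.assert_allclose(Xs.std(0, ddof=1), 1, rtol=1e-12)
        np.testing.assert_allclose(sm.inverse(Xs), X, rtol=1e-12)

    def test_constant_column_dropped_with_warning(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "c"])
        X["b"] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            sm = autoscale_fit(X)
        assert sm.dropped == ["b"]
        assert sm.apply(X).shape == (10, 2)


class TestPCA:
    def test_rank_one_data_fully_explained_by_pc1(self, rng):
        direction = rng.normal(size=5)
        X = np.outer(rng.normal(size=12), direction)
        X += rng.normal(size=X.shape) * 1e-12
        model = fit_pca(X, 2)
        assert model.explained[0] == pytest.approx(1.0, abs=1e-6)

    def test_matches_full_svd_oracle_up_to_sign(self, rng):
        X = rng.normal(size=(8, 5))
        model = fit_pca(X, 4)
        sm = autoscale_fit(X)
        Xs = sm.apply(X)
        U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
        for a in range(4):
            v = Vt[a] * np.sign(Vt[a][np.argmax(np.abs(Vt[a]))])
            np.testing.assert_allclose(model.loadings[:, a], v, atol=1e-10)
            np.testing.assert_allclose(np.abs(model.scores[:, a]),
                                       np.abs(U[:, a] * s[a]), atol=1e-10)
        np.testing.assert_allclose(model.explained,
                                   (s ** 2 / (s ** 2).sum())[:4], atol=1e-12)

    def test_loadings_orthonormal_and_explained_nonincreasing(self, rng):
        model = fit_pca(rng.normal(size=(15, 6)), 4)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)
        assert (np.diff(model.explained) <= 1e-12).all()
        assert model.explained.sum() <= 1 + 1e-12


class TestHotelling:
    def test_identical_scores_give_zero(self):
        # a degenerate (zero-variance) score direction carries no distance
        scores = np.tile([1.0, -2.0], (8, 1))
        t2, _ = hotelling_t2(scores, 2)
        np.testing.assert_allclose(t2, 0, atol=0)

    def test_limit_matches_f_quantile_arithmetic(self):
        from scipy import stats
        scores = np.random.default_rng(1).normal(size=(20, 2))
        _, limit = hotelling_t2(scores, 2, alpha=0.05)
        expected = 2 * (20 ** 2 - 1) / (20 * 18) * stats.f.ppf(0.95, 2, 18)
        assert limit == pytest.approx(expected, rel=1e-12)

    def test_quadratic_scaling(self, rng):
        scores = rng.normal(size=(15, 3))
        t2a, _ = hotelling_t2(scores, 3)
        t2b, _ = hotelling_t2(2 * scores, 3)
        np.testing.assert_allclose(t2b, t2a, rtol=1e-12)  # scale-invariant
        # but scaling rows of a *fixed-variance* reference quadruples T2
        var = scores.var(0, ddof=1)
        t2_fixed = ((2 * scores) ** 2 / var).sum(1)
        np.testing.assert_allclose(t2_fixed, 4 * (scores ** 2 / var).sum(1))


class TestPLS:
    def test_exact_linear_response_fully_fitted(self, rng):
        X = rng.normal(size=(15, 4))
        y = X @ [2.0, -1.0, 0.5, 3.0] + 4.0
        m = fit_pls(pd.DataFrame(X), y, 4)
        assert r2(y, m.predict(X)) == pytest.approx(1.0, abs=1e-10)

    def test_single_predictor_equals_univariate_slope(self, rng):
        x = rng.normal(size=20)
        y = 3.0 * x + rng.normal(size=20)
        m = fit_pls(x.reshape(-1, 1), y, 1)
        xs = (x - x.mean()) / x.std(ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        slope = float(xs @ ys / (xs @ xs))
        assert m.B[0] == pytest.approx(slope, rel=1e-10)

    @pytest.mark.parametrize("shape", [(12, 4), (30, 7), (9, 3)])
    def test_full_rank_pls_equals_least_squares(self, rng, shape):
        n, p = shape
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        m = fit_pls(X, y, p)
        Xc = np.column_stack([np.ones(n), X])
        beta = np.linalg.lstsq(Xc, y, rcond=None)[0]
        np.testing.assert_allclose(m.predict(X), Xc @ beta, atol=1e-8)

    def test_matches_sklearn_nipals_predictions(self, rng):
        X = rng.normal(size=(25, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=25)
        for a in (1, 3, 5):
            ours = fit_pls(X, y, a).predict(X)
            sk = PLSRegression(n_components=a).fit(X, y).predict(X).ravel()
            np.testing.assert_allclose(ours, sk, atol=1e-8)

    def test_scores_orthogonal_and_b_equals_decomposition(self, rng):
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        m = fit_pls(X, y, 4)
        gram = m.T.T @ m.T
        assert np.abs(gram - np.diag(np.diag(gram))).max() < 1e-8
        np.testing.assert_allclose(m.predict(X), m.predict_depths(X)[:, -1],
                                   atol=1e-8)

    def test_training_sse_monotone_in_components(self, rng):
        X = rng.normal(size=(25, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=25)
        m = fit_pls(X, y, 6)
        depth = m.predict_depths(X)
        sse = ((y[:, None] - depth) ** 2).sum(0)
        assert (np.diff(sse) <= 1e-9).all()

    def test_row_order_invariance(self, rng):
        X = rng.normal(size=(18, 5))
        y = rng.normal(size=18)
        perm = rng.permutation(18)
        m1 = fit_pls(X, y, 3)
        m2 = fit_pls(X[perm], y[perm], 3)
        np.testing.assert_allclose(m1.B, m2.B, atol=1e-10)

    def test_rank_exceeded_raises(self, rng):
        X = rng.normal(size=(10, 3))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])  # rank 3, 4 columns
        y = X @ [1, 2, 3, 0.0]
        with pytest.raises(RankError):
            fit_pls(X, y, 4)

    def test_projection_reproduces_training_scores_and_batching(self, rng):
        X = rng.normal(size=(16, 5))
        y = rng.normal(size=16)
        m = fit_pls(X, y, 3)
        np.testing.assert_allclose(m.project(X), m.T, atol=1e-8)
        one = m.project(X[3:4])
        np.testing.assert_allclose(one[0], m.project(X)[3], atol=1e-12)
        np.testing.assert_allclose(m.project(np.vstack([X[3], X[3]]))[0],
                                   m.project(np.vstack([X[3], X[3]]))[1])

    def test_json_round_trip(self, rng, tmp_path):
        X = rng.normal(size=(14, 5))
        y = rng.normal(size=14)
        m = fit_pls(pd.DataFrame(X, columns=list("abcde")), y, 3)
        path = tmp_path / "model.json"
        m.save(path)
        again = PLSModel.load(path)
        np.testing.assert_allclose(again.predict(X), m.predict(X), atol=1e-12)
        np.testing.assert_allclose(again.B, m.B)


class TestQ2:
    def test_noiseless_linear_leave_one_out(self, rng):
        X = rng.normal(size=(10, 3))
        y = X @ [1.0, 2.0, -1.0]
        out = q2_cv(X, y, 3, folds=10)
        assert out["q2"] >= 0.999

    def test_single_component_degenerate_product(self, rng):
        X = rng.normal(size=(14, 4))
        y = X @ rng.normal(size=4) + rng.normal(size=14)
        out = q2_cv(X, y, 1, folds=7, seed=3)
        assert out["q2"] == pytest.approx(
            1.0 - out["press"][0] / out["ss"][0], rel=1e-12)

    def test_matches_brute_force_refit_oracle(self, rng):
        X = rng.normal(size=(12, 4))
        y = X @ [1.0, -1.0, 0.5, 0.0] + rng.normal(size=12) * 0.4
        A, folds = 3, 4
        out = q2_cv(pd.DataFrame(X), y, A, folds=folds, seed=9)
        fid = out["fold_id"]
        preds = np.zeros((12, A))
        for f in range(folds):
            te = fid == f
            for a in range(1, A + 1):
                sk = PLSRegression(n_components=a).fit(X[~te], y[~te])
                preds[te, a - 1] = sk.predict(X[te]).ravel()
        press = ((y[:, None] - preds) ** 2).sum(0)
        ss = [float(((y - y.mean()) ** 2).sum())]
        for a in range(1, A + 1):
            sk = PLSRegression(n_components=a).fit(X, y)
            ss.append(float(((y - sk.predict(X).ravel()) ** 2).sum()))
        oracle = 1.0 - np.prod(press / np.array(ss[:-1]))
        assert out["q2"] == pytest.approx(oracle, abs=1e-8)
        np.testing.assert_allclose(out["press"], press, atol=1e-8)

    def test_fold_assignment_reproducible_and_balanced(self):
        f1 = cv_folds(23, 7, seed=4)
        f2 = cv_folds(23, 7, seed=4)
        np.testing.assert_array_equal(f1, f2)
        counts = np.bincount(f1)
        assert counts.max() - counts.min() <= 1


class TestVIP:
    def test_identical_predictors_all_unit_vip(self, rng):
        signal = rng.normal(size=30)
        X = np.tile(signal.reshape(-1, 1), (1, 5))
        X = X + rng.normal(size=X.shape) * 1e-10
        y = signal + rng.normal(size=30) * 0.1
        v = vip(fit_pls(X, y, 1))
        np.testing.assert_allclose(v, 1.0, atol=1e-4)

    def test_mean_square_is_one(self, rng):
        for a in (1, 2, 4):
            X = rng.normal(size=(20, 6))
            y = X @ rng.normal(size=6) + rng.normal(size=20)
            v = vip(fit_pls(X, y, a))
            assert (v ** 2).mean() == pytest.approx(1.0, abs=1e-6)


class TestMetrics:
    def test_r2_perfect_and_mean_predictor(self, rng):
        y = rng.normal(size=10)
        assert r2(y, y) == pytest.approx(1.0)
        assert r2(y, np.full(10, y.mean())) == pytest.approx(0.0)

    def test_r2_definition_on_random_data(self, rng):
        y, f = rng.normal(size=15), rng.normal(size=15)
        expected = 1 - ((y - f) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert r2(y, f) == pytest.approx(expected, rel=1e-12)

    def test_external_validation_arithmetic(self):
        # the six valid campaign validation runs and their recorded
        # fused-model predictions
        ok = VALIDATION_RUNS[~VALIDATION_RUNS["failed"]]
        y_obs = ok["y_obs_um"].to_numpy()
        y_pred = ok["y_pred_um"].to_numpy()
        assert rmsep(y_obs, y_pred) == pytest.approx(149.2, abs=0.05)
        assert accuracy(y_obs, y_pred, 300.0) == pytest.approx(5 / 6)
        assert accuracy(y_obs, y_pred, 100.0) == pytest.approx(4 / 6)

    def test_accuracy_boundary_inclusive_and_degenerate(self):
        assert accuracy([1.0, 2.0], [4.0, 2.0], 3.0) == 1.0
        assert accuracy([1.0], [1.0], 0.0) == 1.0
        assert rmsep([5.0], [3.0]) == 2.0
        assert rmsep([1.0, 2.0], [1.0, 2.0]) == 0.0


class TestSelectLV:
    def test_one_signal_data_chooses_single_component(self, rng):
        t = rng.normal(size=30)
        X = np.outer(t, [1.0, -0.5, 2.0, 0.3])
        X = X + rng.normal(size=X.shape) * 1e-6
        y = 2.0 * t
        chosen, ledger = select_n_lv(X, y, 3, folds=5)
        assert chosen == 1
        assert ledger.shape[0] == 3

    def test_zero_delta_keeps_maximum(self, rng):
        X = rng.normal(size=(20, 4))
        y = X @ rng.normal(size=4) + rng.normal(size=20)
        chosen, _ = select_n_lv(X, y, 4, folds=5, delta=0.0)
        assert chosen == 4

    def test_two_factor_problem_matches_ledger_inspection(self, rng):
        t1, t2 = rng.normal(size=40), rng.normal(size=40)
        X = np.column_stack([t1, t1 + 0.1 * rng.normal(size=40),
                             t2, t2 + 0.1 * rng.normal(size=40),
                             rng.normal(size=40) * 0.05])
        y = t1 + 0.8 * t2 + 0.02 * rng.normal(size=40)
        chosen, ledger = select_n_lv(X, y, 4, folds=5)
        # manual rule applied to the returned ledger reproduces the choice
        manual = 4
        for a in range(3):
            if (ledger["R2"][a + 1] - ledger["R2"][a] < 0.01
                    and ledger["Q2"][a + 1] - ledger["Q2"][a] < 0.01):
                manual = a + 1
                break
        assert chosen == manual == 2
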