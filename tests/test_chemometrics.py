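import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from prolspec import elm_fit, loocv_rmsecv, lssvm_fit, pls_fit, pls_predict
from prolspec.chemometrics import _pls_fit_fixed


def centred_ols(X, y):
    """Normal-equations oracle: OLS on mean-centred data."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)


class TestPLS:
    def test_rank_one_linear_system_is_exact(self, rng):
        t = rng.normal(size=12)
        v = rng.uniform(0.5, 1.5, size=6)
        X = np.outer(t, v)
        y = 2.0 * X[:, 3]
        model, cv = pls_fit(X, y, max_lv=4)
        assert cv.chosen == 1
        assert cv.rmsecv[0] < 1e-10
        assert np.allclose(model.predict(X), y, atol=1e-10)

    def test_full_rank_equals_ols(self, rng):
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        model = _pls_fit_fixed(X, y, n_lv=5)
        assert np.allclose(model.coef, centred_ols(X, y), atol=1e-8)

    def test_coefficients_match_sklearn_nipals(self, rng):
        # independent implementation cross-check at a fixed LV count
        X = rng.normal(size=(30, 12))
        y = X @ rng.normal(size=12) + rng.normal(scale=0.1, size=30)
        for lv in (1, 3, 5):
            ours = _pls_fit_fixed(X, y, n_lv=lv)
            ref = PLSRegression(n_components=lv, scale=False).fit(X, y[:, None])
            assert np.allclose(ours.coef, ref.coef_.ravel(), atol=1e-8)

    def test_reported_rmsecv_is_bruteforce_loo(self, rng):
        # oracle: explicit refit-per-left-out-sample loop via sklearn
        X = rng.normal(size=(15, 6))
        y = X @ rng.normal(size=6) + rng.normal(scale=0.3, size=15)
        model, cv = pls_fit(X, y, max_lv=4)
        lv = cv.chosen
        preds = np.empty(15)
        for i in range(15):
            keep = np.arange(15) != i
            ref = PLSRegression(n_components=lv, scale=False).fit(
                X[keep], y[keep][:, None]
            )
            preds[i] = ref.predict(X[i][None, :]).ravel()[0]
        oracle = np.sqrt(np.mean((preds - y) ** 2))
        assert np.isclose(cv.rmsecv[lv - 1], oracle, atol=1e-10)

    def test_training_rmse_non_increasing_in_lv(self, rng):
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        rmses = []
        for lv in range(1, 8):
            m = _pls_fit_fixed(X, y, lv)
            rmses.append(np.sqrt(np.mean((m.predict(X) - y) ** 2)))
        assert np.all(np.diff(rmses) <= 1e-12)

    def test_degenerate_inputs_rejected(self, rng):
        X = rng.normal(size=(8, 3))
        with pytest.raises(ValueError, match="constant"):
            pls_fit(X, np.ones(8))
        with pytest.raises(ValueError, match="variance"):
            pls_fit(np.ones((8, 3)), rng.normal(size=8))


class TestPLSPredict:
    def test_exact_fit_reproduces_training_targets(self, rng):
        X = rng.normal(size=(10, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0])
        model = _pls_fit_fixed(X, y, n_lv=4)
        assert np.allclose(pls_predict(model, X), y, atol=1e-8)

    def test_mean_spectrum_maps_to_mean_target(self, rng):
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        model = _pls_fit_fixed(X, y, n_lv=3)
        assert np.isclose(
            pls_predict(model, X.mean(axis=0)[None, :])[0], y.mean()
        )

    def test_prediction_is_affine(self, rng):
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        model = _pls_fit_fixed(X, y, n_lv=3)
        x1, x2 = rng.normal(size=(2, 5))
        for a in (0.0, 0.25, 0.8, 1.0):
            combo = a * x1 + (1 - a) * x2
            lhs = pls_predict(model, combo[None, :])[0]
            rhs = a * pls_predict(model, x1[None, :])[0] \
                + (1 - a) * pls_predict(model, x2[None, :])[0]
            assert np.isclose(lhs, rhs)

    def test_band_mismatch_raises(self, rng):
        model = _pls_fit_fixed(rng.normal(size=(8, 4)), rng.normal(size=8), 2)
        with pytest.raises(ValueError, match="band count"):
            model.predict(rng.normal(size=(3, 5)))


class TestLSSVM:
    def test_solution_matches_direct_kkt_solve(self, rng):
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        gam, sig2 = 100.0, 2.0
        model, _ = lssvm_fit(X, y, gam_grid=[gam], sig2_grid=[sig2], refine=False)
        # independent dense solve of [[0 1'],[1 K+I/gam]] [b;a] = [0;y]
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        K = np.exp(-d2 / sig2)
        A = np.zeros((6, 6))
        A[0, 1:] = 1.0
        A[1:, 0] = 1.0
        A[1:, 1:] = K + np.eye(5) / gam
        sol = np.linalg.solve(A, np.concatenate(([0.0], y)))
        assert np.isclose(model.bias, sol[0], atol=1e-8)
        assert np.allclose(model.alpha, sol[1:], atol=1e-8)

    def test_huge_gam_near_interpolates(self, rng):
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        model, _ = lssvm_fit(X, y, gam_grid=[1e8], sig2_grid=[1.0], refine=False)
        assert np.max(np.abs(model.predict(X) - y)) < 1e-4

    def test_tiny_gam_predicts_the_mean(self, rng):
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        model, _ = lssvm_fit(X, y, gam_grid=[1e-10], sig2_grid=[1.0], refine=False)
        assert np.allclose(model.predict(X), y.mean(), atol=1e-6)

    def test_chosen_pair_is_two_positive_scalars(self, rng):
        X = rng.normal(size=(10, 4))
        y = X @ rng.normal(size=4) + rng.normal(scale=0.1, size=10)
        model, cv = lssvm_fit(X, y, gam_grid=[1.0, 100.0], sig2_grid=[0.5, 5.0])
        gam, sig2 = cv.chosen
        assert gam > 0 and sig2 > 0
        assert (model.gam, model.sig2) == (gam, sig2)

    def test_rejects_invalid_grids(self, rng):
        X, y = rng.normal(size=(6, 2)), rng.normal(size=6)
        with pytest.raises(ValueError):
            lssvm_fit(X, y, gam_grid=[], sig2_grid=[1.0])
        with pytest.raises(ValueError):
            lssvm_fit(X, y, gam_grid=[-1.0], sig2_grid=[1.0])


class TestELM:
    def test_same_seed_identical_weights(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        m1, _ = elm_fit(X, y, seed=5, node_range=range(1, 8))
        m2, _ = elm_fit(X, y, seed=5, node_range=range(1, 8))
        assert np.array_equal(m1.beta, m2.beta)
        assert m1.n_nodes == m2.n_nodes

    def test_full_capacity_interpolates(self, rng):
        X = rng.uniform(0.0, 1.0, size=(8, 3))
        y = rng.normal(size=8)
        m, _ = elm_fit(X, y, seed=1, node_range=range(8, 9))
        assert np.sqrt(np.mean((m.predict(X) - y) ** 2)) < 1e-6

    def test_default_search_explores_one_to_n(self, rng):
        X = rng.normal(size=(9, 4))
        y = rng.normal(size=9)
        _, cv = elm_fit(X, y, seed=2)
        assert cv.candidates == list(range(1, 10))

    def test_paper_literal_mode_minimises_prediction_rmse(self, rng):
        X = rng.normal(size=(12, 4))
        beta = rng.normal(size=4)
        y = X @ beta
        Xp = rng.normal(size=(6, 4))
        yp = Xp @ beta
        m, cv = elm_fit(X, y, seed=3, selection="rmsep", pred_set=(Xp, yp))
        rmseps = cv.rmsecv
        chosen_idx = cv.candidates.index(cv.chosen)
        assert rmseps[chosen_idx] == rmseps.min()

    def test_empty_node_range_raises(self, rng):
        with pytest.raises(ValueError, match="node"):
            elm_fit(rng.normal(size=(6, 2)), rng.normal(size=6),
                    node_range=range(0))


class TestLOOCV:
    def test_constant_mean_predictor_closed_form(self):
        # predictor = training-fold mean: residual_i = (y_i - ybar) n/(n-1)
        y = np.array([0.0, 1.0, 2.0])
        X = np.zeros((3, 2))

        def fit(Xtr, ytr):
            mean = ytr.mean()
            return lambda Xnew: np.full(len(np.atleast_2d(Xnew)), mean)

        rmsecv, _ = loocv_rmsecv(fit, X, y)
        expected = np.sqrt(np.mean((y - y.mean()) ** 2)) * 3 / 2
        assert np.isclose(rmsecv, expected)

    def test_perfect_linear_data_with_pls(self, rng):
        X = rng.normal(size=(10, 3))
        y = X @ np.array([1.0, 2.0, -1.0]) + 0.5
        rmsecv, _ = loocv_rmsecv(lambda A, b: _pls_fit_fixed(A, b, 3), X, y)
        assert rmsecv < 1e-8

    @pytest.mark.parametrize("engine", ["pls", "lssvm", "elm"])
    def test_matches_naive_double_loop(self, rng, engine):
        X = rng.normal(size=(8, 4))
        y = X @ rng.normal(size=4) + rng.normal(scale=0.2, size=8)
        if engine == "pls":
            fit = lambda A, b: _pls_fit_fixed(A, b, 2)
        elif engine == "lssvm":
            fit = lambda A, b: lssvm_fit(
                A, b, gam_grid=[50.0], sig2_grid=[4.0], refine=False
            )[0]
        else:
            fit = lambda A, b: elm_fit(A, b, seed=4, node_range=range(3, 4))[0]
        rmsecv, preds = loocv_rmsecv(fit, X, y)
        naive = np.empty(8)
        for i in range(8):  # independently written double loop
            keep = [j for j in range(8) if j != i]
            model = fit(X[keep], y[keep])
            naive[i] = model.predict(X[i][None, :])[0]
        assert np.allclose(preds, naive, atol=1e-10)
        assert np.isclose(rmsecv, np.sqrt(np.mean((naive - y) ** 2)))

    def test_order_invariance_of_deterministic_engines(self, rng):
        X = rng.normal(size=(12, 5))
        y = X @ rng.normal(size=5) + rng.normal(scale=0.1, size=12)
        perm = rng.permutation(12)
        m1, _ = pls_fit(X, y, max_lv=4)
        m2, _ = pls_fit(X[perm], y[perm], max_lv=4)
        assert np.allclose(m1.coef, m2.coef, atol=1e-10)
        l1, _ = lssvm_fit(X, y, gam_grid=[10.0], sig2_grid=[2.0], refine=False)
        l2, _ = lssvm_fit(X[perm], y[perm], gam_grid=[10.0], sig2_grid=[2.0],
                          refine=False)
        x_new = rng.normal(size=(3, 5))
        assert np.allclose(l1.predict(x_new), l2.predict(x_new), atol=1e-8)
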