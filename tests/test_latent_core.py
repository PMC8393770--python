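import numpy as np
import pytest

from ibernir.latent_core import (
    CVResult,
    fit_pca,
    fit_pls,
    loo_cv,
    pca_project,
    pls_predict,
    select_components,
)


def _random(n, p, seed=0):
    return np.random.default_rng(seed).standard_normal((n, p))


class TestPCA:
    def test_matches_svd_oracle_up_to_sign(self):
        X = _random(20, 50, seed=1)
        model = fit_pca(X, 5)
        Xc = X - X.mean(axis=0)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        for a in range(5):
            v = Vt[a]
            # orient the oracle loading the same way (largest entry positive)
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(model.loadings[:, a], v, atol=1e-8)
            np.testing.assert_allclose(
                model.explained_variance[a], S[a] ** 2 / 19, rtol=1e-10
            )

    def test_rank_one_matrix_first_component_explains_all(self):
        t = np.array([1.0, -2.0, 0.5, 3.0])
        w = np.array([0.2, 0.5, -0.1])
        model = fit_pca(np.outer(t, w), 1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_full_rank_reconstruction(self):
        X = _random(6, 4, seed=2)
        model = fit_pca(X, 3)
        recon = model.mean + model.scores @ model.loadings.T
        residual = X - recon
        # remaining variance lives in the 4th direction only
        model4 = fit_pca(X, 4)
        recon4 = model4.mean + model4.scores @ model4.loadings.T
        np.testing.assert_allclose(recon4, X, atol=1e-9)
        assert np.linalg.norm(residual) >= np.linalg.norm(X - recon4)

    def test_loadings_orthonormal_scores_orthogonal(self):
        model = fit_pca(_random(15, 30, seed=3), 6)
        np.testing.assert_allclose(
            model.loadings.T @ model.loadings, np.eye(6), atol=1e-8
        )
        G = model.scores.T @ model.scores
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-6)
        assert np.all(np.diff(model.explained_variance) <= 1e-10)

    def test_invalid_component_count(self):
        with pytest.raises(ValueError):
            fit_pca(_random(5, 3), 0)
        with pytest.raises(ValueError):
            fit_pca(_random(5, 3), 5)

    def test_rank_deficiency_warns_and_truncates(self):
        X = np.outer([1.0, 2, 3, 4, 5], [0.3, 0.4, 0.5, 0.6])
        with pytest.warns(UserWarning, match="rank"):
            model = fit_pca(X, 3)
        assert model.A == 1


class TestPCAProject:
    def test_training_data_recovers_training_scores(self):
        X = _random(10, 8, seed=4)
        model = fit_pca(X, 3)
        scores, s_dist, lev = pca_project(model, X)
        np.testing.assert_allclose(scores, model.scores, atol=1e-10)
        assert np.all(lev >= 1.0 / 10 - 1e-12)

    def test_mean_sample_has_zero_scores_and_base_leverage(self):
        X = _random(12, 6, seed=5)
        model = fit_pca(X, 2)
        scores, s_dist, lev = pca_project(model, model.mean[None, :])
        np.testing.assert_allclose(scores, 0, atol=1e-10)
        assert s_dist[0] == pytest.approx(0, abs=1e-10)
        assert lev[0] == pytest.approx(1 / 12, abs=1e-12)

    def test_sample_on_first_loading_has_no_residual(self):
        X = _random(12, 6, seed=6)
        model = fit_pca(X, 2)
        x = model.mean + 2.5 * model.loadings[:, 0]
        scores, s_dist, _ = pca_project(model, x[None, :])
        assert scores[0, 0] == pytest.approx(2.5, abs=1e-10)
        assert scores[0, 1] == pytest.approx(0.0, abs=1e-10)
        assert s_dist[0] == pytest.approx(0, abs=1e-10)

    def test_dimension_mismatch(self):
        model = fit_pca(_random(8, 5), 2)
        with pytest.raises(ValueError, match="column count"):
            pca_project(model, _random(3, 4))


class TestPLS:
    def test_single_latent_direction_fits_exactly(self):
        # X varies along one direction only; its projection drives y
        rng = np.random.default_rng(7)
        t = rng.standard_normal(20)
        p = rng.standard_normal(10)
        X = np.outer(t, p)
        y = X @ np.linspace(-1, 1, 10)
        model = fit_pls(X, y, 1)
        resid = y - pls_predict(model, X, 1)[:, 0]
        assert np.max(np.abs(resid)) < 1e-8

    def test_full_rank_pls_equals_least_squares_oracle(self):
        X = _random(12, 5, seed=8)
        y = _random(12, 1, seed=9)[:, 0]
        model = fit_pls(X, y, 5)
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        X_new = _random(4, 5, seed=10)
        ols_pred = (X_new - X.mean(axis=0)) @ beta + y.mean()
        np.testing.assert_allclose(
            pls_predict(model, X_new, 5)[:, 0], ols_pred, atol=1e-6
        )

    def test_pls2_matches_reference_implementation(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = _random(25, 12, seed=11)
        Y = _random(25, 3, seed=12)
        a = 4
        ours = pls_predict(fit_pls(X, Y, a), X, a)
        ref = sklearn.PLSRegression(
            n_components=a, scale=False, tol=1e-12, max_iter=5000
        ).fit(X, Y)
        np.testing.assert_allclose(ours, ref.predict(X), atol=1e-5)

    def test_constant_response_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_pls(_random(6, 4), np.ones(6), 2)

    def test_scores_mutually_orthogonal(self):
        model = fit_pls(_random(18, 9, seed=13), _random(18, 2, seed=14), 5)
        G = model.T.T @ model.T
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-7)

    def test_predict_at_mean_gives_mean_response(self):
        X = _random(10, 6, seed=15)
        y = _random(10, 1, seed=16)[:, 0]
        model = fit_pls(X, y, 3)
        pred = pls_predict(model, X.mean(axis=0)[None, :], 3)
        assert pred[0, 0] == pytest.approx(y.mean(), abs=1e-10)

    def test_successive_components_change_predictions(self):
        X = _random(15, 8, seed=17)
        y = _random(15, 1, seed=18)[:, 0]
        model = fit_pls(X, y, 4)
        p3 = pls_predict(model, X, 3)
        p4 = pls_predict(model, X, 4)
        assert np.max(np.abs(p3 - p4)) > 1e-8

    def test_component_count_out_of_range(self):
        model = fit_pls(_random(10, 6), _random(10, 1)[:, 0], 3)
        with pytest.raises(ValueError):
            model.coef(4)
        with pytest.raises(ValueError):
            fit_pls(_random(10, 6), _random(10, 1)[:, 0], 10)


class TestLOOCV:
    def test_matches_brute_force_refits(self):
        X = _random(5, 4, seed=19)
        y = _random(5, 1, seed=20)[:, 0]
        cv = loo_cv(X, y, 3)
        for i in range(5):
            mask = np.ones(5, dtype=bool)
            mask[i] = False
            sub = fit_pls(X[mask], y[mask], 3)
            for a in (1, 2, 3):
                expected = pls_predict(sub, X[i], a)[0, 0]
                assert cv.predictions[i, a - 1, 0] == pytest.approx(
                    expected, abs=1e-10
                )

    def test_noiseless_single_direction_is_predicted_perfectly(self):
        rng = np.random.default_rng(21)
        X = np.outer(rng.standard_normal(12), rng.standard_normal(6))
        y = X @ np.arange(1.0, 7.0)
        cv = loo_cv(X, y, 1)
        assert cv.rmsecv[0, 0] < 1e-6 * np.std(y)
        assert cv.one_minus_vr[0, 0] == pytest.approx(1.0, abs=1e-10)

    def test_independent_response_has_no_skill(self):
        # mean cross-validated 1-VR over repeated null draws stays ~<= 0
        rng = np.random.default_rng(22)
        vals = []
        for _ in range(200):
            X = rng.standard_normal((12, 5))
            y = rng.standard_normal(12)
            vals.append(loo_cv(X, y, 2).one_minus_vr[1, 0])
        assert np.mean(vals) < 0.1

    def test_prediction_invariant_to_sample_order(self):
        X = _random(8, 5, seed=23)
        y = _random(8, 1, seed=24)[:, 0]
        cv = loo_cv(X, y, 2)
        perm = np.random.default_rng(25).permutation(8)
        cv_p = loo_cv(X[perm], y[perm], 2)
        np.testing.assert_allclose(
            cv_p.predictions[np.argsort(perm)], cv.predictions, atol=1e-10
        )
        np.testing.assert_allclose(cv_p.rmsecv, cv.rmsecv, atol=1e-12)

    def test_a_max_bound(self):
        with pytest.raises(ValueError, match="n - 2"):
            loo_cv(_random(5, 4), _random(5, 1)[:, 0], 4)


class TestSelectComponents:
    @pytest.mark.parametrize(
        "curve, tol, expected",
        [
            ([0.9, 0.5, 0.498, 0.497], 0.02, 2),
            ([0.3, 0.4, 0.5], 0.02, 1),
            ([0.7], 0.02, 1),
            ([0.9, 0.5, 0.498, 0.497], 0.0, 4),
        ],
    )
    def test_secv_plateau_rule(self, curve, tol, expected):
        assert select_components(np.asarray(curve), tol=tol) == expected

    def test_monotone_in_tolerance(self):
        rng = np.random.default_rng(26)
        for _ in range(20):
            curve = np.abs(rng.standard_normal(8)) + 0.1
            picks = [select_components(curve, t) for t in (0.0, 0.01, 0.05, 0.2)]
            assert all(a >= b for a, b in zip(picks, picks[1:]))

    def test_empty_curve_errors(self):
        with pytest.raises(ValueError, match="empty"):
            select_components(np.array([]))
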