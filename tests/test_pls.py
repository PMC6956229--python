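import numpy as np
import pandas as pd
import pytest

from rollcompact.pls import (
    PLSError, PLSModelState, autoscale, coefficients, cross_validate, fit_pls,
    hotelling_outliers, score_limits, select_components, vip,
)


from _oracles import oracle_predict, svd_pls2


class TestAutoscale:
    def test_round_trip(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 3, (20, 4))
        Xs, stats = autoscale(X)
        assert np.allclose(Xs.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(Xs.std(axis=0, ddof=1), 1, atol=1e-12)
        assert np.allclose(stats.inverse(Xs), X, atol=1e-12)
        assert np.allclose(np.linalg.norm(Xs, axis=0), np.sqrt(len(X) - 1))

    def test_constant_column_named_in_error(self):
        X = np.ones((10, 2))
        X[:, 0] = np.arange(10)
        with pytest.raises(PLSError, match="width"):
            autoscale(X, columns=["length", "width"])


class TestFit:
    def test_one_component_weight_proportional_to_xty(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=(30, 1))
        model = fit_pls(X, y, 1)
        Xs, _ = autoscale(X)
        ys, _ = autoscale(y)
        w_ref = Xs.T @ ys[:, 0]
        w_ref /= np.linalg.norm(w_ref)
        assert np.allclose(np.abs(model.W[:, 0]), np.abs(w_ref), atol=1e-9)

    def test_full_rank_equals_least_squares(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 4))
        Y = rng.normal(size=(40, 2))
        model = fit_pls(X, Y, 4)
        Xs, xs = autoscale(X)
        Ys, ys = autoscale(Y)
        B, *_ = np.linalg.lstsq(Xs, Ys, rcond=None)
        assert np.allclose(model.predict(X), ys.inverse(Xs @ B), atol=1e-8)

    def test_matches_svd_oracle_over_seeds(self):
        """NIPALS predictions agree with the SVD-based oracle to 1e-8 on
        random 20x6 / 20x2 blocks across 50 seeds."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(20, 6))
            Y = rng.normal(size=(20, 2)) + X[:, :2] @ rng.normal(size=(2, 2))
            model = fit_pls(X, Y, 3)
            Xs, xs = autoscale(X)
            Ys, ys = autoscale(Y)
            W, P, C = svd_pls2(Xs, Ys, 3)
            pred_oracle = oracle_predict(X, xs, ys, W, P, C)
            assert np.allclose(model.predict(X), pred_oracle, atol=1e-8)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 6))
        Y = rng.normal(size=(25, 2))
        model = fit_pls(X, Y, 4)
        G = model.T.T @ model.T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() <= 1e-8 * np.diag(G).max()

    def test_missing_cells_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        X[2, 1] = np.nan
        with pytest.raises(PLSError, match="missing"):
            fit_pls(X, np.random.default_rng(1).normal(size=(10, 1)), 1)

    def test_matches_sklearn_predictions(self):
        """Cross-check against scikit-learn's PLSRegression (same NIPALS
        family, Y-aware deflation differences wash out in predictions)."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 6))
        Y = X[:, :3] @ rng.normal(size=(3, 2)) + 0.1 * rng.normal(size=(30, 2))
        model = fit_pls(X, Y, 3)
        sk = PLSRegression(n_components=3, scale=True, tol=1e-12,
                           max_iter=2000).fit(X, Y)
        assert np.allclose(model.predict(X), sk.predict(X), atol=1e-6)


class TestVIP:
    def test_mean_square_is_one(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 7))
        Y = rng.normal(size=(30, 2))
        model = fit_pls(X, Y, 3)
        v = vip(model)
        assert np.mean(v**2) == pytest.approx(1.0, abs=1e-10)
        assert np.sum(v**2) == pytest.approx(7.0, abs=1e-8)

    def test_symmetric_predictors_have_unit_vip(self):
        # p interchangeable predictors of equal relevance -> all VIP = 1
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(400, 4))
        y = Z.sum(axis=1, keepdims=True)
        model = fit_pls(Z, y, 1)
        assert np.allclose(vip(model), 1.0, atol=0.15)

    def test_informative_predictor_ranks_first(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(100, 5))
        y = (3.0 * X[:, 0] + 0.1 * rng.normal(size=100)).reshape(-1, 1)
        model = fit_pls(X, y, 2)
        v = vip(model)
        assert np.argmax(v) == 0 and v[0] > 1.0


class TestCrossValidation:
    def test_pure_noise_has_nonpositive_q2(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 5))
        Y = rng.normal(size=(60, 2))
        q2, _ = cross_validate(X, Y, 3, seed=0)
        assert (q2 <= 0.05).all()   # no predictable variance

    def test_noiseless_linear_map_reaches_high_q2(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 5))
        Y = X @ rng.normal(size=(5, 2))
        q2, _ = cross_validate(X, Y, 5, seed=0)
        assert q2[-1] > 0.99

    def test_q2_below_r2(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 6))
        Y = X[:, :3] @ rng.normal(size=(3, 2)) + 0.5 * rng.normal(size=(50, 2))
        for a in (1, 2, 3):
            model = fit_pls(X, Y, a)
            q2, _ = cross_validate(X, Y, a, seed=1)
            assert q2[a - 1] <= model.r2y_cum + 1e-12

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(40, 5))
        Y = rng.normal(size=(40, 2))
        q2a, ra = cross_validate(X, Y, 3, seed=5)
        q2b, rb = cross_validate(X, Y, 3, seed=5)
        assert np.array_equal(q2a, q2b) and np.array_equal(ra, rb)

    def test_too_few_rows_rejected(self):
        with pytest.raises(PLSError):
            cross_validate(np.ones((10, 2)), np.ones((10, 1)), 1, n_folds=7)

    def test_component_selection_stops_at_gain_threshold(self):
        q2 = np.array([0.50, 0.65, 0.655, 0.70])
        assert select_components(q2, gain=0.01) == 2


class TestScoreLimitsAndSerialization:
    def test_hotelling_radius_approaches_chi2(self):
        # standard-normal 2-D scores, large n: ellipse ~ circle sqrt(chi2_0.95(2))
        rng = np.random.default_rng(12)
        n = 20000
        X = rng.normal(size=(n, 2))
        Y = X @ np.array([[1.0], [0.5]]) + 0.1 * rng.normal(size=(n, 1))
        model = fit_pls(X, Y, 2)
        model.T = rng.normal(size=(n, 2))  # exact standard-normal scores
        semi, radius = score_limits(model)
        assert np.allclose(semi, np.sqrt(5.991), rtol=0.05)
        assert radius == pytest.approx(np.sqrt(5.991), rel=0.05)

    def test_degenerate_scores_give_zero_radius(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(30, 3))
        Y = rng.normal(size=(30, 1))
        model = fit_pls(X, Y, 2)
        model.T = np.zeros_like(model.T)
        _, radius = score_limits(model)
        assert radius == 0.0

    def test_outlier_flagging(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(100, 3))
        Y = X @ np.ones((3, 1)) + 0.1 * rng.normal(size=(100, 1))
        model = fit_pls(X, Y, 2)
        model.T[0] = model.T.std(axis=0) * 10  # plant one extreme score
        flags = hotelling_outliers(model)
        assert flags[0] and flags.mean() < 0.2

    def test_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(15)
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        Y = pd.DataFrame(rng.normal(size=(30, 2)), columns=["TS", "SF"])
        model = fit_pls(X, Y, 2)
        path = tmp_path / "model.json"
        model.save(path)
        back = PLSModelState.load(path)
        assert np.allclose(back.predict(X), model.predict(X), atol=1e-12)
        assert back.x_columns == model.x_columns

    def test_coefficient_identity(self):
        rng = np.random.default_rng(16)
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        Y = pd.DataFrame(rng.normal(size=(30, 2)), columns=["TS", "SF"])
        model = fit_pls(X, Y, 3)
        # prediction through B equals prediction through scores x Y-loadings
        Xs = model.x_scaling.transform(X)
        via_b = model.y_scaling.inverse(Xs @ model.b_scaled)
        via_scores = model.y_scaling.inverse((Xs @ model.rotation) @ model.C.T)
        assert np.allclose(via_b, via_scores, atol=1e-10)
        # single predictor, single response reduces to the regression slope
        x1 = X[["a"]]
        y1 = Y[["TS"]]
        m1 = fit_pls(x1, y1, 1)
        slope = np.polyfit(X["a"], Y["TS"], 1)[0]
        raw = coefficients(m1).iloc[0]["coef_raw"]
        assert raw == pytest.approx(slope, rel=1e-10)
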