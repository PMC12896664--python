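"""Fusion, calibrators vs independent oracles, metric identities, Monte-Carlo CV."""

import numpy as np
import pytest

import teanir as tn
from teanir.dataset import ValidationError
from teanir.model import DEFAULT_LAMBDA_GRID, feature_combinations


class TestFuseFeatures:
    def test_width_is_sum_of_block_widths(self, rng):
        a = tn.FeatureBlock(rng.normal(size=(10, 4)), "CARS")
        b = tn.FeatureBlock(rng.normal(size=(10, 6)), "BC")
        fused = tn.fuse_features([a, b])
        assert fused.n_features == 10
        assert fused.provenance == "CARS+BC"

    def test_columns_standardized(self, rng):
        blocks = [tn.FeatureBlock(rng.normal(5, 3, size=(20, 3)), "AFD")]
        fused = tn.fuse_features(blocks)
        np.testing.assert_allclose(fused.X.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(fused.X.std(axis=0), 1, atol=1e-10)

    def test_constant_columns_dropped_with_warning(self, rng):
        X = rng.normal(size=(12, 3))
        X[:, 1] = 4.2
        with pytest.warns(UserWarning):
            fused = tn.fuse_features([tn.FeatureBlock(X, "FFT")])
        assert fused.n_features == 2

    def test_sample_mismatch_rejected(self, rng):
        a = tn.FeatureBlock(rng.normal(size=(10, 2)), "CARS")
        b = tn.FeatureBlock(rng.normal(size=(11, 2)), "BC")
        with pytest.raises(ValidationError):
            tn.fuse_features([a, b])

    def test_combination_enumeration_counts(self):
        combos = list(feature_combinations(["CARS", "BC", "AFD"]))
        assert len(combos) == 7
        assert sum(len(c) == 1 for c in combos) == 3
        assert sum(len(c) == 2 for c in combos) == 3
        assert sum(len(c) == 3 for c in combos) == 1


class TestRidge:
    def test_tiny_lambda_matches_ols_normal_equations(self, rng):
        X = rng.standard_normal((40, 5))
        y = X @ np.array([1.0, -2, 0.5, 3, 0]) + rng.standard_normal(40)
        model = tn.fit_ridge(X, y, lambda_grid=[1e-10])
        Z = (X - X.mean(0)) / X.std(0)
        beta = np.linalg.solve(Z.T @ Z, Z.T @ (y - y.mean()))
        np.testing.assert_allclose(model.coef_, beta, atol=1e-5)

    def test_huge_lambda_shrinks_to_mean_prediction(self, rng):
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30) + 5
        model = tn.fit_ridge(X, y, lambda_grid=[1e12])
        np.testing.assert_allclose(model.predict(X), y.mean(), atol=1e-6)

    def test_duplicated_predictors_share_coefficients(self, rng):
        X = rng.standard_normal((50, 3))
        y = X @ np.array([2.0, -1, 0.5]) + 0.01 * rng.standard_normal(50)
        Xd = np.hstack([X, X[:, :1]])
        model = tn.fit_ridge(Xd, y, lambda_grid=[1.0])
        assert model.coef_[0] == pytest.approx(model.coef_[3], abs=1e-8)

    def test_lambda_selected_from_grid_by_inner_cv(self, rng):
        X = rng.standard_normal((60, 10))
        y = X @ rng.standard_normal(10) + rng.standard_normal(60)
        model = tn.fit_ridge(X, y)
        assert model.lambda_ in DEFAULT_LAMBDA_GRID


def _nipals_pls1(X, y, ncomp):
    """Independent NIPALS oracle for univariate-y PLS regression."""
    X = X - X.mean(0)
    y = y - y.mean()
    Xk, yk = X.copy(), y.copy()
    W, P, Q = [], [], []
    for _ in range(ncomp):
        w = Xk.T @ yk
        w = w / np.linalg.norm(w)
        t = Xk @ w
        p = Xk.T @ t / (t @ t)
        q = yk @ t / (t @ t)
        Xk = Xk - np.outer(t, p)
        yk = yk - q * t
        W.append(w); P.append(p); Q.append(q)
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
    return W @ np.linalg.solve(P.T @ W, Q)


class TestPLSR:
    def test_single_component_univariate_is_simple_regression(self, rng):
        x = rng.standard_normal(30)
        y = 3 * x + rng.standard_normal(30)
        model = tn.fit_plsr(x[:, None], y, max_components=1)
        slope = np.cov(x, y)[0, 1] / np.var(x, ddof=1)
        pred = model.predict(x[:, None])
        np.testing.assert_allclose(pred, y.mean() + slope * (x - x.mean()),
                                   atol=1e-8)

    def test_full_rank_components_fit_noiseless_target_exactly(self, rng):
        X = rng.standard_normal((20, 4))
        y = X @ np.array([1.0, 2, -1, 0.5])
        model = tn.fit_plsr(X, y, max_components=4)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-8)

    def test_regression_vector_matches_nipals_oracle(self, rng):
        X = rng.standard_normal((6, 4))
        y = rng.standard_normal(6)
        from sklearn.cross_decomposition import PLSRegression
        for nc in (1, 2, 3):
            impl = PLSRegression(n_components=nc, scale=False).fit(X, y)
            beta_impl = np.ravel(impl.coef_)
            beta_oracle = _nipals_pls1(X, y, nc)
            np.testing.assert_allclose(beta_impl, beta_oracle, atol=1e-8)


class TestMetrics:
    def test_perfect_prediction(self):
        r2, nrmse, rpd = tn.evaluate_metrics([1, 2, 3], [1, 2, 3])
        assert (r2, nrmse) == (1.0, 0.0) and np.isinf(rpd)

    def test_mean_prediction_gives_zero_r2(self):
        r2, _, _ = tn.evaluate_metrics([1.0, 2, 3], [2.0, 2, 2])
        assert r2 == pytest.approx(0.0)

    def test_hand_computed_example(self):
        ya, yp = [1.0, 2, 3], [1.1, 1.9, 3.2]
        r2, nrmse, rpd = tn.evaluate_metrics(ya, yp)
        rmse = np.sqrt(0.06 / 3)
        assert r2 == pytest.approx(1 - 0.06 / 2, abs=1e-12)
        assert nrmse == pytest.approx(rmse / 2, abs=1e-12)
        spread = np.sqrt(np.sum((np.array(ya) - np.mean(yp)) ** 2) / 2)
        assert rpd == pytest.approx(spread / rmse, abs=1e-12)

    def test_rpd_identity_when_prediction_mean_matches(self, rng):
        ya = rng.normal(5, 2, 40)
        resid = rng.normal(0, 0.5, 40)
        yp = ya + resid - resid.mean()        # forces mean(yp) = mean(ya)
        r2, _, rpd = tn.evaluate_metrics(ya, yp)
        n = len(ya)
        identity = np.sqrt(n / (n - 1)) / np.sqrt(1 - r2)
        assert rpd == pytest.approx(identity, abs=1e-10)

    def test_conventional_rpd_switch(self, rng):
        ya = rng.normal(5, 2, 30)
        yp = ya + rng.normal(0, 0.4, 30)
        _, _, rpd = tn.evaluate_metrics(ya, yp, conventional_rpd=True)
        rmse = np.sqrt(np.mean((ya - yp) ** 2))
        assert rpd == pytest.approx(np.std(ya, ddof=1) / rmse, abs=1e-12)

    def test_zero_mean_actuals_rejected(self):
        with pytest.raises(ValidationError):
            tn.evaluate_metrics([-1.0, 1.0], [0.0, 0.0])


class TestMonteCarloCV:
    def _block(self, X):
        return tn.FeatureBlock(X, "CARS")

    def test_noiseless_linear_target_learned(self, rng):
        X = rng.standard_normal((60, 5))
        y = X @ np.arange(1.0, 6.0) + 10
        res = tn.monte_carlo_cv(self._block(X), y, "rr", folds=5, repeats=3,
                                seed=0)
        assert res.R2_validate > 0.999

    def test_permuted_target_scores_near_zero(self, rng):
        X = rng.standard_normal((80, 5))
        y = rng.permutation(X @ np.ones(5))
        res = tn.monte_carlo_cv(self._block(X), y + 10, "rr", folds=5,
                                repeats=10, seed=1)
        assert res.R2_validate <= 0.05

    def test_same_seed_reproduces_everything(self, rng):
        X = rng.standard_normal((50, 4))
        y = X @ np.ones(4) + rng.standard_normal(50) + 5
        a = tn.monte_carlo_cv(self._block(X), y, "plsr", folds=5, repeats=4,
                              seed=3)
        b = tn.monte_carlo_cv(self._block(X), y, "plsr", folds=5, repeats=4,
                              seed=3)
        assert a.R2_validate == b.R2_validate
        assert a.per_repeat.equals(b.per_repeat)

    def test_leaked_global_selection_is_optimistic_on_noise(self):
        """Sentinel: supervised band-pair selection fitted outside the CV loop
        inflates validation R^2 relative to fold-internal re-extraction."""
        rng = np.random.default_rng(42)
        X = rng.uniform(0.2, 1.0, (120, 40))
        y = rng.normal(5, 1, 120)
        # leaked: selector sees all samples before CV
        sel = tn.BandCombinationFeaturizer(alpha=0.9999).fit(X, y)
        leaked = tn.monte_carlo_cv(tn.FeatureBlock(sel.transform(X), "BC"), y,
                                   "rr", folds=5, repeats=5, seed=0)
        # honest: selector refit inside each training fold
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler
        from teanir.model import RidgeCalibrator
        nested = Pipeline([("bc", tn.BandCombinationFeaturizer(alpha=0.9999)),
                           ("sc", StandardScaler()),
                           ("m", RidgeCalibrator(random_state=0))])
        honest = tn.monte_carlo_cv(tn.FeatureBlock(X, "BC"), y, nested,
                                   folds=5, repeats=5, seed=0)
        assert leaked.R2_validate > honest.R2_validate + 0.05

    def test_repeat_doubling_stability(self, rng):
        X = rng.standard_normal((80, 6))
        y = X @ np.ones(6) + 0.5 * rng.standard_normal(80) + 5
        a = tn.monte_carlo_cv(self._block(X), y, "rr", folds=5, repeats=5, seed=0)
        b = tn.monte_carlo_cv(self._block(X), y, "rr", folds=5, repeats=10, seed=0)
        assert abs(a.R2_validate - b.R2_validate) < 0.02
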