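"""LASSO solver optimality, cross-validation and incremental-R2 contracts."""

import numpy as np
import pandas as pd
import pytest

import methstrata as ms
from methstrata.containers import MethylationMatrix, PhenotypeTable
from methstrata.predict import (
    EpigeneticScore,
    LassoFit,
    compute_score,
    kkt_violation,
    lambda_grid,
    lasso_coordinate_descent,
    lasso_path,
)


def _instance(n, p, seed=0, sparse=10, noise=1.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)
    w = np.zeros(p)
    w[rng.choice(p, min(sparse, p), replace=False)] = rng.standard_normal(
        min(sparse, p))
    y = X @ w + noise * rng.standard_normal(n)
    return X, y


class TestCoordinateDescent:
    def test_lambda_max_gives_zero_model(self):
        X, y = _instance(50, 20, seed=1)
        lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / len(y)
        w, _ = lasso_coordinate_descent(X, y, lam_max * 1.001)
        assert np.all(w == 0)

    def test_unpenalized_limit_matches_ols(self):
        X, y = _instance(120, 15, seed=2)
        w, intercept = lasso_coordinate_descent(X, y, 0.0)
        w_ols, *_ = np.linalg.lstsq(X, y - y.mean(), rcond=None)
        assert np.max(np.abs(w - w_ols)) < 1e-6

    def test_single_predictor_soft_threshold_closed_form(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        x = (x - x.mean()) / x.std()
        y = 0.8 * x + rng.standard_normal(200)
        rho = float(x @ (y - y.mean())) / len(y)
        for lam in (0.05, 0.2, abs(rho) + 0.1):
            w, _ = lasso_coordinate_descent(x[:, None], y, lam)
            expected = np.sign(rho) * max(abs(rho) - lam, 0.0)
            assert w[0] == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("seed,n,p", [(4, 80, 40), (5, 60, 150),
                                          (6, 100, 100)])
    def test_kkt_certificate(self, seed, n, p):
        X, y = _instance(n, p, seed=seed)
        grid = lambda_grid(X, y, n_lambda=20)
        for lam in grid[::5]:
            w, _ = lasso_coordinate_descent(X, y, lam)
            assert kkt_violation(X, y - y.mean(), w, lam) <= 1e-7

    def test_agrees_with_sklearn(self):
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        X, y = _instance(100, 30, seed=7)
        lam = 0.1
        w, _ = lasso_coordinate_descent(X, y, lam)
        ref = sklearn_linear.Lasso(alpha=lam, fit_intercept=True,
                                   tol=1e-10, max_iter=100000).fit(X, y)
        assert np.max(np.abs(w - ref.coef_)) < 1e-5

    def test_negative_lambda_rejected(self):
        X, y = _instance(30, 5)
        with pytest.raises(ValueError):
            lasso_coordinate_descent(X, y, -0.1)

    def test_nonfinite_inputs_rejected(self):
        X, y = _instance(30, 5)
        X[0, 0] = np.inf
        with pytest.raises(ValueError):
            lasso_coordinate_descent(X, y, 0.1)


class TestPath:
    def test_l1_norm_monotone_in_lambda(self):
        X, y = _instance(90, 60, seed=8)
        grid = lambda_grid(X, y, n_lambda=40)
        W = lasso_path(X, y, grid)
        norms = np.abs(W).sum(axis=1)
        assert np.all(np.diff(norms) >= -1e-8)

    def test_dfmax_truncates_but_preserves_head(self):
        X, y = _instance(60, 200, seed=9)
        grid = lambda_grid(X, y, n_lambda=50)
        full = lasso_path(X, y, grid)
        capped = lasso_path(X, y, grid, dfmax=10)
        nnz = (full != 0).sum(axis=1)
        first_over = int(np.argmax(nnz > 10))
        assert np.allclose(full[:first_over + 1], capped[:first_over + 1])


def _fit_cv_inputs(n=160, p=60, seed=10, causal=8, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    ids = [f"cg{j:03d}" for j in range(p)]
    w = np.zeros(p)
    causal_idx = rng.choice(p, causal, replace=False)
    w[causal_idx] = rng.uniform(0.5, 1.5, causal) * rng.choice([-1, 1], causal)
    y = X @ w + noise * rng.standard_normal(n)
    meth = MethylationMatrix(
        pd.DataFrame(X, index=[f"s{i:03d}" for i in range(n)], columns=ids),
        "residualized")
    return meth, pd.Series(y, index=meth.sample_ids), causal_idx, ids


class TestFitLassoCV:
    def test_reproducible_given_folds_seed(self):
        meth, y, *_ = _fit_cv_inputs(noise=1.0)
        f1 = ms.fit_lasso_cv(meth, y, folds_seed=3, n_lambda=30)
        f2 = ms.fit_lasso_cv(meth, y, folds_seed=3, n_lambda=30)
        assert f1.lambda_selected == f2.lambda_selected
        assert f1.weights == f2.weights

    def test_noiseless_sparse_recovery(self):
        meth, y, causal_idx, ids = _fit_cv_inputs(noise=0.0)
        fit = ms.fit_lasso_cv(meth, y, folds_seed=1, n_lambda=60)
        support = set(fit.weights)
        assert {ids[j] for j in causal_idx} <= support
        score = compute_score(fit, meth)
        r2 = np.corrcoef(score.score, y)[0, 1] ** 2
        assert r2 > 0.99

    def test_constant_response_rejected(self):
        meth, y, *_ = _fit_cv_inputs()
        with pytest.raises(ValueError):
            ms.fit_lasso_cv(meth, pd.Series(1.0, index=y.index))

    def test_selected_lambda_on_grid(self):
        meth, y, *_ = _fit_cv_inputs(noise=1.0, seed=11)
        fit = ms.fit_lasso_cv(meth, y, folds_seed=2, n_lambda=25)
        assert fit.lambda_selected in fit.lambda_grid
        assert len(fit.cv_mean_error) == len(fit.lambda_grid) == 25
        assert fit.n_nonzero == len(fit.weights)


class TestScore:
    def _manual_fit(self, ids, weights, intercept=1.0):
        return LassoFit(trait="t", probe_set="ps", probe_ids=ids,
                        intercept=intercept, weights=weights,
                        weights_std=weights, lambda_grid=np.array([0.1]),
                        cv_mean_error=np.array([1.0]), cv_se=np.array([0.1]),
                        lambda_selected=0.1, n_nonzero=len(weights),
                        folds_seed=0, n_train=10)

    def test_score_is_linear_in_probe_values(self):
        meth, y, _, ids = _fit_cv_inputs(n=40)
        fit = self._manual_fit(ids, {ids[0]: 2.0, ids[3]: -1.0})
        s1 = compute_score(fit, meth)
        shifted = meth.values.copy()
        shifted[ids[0]] = shifted[ids[0]] + 0.5
        s2 = compute_score(fit, MethylationMatrix(shifted, "residualized"))
        assert np.allclose(s2.score - s1.score, 2.0 * 0.5)

    def test_zero_weights_constant_intercept(self):
        meth, *_ = _fit_cv_inputs(n=20)
        fit = self._manual_fit(list(meth.probe_ids), {}, intercept=3.5)
        s = compute_score(fit, meth)
        assert np.all(s.score == 3.5)

    def test_missing_probe_error(self):
        meth, y, _, ids = _fit_cv_inputs(n=20)
        fit = self._manual_fit(ids, {"cg999": 1.0})
        with pytest.raises(Exception, match="cg999"):
            compute_score(fit, meth)


def _test_pheno(n=300, seed=12):
    rng = np.random.default_rng(seed)
    data = pd.DataFrame({
        "age": rng.uniform(25, 75, n),
        "sex": rng.integers(0, 2, n),
        "height": rng.normal(170, 8, n),
        "batch": "b0",
    }, index=[f"s{i:03d}" for i in range(n)])
    return data, rng


class TestIncrementalR2:
    def test_matches_independent_two_regression_oracle(self):
        smf = pytest.importorskip("statsmodels.api")
        data, rng = _test_pheno()
        score = rng.standard_normal(len(data))
        y = 0.05 * data["age"] + 0.4 * score + rng.standard_normal(len(data))
        pheno = PhenotypeTable(data.assign(t=y), traits=["t"])
        es = EpigeneticScore(pheno.data.index,
                             pd.Series(score, index=pheno.data.index),
                             "t", "ps", 0.1)
        res = ms.incremental_r2(es, pheno, "t")
        X0 = smf.add_constant(data[["age", "sex"]])
        m0 = smf.OLS(y, X0).fit()
        m1 = smf.OLS(y, X0.assign(score=score)).fit()
        assert res.r2_null == pytest.approx(m0.rsquared, abs=1e-10)
        assert res.r2_full == pytest.approx(m1.rsquared, abs=1e-10)
        assert res.incremental_r2 == pytest.approx(
            m1.rsquared - m0.rsquared, abs=1e-10)
        assert 0 <= res.r2_null <= res.r2_full <= 1

    def test_independent_score_contributes_nothing(self):
        data, rng = _test_pheno(seed=13)
        y = rng.standard_normal(len(data))
        score = rng.standard_normal(len(data))
        pheno = PhenotypeTable(data.assign(t=y), traits=["t"])
        es = EpigeneticScore(pheno.data.index,
                             pd.Series(score, index=pheno.data.index),
                             "t", "ps", 0.1)
        res = ms.incremental_r2(es, pheno, "t")
        assert res.incremental_r2 < 0.03

    def test_constant_score_degenerate_not_error(self):
        data, rng = _test_pheno(seed=14)
        y = rng.standard_normal(len(data))
        pheno = PhenotypeTable(data.assign(t=y), traits=["t"])
        es = EpigeneticScore(pheno.data.index,
                             pd.Series(2.0, index=pheno.data.index),
                             "t", "ps", 0.1)
        res = ms.incremental_r2(es, pheno, "t")
        assert res.degenerate
        assert res.incremental_r2 == 0.0

    def test_age_uses_squared_correlation(self):
        data, rng = _test_pheno(seed=15)
        score = 0.9 * data["age"].to_numpy() + rng.standard_normal(len(data))
        pheno = PhenotypeTable(data, traits=[])
        es = EpigeneticScore(pheno.data.index,
                             pd.Series(score, index=pheno.data.index),
                             "age", "ps", 0.1)
        res = ms.incremental_r2(es, pheno, "age")
        expected = np.corrcoef(score, data["age"])[0, 1] ** 2
        assert res.incremental_r2 == pytest.approx(expected)
        assert res.r2_null == 0.0
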