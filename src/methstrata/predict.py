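"""LASSO methylation scores: training, cross-validation, transfer, incremental R2.

The LASSO objective on standardized features is

    (1 / 2n) ||y - X w||^2 + lambda ||w||_1

solved by cyclic coordinate descent with soft-thresholding, warm starts
along a descending 100-value log-spaced lambda path (ratio 1e-3 from
lambda_max), sequential-strong-rule screening, and a KKT check over all
features before a solution is accepted.  Model selection follows the
minimum mean cross-validated squared error over ten folds; the selected
lambda is refit on the full training sample, coefficients are
back-transformed to the raw probe scale, and the resulting epigenetic
score is evaluated on the test sample as the incremental R2 of

    Full : phenotype ~ age + sex (+ height) + score
    Null : phenotype ~ age + sex (+ height)

For chronological age the R2 is the squared correlation between score and
age, without further covariates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .containers import AlignmentError, MethylationMatrix, PhenotypeTable
from .preprocess import HEIGHT_TRAITS

__all__ = [
    "LassoFit",
    "EpigeneticScore",
    "IncrementalR2Result",
    "lasso_coordinate_descent",
    "lambda_grid",
    "lasso_path",
    "fit_lasso_cv",
    "compute_score",
    "incremental_r2",
    "kkt_violation",
]

KKT_TOL = 1e-7
CD_TOL = 1e-8


@njit(cache=False)
def _cd_pass(X, r, w, vnorm, active, lam, tol, max_iter):  # pragma: no cover
    """Cyclic coordinate descent over ``active`` until max coord change < tol."""
    n = X.shape[0]
    it = 0
    while it < max_iter:
        it += 1
        max_change = 0.0
        for a in range(active.size):
            j = active[a]
            rho = 0.0
            for i in range(n):
                rho += X[i, j] * r[i]
            rho = rho / n + vnorm[j] * w[j]
            if rho > lam:
                wj = (rho - lam) / vnorm[j]
            elif rho < -lam:
                wj = (rho + lam) / vnorm[j]
            else:
                wj = 0.0
            d = wj - w[j]
            if d != 0.0:
                for i in range(n):
                    r[i] -= d * X[i, j]
                w[j] = wj
                ad = abs(d)
                if ad > max_change:
                    max_change = ad
        if max_change < tol:
            break
    return it


def kkt_violation(X: np.ndarray, y: np.ndarray, w: np.ndarray, lam: float) -> float:
    """Worst violation of the LASSO stationarity (subgradient) conditions.

    Zero (up to tolerance) certifies optimality: |x_j'r / n| <= lambda for
    w_j = 0 and x_j'r / n = lambda sign(w_j) for w_j != 0.
    """
    n = len(y)
    r = y - X @ w
    c = X.T @ r / n
    viol_zero = np.maximum(np.abs(c) - lam, 0.0)
    nz = w != 0
    viol = viol_zero.copy()
    viol[nz] = np.abs(c[nz] - lam * np.sign(w[nz]))
    return float(viol.max()) if len(viol) else 0.0


def _solve_one(X, y, r, w, vnorm, lam, ever_active, tol, max_iter,
               strong_mask=None):
    """Solve at one lambda: CD over ever-active set, then add KKT violators.

    Violators are looked for in the strong set first (cheap), and only then
    in all features, so screening never changes the solution.
    """
    n, p = X.shape
    add_tol = max(KKT_TOL, tol)
    while True:
        active = np.flatnonzero(ever_active)
        if active.size:
            _cd_pass(X, r, w, vnorm, active, lam, tol, max_iter)
        c = X.T @ r / n
        viol = (np.abs(c) > lam + add_tol) & ~ever_active
        if strong_mask is not None:
            strong_viol = viol & strong_mask
            if strong_viol.any():
                ever_active |= strong_viol
                continue
        if viol.any():
            ever_active |= viol
            continue
        break
    return w, r


def lasso_coordinate_descent(X: np.ndarray, y: np.ndarray, lam: float,
                             w_init: np.ndarray | None = None,
                             tol: float = CD_TOL,
                             max_iter: int = 100000) -> tuple[np.ndarray, float]:
    """Solve the LASSO at one penalty; returns (weights, intercept).

    ``X`` columns are expected standardized (mean 0, SD 1); ``y`` is
    centered internally, the intercept is its mean.  The returned solution
    satisfies the KKT conditions to ``KKT_TOL``.
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    X = np.asfortranarray(X)
    intercept = float(y.mean())
    yc = y - intercept
    n, p = X.shape
    vnorm = np.einsum("ij,ij->j", X, X) / n
    vnorm = np.where(vnorm > 0, vnorm, 1.0)
    w = np.zeros(p) if w_init is None else np.array(w_init, dtype=float)
    r = yc - X @ w
    ever_active = w != 0
    if not ever_active.any():
        # seed with the most correlated features
        c = np.abs(X.T @ yc / n)
        ever_active = c > lam
        if not ever_active.any() and lam == 0.0:
            ever_active = np.ones(p, dtype=bool)
    w, r = _solve_one(X, yc, r, w, vnorm, lam, ever_active, tol, max_iter)
    return w, intercept


def lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = 100,
                ratio: float = 1e-3) -> np.ndarray:
    """Descending log-spaced grid from lambda_max (all-zero model) down."""
    n = len(y)
    yc = y - y.mean()
    lam_max = float(np.max(np.abs(X.T @ yc)) / n)
    if lam_max <= 0:
        raise ValueError("response is constant: lambda grid undefined")
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def lasso_path(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
               tol: float = CD_TOL, max_iter: int = 100000,
               dfmax: int | None = None) -> np.ndarray:
    """Warm-started solutions along a descending lambda path.

    Uses sequential strong rules for screening, with a full KKT sweep at
    every lambda so screening never changes the solution.  Returns an array
    of shape (len(lambdas), p).

    ``dfmax`` truncates the path once the active set exceeds that many
    features (the saturated tail is never the cross-validation optimum);
    remaining rows repeat the last computed solution.
    """
    X = np.asfortranarray(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    yc = y - y.mean()
    vnorm = np.einsum("ij,ij->j", X, X) / n
    vnorm = np.where(vnorm > 0, vnorm, 1.0)
    W = np.zeros((len(lambdas), p))
    w = np.zeros(p)
    r = yc.copy()
    lam_prev = float(np.max(np.abs(X.T @ yc)) / n)
    for i, lam in enumerate(lambdas):
        c = X.T @ r / n
        strong = np.abs(c) > 2.0 * lam - lam_prev
        w, r = _solve_one(X, yc, r, w, vnorm, lam, (w != 0) | strong,
                          tol, max_iter, strong_mask=strong)
        W[i] = w
        lam_prev = lam
        if dfmax is not None and int(np.count_nonzero(w)) > dfmax:
            W[i + 1:] = w  # saturated: repeat the last solution
            break
    return W


@dataclass
class LassoFit:
    """A cross-validated LASSO predictor for one trait and probe set."""

    trait: str
    probe_set: str
    probe_ids: list[str]
    intercept: float                       # raw-scale intercept
    weights: dict[str, float]              # nonzero raw-scale coefficients
    weights_std: dict[str, float]          # same, on the standardized scale
    lambda_grid: np.ndarray
    cv_mean_error: np.ndarray
    cv_se: np.ndarray
    lambda_selected: float
    n_nonzero: int
    folds_seed: int
    n_train: int

    def __post_init__(self) -> None:
        if not any(np.isclose(self.lambda_selected, self.lambda_grid)):
            raise ValueError("selected lambda not on the grid")


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD so standardized x_j'x_j / n = 1
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def fit_lasso_cv(meth_train: MethylationMatrix, y_train: pd.Series,
                 trait: str = "", probe_set_name: str = "",
                 n_folds: int = 10, folds_seed: int = 0,
                 n_lambda: int = 100, ratio: float = 1e-3,
                 cv_tol: float = 1e-5, dfmax: int | None = None) -> LassoFit:
    """Ten-fold cross-validated LASSO on a probe-set-restricted matrix.

    Samples are assigned to folds by a seeded permutation (sizes equal
    +/- 1); features are standardized within each fold's training portion
    (no leakage), the per-lambda mean squared CV error is minimised, and
    the winning lambda is refit on the full training data.

    Fold paths run at the relaxed tolerance ``cv_tol`` (they only feed the
    CV error curve); the final refit is polished to the tight coordinate
    tolerance and carries a KKT certificate.  ``dfmax`` (default half the
    fold-training size) truncates fold paths once they saturate — the
    overfit tail of the path is never the CV optimum.
    """
    common = meth_train.sample_ids.intersection(y_train.dropna().index)
    if len(common) < n_folds:
        raise ValueError(f"n_train={len(common)} < n_folds={n_folds}")
    X_raw = meth_train.values.loc[common].to_numpy(dtype=float)
    y = y_train.loc[common].to_numpy(dtype=float)
    n, p = X_raw.shape
    if np.var(y) <= 0:
        raise ValueError("constant response")

    Z_full, mean_full, sd_full = _standardize(X_raw)
    grid = lambda_grid(Z_full, y, n_lambda=n_lambda, ratio=ratio)

    if dfmax is None:
        dfmax = max(100, (n - n // n_folds) // 2)
    rng = np.random.default_rng(folds_seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[perm] = np.arange(n) % n_folds
    sq_err = np.zeros((n_folds, len(grid)))
    for f in range(n_folds):
        val = fold_of == f
        if val.sum() < 2 or (~val).sum() < 2:
            raise ValueError(f"fold {f} has fewer than 2 samples")
        Z_tr, mu, sd = _standardize(X_raw[~val])
        y_tr = y[~val]
        W = lasso_path(Z_tr, y_tr, grid, tol=cv_tol, dfmax=dfmax)
        Z_val = (X_raw[val] - mu) / sd
        preds = y_tr.mean() + Z_val @ W.T
        sq_err[f] = np.mean((y[val][:, None] - preds) ** 2, axis=0)
    cv_mean = sq_err.mean(axis=0)
    cv_se = sq_err.std(axis=0, ddof=1) / math.sqrt(n_folds)
    best = int(np.argmin(cv_mean))
    lam_sel = float(grid[best])

    W_full = lasso_path(Z_full, y, grid[: best + 1], tol=cv_tol, dfmax=None)
    w_std, _ = lasso_coordinate_descent(Z_full, y, lam_sel, w_init=W_full[-1])
    nz = np.flatnonzero(w_std)
    probe_ids = [str(c) for c in meth_train.probe_ids]
    w_raw = w_std[nz] / sd_full[nz]
    intercept = float(y.mean() - np.sum(w_raw * mean_full[nz]))
    return LassoFit(
        trait=trait,
        probe_set=probe_set_name,
        probe_ids=probe_ids,
        intercept=intercept,
        weights={probe_ids[j]: float(w_raw[i]) for i, j in enumerate(nz)},
        weights_std={probe_ids[j]: float(w_std[j]) for j in nz},
        lambda_grid=grid,
        cv_mean_error=cv_mean,
        cv_se=cv_se,
        lambda_selected=lam_sel,
        n_nonzero=int(len(nz)),
        folds_seed=folds_seed,
        n_train=n,
    )


@dataclass
class EpigeneticScore:
    """Weighted probe score for a sample set, with fit provenance."""

    sample_ids: pd.Index
    score: pd.Series
    trait: str
    probe_set: str
    lambda_selected: float


def compute_score(fit: LassoFit, meth_test: MethylationMatrix) -> EpigeneticScore:
    """Apply raw-scale coefficients to the corresponding test probes."""
    probes = list(fit.weights)
    missing = [pr for pr in probes if pr not in meth_test.probe_ids]
    if missing:
        raise AlignmentError(
            f"{len(missing)} predictor probes absent from test matrix: "
            f"{missing[:5]}")
    if probes:
        Xt = meth_test.values.loc[:, probes].to_numpy(dtype=float)
        w = np.array([fit.weights[pr] for pr in probes])
        score = fit.intercept + Xt @ w
    else:
        score = np.full(meth_test.n_samples, fit.intercept)
    s = pd.Series(score, index=meth_test.sample_ids)
    return EpigeneticScore(meth_test.sample_ids, s, fit.trait, fit.probe_set,
                           fit.lambda_selected)


@dataclass
class IncrementalR2Result:
    """Null-vs-full R2 decomposition on the test sample."""

    trait: str
    probe_set: str
    r2_null: float
    r2_full: float
    incremental_r2: float
    n_test: int
    degenerate: bool = False


def _ols_r2(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0:
        return 0.0
    return 1.0 - float(np.sum(resid ** 2)) / tss


def incremental_r2(score: EpigeneticScore, pheno: PhenotypeTable, trait: str,
                   use_height: bool | None = None) -> IncrementalR2Result:
    """Incremental R2 of the epigenetic score over a covariate-only model.

    Both models are OLS on the test sample (phenotype ~ age + sex, with
    height added for lung traits); the full model adds the score.  For
    chronological age the R2 is the squared correlation of score and age.
    A constant score yields incremental R2 = 0 with a degeneracy flag.
    """
    if use_height is None:
        use_height = trait.lower() in HEIGHT_TRAITS
    common = pheno.data.index.intersection(score.score.index)
    y = pheno.data.loc[common, trait].astype(float)
    s = score.score.loc[common]
    keep = y.notna() & s.notna()
    y, s = y[keep].to_numpy(), s[keep].to_numpy()
    n_test = len(y)

    if trait == "age":
        if np.std(s) == 0 or np.std(y) == 0:
            return IncrementalR2Result(trait, score.probe_set, 0.0, 0.0, 0.0,
                                       n_test, degenerate=True)
        r2 = float(np.corrcoef(s, y)[0, 1] ** 2)
        return IncrementalR2Result(trait, score.probe_set, 0.0, r2, r2, n_test)

    cov_cols = ["age", "sex"] + (["height"] if use_height else [])
    C = pheno.data.loc[common, cov_cols][keep.to_numpy()].to_numpy(dtype=float)
    X_null = np.column_stack([np.ones(n_test), C])
    r2_null = _ols_r2(X_null, y)
    degenerate = bool(np.std(s) == 0)
    X_full = np.column_stack([X_null, s])
    r2_full = _ols_r2(X_full, y)
    if degenerate:
        r2_full = r2_null
    inc = max(r2_full - r2_null, 0.0)
    return IncrementalR2Result(trait, score.probe_set, r2_null, r2_full, inc,
                               n_test, degenerate=degenerate)
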