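"""Covariate adjustment of probe values and phenotype preparation.

Probe Beta-values are corrected for age, sex and batch by per-probe ordinary
least squares, separately within the training and test samples (the two arms
are never pooled and no coefficients are transferred between them).
Phenotypes are trimmed for outliers at +/- k SDs (single pass, k = 4 by
default) and residualized on age, age-squared and sex (plus height for lung
traits); chronological age is used unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .containers import AlignmentError, MethylationMatrix, PhenotypeTable

__all__ = [
    "residualize_probes",
    "trim_outliers",
    "prepare_phenotype",
    "TrimResult",
    "PreparedTrait",
    "CollinearityError",
]

#: trait names whose preparation and evaluation models include height
HEIGHT_TRAITS = ("fev", "fvc")


class CollinearityError(ValueError):
    """Covariate design matrix is rank deficient."""


def _covariate_design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + age + sex + one-hot batch (first level as reference)."""
    cols: list[np.ndarray] = [np.ones(len(covariates))]
    names = ["intercept"]
    cols.append(covariates["age"].to_numpy(dtype=float))
    names.append("age")
    cols.append(covariates["sex"].to_numpy(dtype=float))
    names.append("sex")
    batch = pd.Categorical(covariates["batch"])
    for level in batch.categories[1:]:
        cols.append((batch == level).astype(float))
        names.append(f"batch[{level}]")
    return np.column_stack(cols), names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = diag < tol
    if bad.any():
        offenders = [names[piv[i]] for i in np.flatnonzero(bad)]
        raise CollinearityError(
            f"covariate design is rank deficient; collinear columns: {offenders}")


def residualize_probes(meth: MethylationMatrix,
                       covariates: pd.DataFrame) -> MethylationMatrix:
    """OLS-adjust every probe for age, sex and batch; returns residuals.

    The input must be a raw Beta matrix; the output has
    ``state="residualized"`` and unbounded values.  Call separately on the
    training and test matrices — adjustment is always within-sample.
    """
    if meth.state != "raw":
        raise ValueError("residualize_probes expects a raw Beta matrix")
    if not meth.sample_ids.equals(covariates.index):
        raise AlignmentError("methylation and covariate sample ids differ")
    X, names = _covariate_design(covariates)
    _check_rank(X, names)
    M = meth.values.to_numpy()
    coef, *_ = np.linalg.lstsq(X, M, rcond=None)
    resid = M - X @ coef
    return MethylationMatrix(
        pd.DataFrame(resid, index=meth.sample_ids, columns=meth.probe_ids),
        state="residualized")


@dataclass
class TrimResult:
    """Outlier-trimmed trait vector with bookkeeping."""

    values: pd.Series
    n_trimmed: int
    mean: float
    sd: float
    threshold: float


def trim_outliers(values: pd.Series | np.ndarray, k: float = 4.0) -> TrimResult:
    """Set values more than ``k`` SDs from the mean to missing (single pass).

    Mean and SD are computed on the non-missing input; the pass is not
    re-iterated.  A zero-SD (constant) vector removes nothing, and
    ``k = inf`` is the identity.
    """
    s = pd.Series(values).astype(float)
    obs = s.dropna()
    if len(obs) == 0:
        raise ValueError("trim_outliers: all values missing")
    mean = float(obs.mean())
    sd = float(obs.std(ddof=1)) if len(obs) > 1 else 0.0
    threshold = k * sd
    out = s.copy()
    if np.isfinite(threshold) and sd > 0:
        mask = (s - mean).abs() > threshold
        out[mask] = np.nan
        n_trimmed = int(mask.sum())
    else:
        n_trimmed = 0
    return TrimResult(out, n_trimmed, mean, sd, threshold)


@dataclass
class PreparedTrait:
    """Residualized trait vector plus a preprocessing log."""

    trait: str
    values: pd.Series  # aligned to retained samples
    n_input: int
    n_dropped_missing: int
    n_trimmed: int
    r2_covariates: float
    adjusted: bool


def prepare_phenotype(pheno: PhenotypeTable, trait: str, k_sd: float = 4.0,
                      use_height: bool | None = None) -> PreparedTrait:
    """Trim and residualize one trait for downstream modelling.

    The trait is trimmed for outliers on its raw values, then regressed on
    age, age-squared and sex (plus height when ``use_height`` — inferred
    from the trait name for FEV/FVC if not given); the residuals are
    returned.  Chronological age is returned untouched.  Samples with
    missing trait or covariate values are dropped listwise.
    """
    if trait not in pheno.traits and trait not in pheno.data.columns:
        raise KeyError(f"unknown trait {trait!r}")
    y = pheno.data[trait].astype(float)
    n_input = len(y)

    if trait == "age":
        obs = y.dropna()
        return PreparedTrait(trait, obs, n_input, n_input - len(obs), 0, 0.0, False)

    if use_height is None:
        use_height = trait.lower() in HEIGHT_TRAITS

    trim = trim_outliers(y, k=k_sd)
    y = trim.values

    cov_cols = ["age", "sex"] + (["height"] if use_height else [])
    for c in cov_cols:
        if c not in pheno.data.columns:
            raise ValueError(f"trait {trait!r} requires covariate {c!r}")
    keep = y.notna()
    for c in cov_cols:
        keep &= pheno.data[c].notna()
    n_dropped = max(int(n_input - keep.sum()) - trim.n_trimmed, 0)
    y = y[keep]
    cov = pheno.data.loc[keep, cov_cols]

    age = cov["age"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(y)), age, age ** 2,
                         cov["sex"].to_numpy(dtype=float)])
    if use_height:
        X = np.column_stack([X, cov["height"].to_numpy(dtype=float)])
    coef, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
    fitted = X @ coef
    resid = y.to_numpy() - fitted
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / tss if tss > 0 else 0.0
    return PreparedTrait(trait, pd.Series(resid, index=y.index),
                         n_input, n_dropped, trim.n_trimmed, r2, True)
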