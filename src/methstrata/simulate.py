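"""Synthetic DNA-methylation cohorts with mQTL, covariate and trait structure.

The generator emulates the statistical structure of array-based blood DNAm
studies: a mixture of hypo-, intermediate- and hypermethylated probes, a
subset of probes whose variation is partly driven by a biallelic cis genetic
variant (an mQTL), additive age / sex / batch effects on probe values, and
quantitative traits whose variance is, by construction, a configurable
proportion attributable to a causal probe subset.

Probe values are generated on a logit-latent scale and mapped through the
inverse logit, which guarantees Beta-values strictly inside (0, 1) and lets
variance fractions (mQTL R-squared, age R-squared, ...) be specified on a
linear scale.  Per-probe dispersions are parameterised by the *target
Beta-scale SD* so the hypo/hyper stratum can be calibrated to a mean SD of
about 0.01 and the intermediate stratum to about 0.03, the orders of
magnitude seen on real blood arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import FEATURE_CATEGORIES, MethylationMatrix, PhenotypeTable

__all__ = [
    "SimulationConfig",
    "TraitSpec",
    "Cohort",
    "CohortArm",
    "ConfigurationError",
    "simulate_probe_annotation",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_methylation",
    "simulate_phenotypes",
    "make_cohort",
]


class ConfigurationError(ValueError):
    """Inconsistent simulation configuration."""


Archetype = Literal["age_like", "complex_like", "biochemical_like"]
CausalPool = Literal["any", "variable", "non_mqtl_variable", "mqtl_variable",
                     "hypo_hyper"]
_POOLS = ("any", "variable", "non_mqtl_variable", "mqtl_variable", "hypo_hyper")


@dataclass
class TraitSpec:
    """Specification of one simulated trait.

    ``h2m`` is the proportion of the trait's non-covariate variance that is
    attributable to DNAm in the generating population.  The ``age_like``
    archetype ignores ``h2m``: chronological age itself is returned as the
    trait, and age already drives a fraction of probes directly, so DNAm can
    capture (essentially) all of its variance.

    ``mqtl_signal_share`` routes that fraction of the causal variance
    through a *concentrated* set of ``n_causal_mqtl`` mQTL probes (large
    per-probe effects), the remainder spreading diffusely over non-mQTL
    probes.  This mirrors the architecture in which genetically controlled
    CpGs carry fewer, larger trait associations while environment-driven
    signal is polygenic across many probes — the total variance per stratum
    stays matched, but sparse methods recover the concentrated part far more
    easily.  ``None`` disables the split (uniform weights over the pool).
    """

    name: str
    archetype: Archetype = "complex_like"
    h2m: float = 0.61
    n_causal: int = 500
    causal_pool: CausalPool = "any"
    covariate_effects: dict = field(default_factory=dict)
    mqtl_signal_share: float | None = None
    n_causal_mqtl: int | None = None

    def __post_init__(self) -> None:
        if self.archetype not in ("age_like", "complex_like", "biochemical_like"):
            raise ConfigurationError(f"unknown archetype {self.archetype!r}")
        if not (0.0 <= self.h2m <= 1.0):
            raise ConfigurationError(f"h2m must be in [0, 1], got {self.h2m}")
        if self.causal_pool not in _POOLS:
            raise ConfigurationError(f"unknown causal pool {self.causal_pool!r}")
        if self.mqtl_signal_share is not None:
            if not (0.0 <= self.mqtl_signal_share <= 1.0):
                raise ConfigurationError("mqtl_signal_share must be in [0, 1]")
            if self.causal_pool not in ("any", "variable"):
                raise ConfigurationError(
                    "mqtl_signal_share needs a pool containing mQTL and "
                    "non-mQTL probes")

    @classmethod
    def complex_like(cls, name: str, h2m: float = 0.61, n_causal: int = 500,
                     **kw) -> "TraitSpec":
        kw.setdefault("causal_pool", "variable")
        kw.setdefault("mqtl_signal_share", 0.5)
        kw.setdefault("n_causal_mqtl", max(5, n_causal // 10))
        return cls(name=name, archetype="complex_like", h2m=h2m,
                   n_causal=n_causal, **kw)

    @classmethod
    def biochemical_like(cls, name: str, h2m: float = 0.441, n_causal: int = 100,
                         **kw) -> "TraitSpec":
        kw.setdefault("causal_pool", "variable")
        kw.setdefault("mqtl_signal_share", 0.5)
        kw.setdefault("n_causal_mqtl", max(5, n_causal // 10))
        return cls(name=name, archetype="biochemical_like", h2m=h2m,
                   n_causal=n_causal, **kw)

    @classmethod
    def age_like(cls, name: str = "age") -> "TraitSpec":
        return cls(name=name, archetype="age_like", h2m=1.0, n_causal=0,
                   causal_pool="any", covariate_effects={})


def _default_traits() -> list[TraitSpec]:
    return [
        TraitSpec.age_like(),
        TraitSpec.complex_like("smoking_like", h2m=0.796, n_causal=150,
                               covariate_effects={"age": 0.015, "sex": 0.2}),
        TraitSpec.complex_like("complex_1", h2m=0.61, n_causal=500,
                               covariate_effects={"age": 0.01, "sex": 0.3}),
        TraitSpec.biochemical_like("biochem_1", h2m=0.441, n_causal=100,
                                   covariate_effects={"age": 0.01, "sex": 0.1}),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator.

    Defaults mirror a two-arm array study: 4450 training and 2578 test
    samples, with roughly 37% of probes hypo- or hypermethylated (mean Beta
    outside the 10-90% band) and half of the probes carrying a reported
    mQTL.  ``mqtl_r2_range`` is the per-probe fraction of (non-covariate)
    latent variance explained by the genotype; most real mQTLs explain well
    under 30% of inter-individual variation, hence the (0.05, 0.30) default.
    """

    n_train: int = 4450
    n_test: int = 2578
    m_probes: int = 20000
    frac_hypo: float = 0.183
    frac_hyper: float = 0.183
    frac_mqtl: float = 0.5
    mqtl_r2_range: tuple[float, float] = (0.05, 0.30)
    maf_range: tuple[float, float] = (0.05, 0.5)
    trait_specs: list[TraitSpec] = field(default_factory=_default_traits)
    batch_count: int = 31
    seed: int = 0

    # demographic model
    age_mean: float = 50.0
    age_sd: float = 12.5
    p_female: float = 0.614
    # target Beta-scale SD ranges per stratum (delta-method calibrated)
    sd_beta_range_hypo_hyper: tuple[float, float] = (0.004, 0.016)
    sd_beta_range_intermediate: tuple[float, float] = (0.01, 0.05)
    # covariate effects on probes (fractions of latent variance)
    frac_age_probes: float = 0.10
    age_r2_range: tuple[float, float] = (0.01, 0.10)
    frac_sex_probes: float = 0.05
    sex_r2_range: tuple[float, float] = (0.005, 0.05)
    batch_shift_sd: float = 0.05
    # genomic feature category probabilities; None means uniform
    feature_probs: dict | None = None
    # optional enrichment of features among the most variable probes
    feature_highvar_probs: dict | None = None
    feature_highvar_frac: float = 0.0
    # P(EWAS-catalog flag | probe class)
    ewas_catalog_probs: dict = field(default_factory=lambda: {
        "variable_mqtl": 0.15,
        "variable_non_mqtl": 0.06,
        "hypo_or_hyper": 0.01,
    })

    def validate(self) -> None:
        for name in ("frac_hypo", "frac_hyper", "frac_mqtl"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.frac_hypo + self.frac_hyper > 1.0:
            raise ConfigurationError(
                f"frac_hypo + frac_hyper = {self.frac_hypo + self.frac_hyper} > 1")
        if min(self.n_train, self.n_test, self.m_probes) < 1:
            raise ConfigurationError("n_train, n_test and m_probes must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        lo, hi = self.mqtl_r2_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ConfigurationError(f"mqtl_r2_range must lie in [0, 1), got {self.mqtl_r2_range}")
        for spec in self.trait_specs:
            if spec.n_causal > self.m_probes:
                raise ConfigurationError(
                    f"trait {spec.name!r}: n_causal={spec.n_causal} > m_probes={self.m_probes}")
        if self.batch_count < 1:
            raise ConfigurationError("batch_count must be >= 1")


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for a named sub-stream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(stream))))


# stream ids of the master seed, fixed so outputs are reproducible
_S_ANNOT, _S_GENO_TR, _S_GENO_TE, _S_COV_TR, _S_COV_TE = 0, 1, 2, 3, 4
_S_METH_TR, _S_METH_TE, _S_PHENO = 5, 6, 7


def _feature_draw(rng: np.random.Generator, m: int,
                  probs: Mapping[str, float] | None) -> np.ndarray:
    cats = np.array(FEATURE_CATEGORIES)
    if probs is None:
        p = np.full(len(cats), 1.0 / len(cats))
    else:
        p = np.array([float(probs.get(c, 0.0)) for c in cats])
        if p.sum() <= 0:
            raise ConfigurationError("feature probabilities sum to zero")
        p = p / p.sum()
    return rng.choice(cats, size=m, p=p)


def simulate_probe_annotation(config: SimulationConfig,
                              rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-probe generative parameters and annotation flags.

    Returns a DataFrame indexed by probe id with QC/mQTL/catalog flags, a
    genomic feature category, and the generative columns ``target_mean``,
    ``target_sd_beta``, ``dispersion_latent``, ``maf``, ``mqtl_r2``,
    ``age_r2`` and ``sex_r2`` consumed by :func:`simulate_methylation`.
    """
    config.validate()
    if rng is None:
        rng = _rng(config.seed, _S_ANNOT)
    m = config.m_probes
    probe_ids = [f"cg{i:08d}" for i in range(m)]

    u = rng.random(m)
    stratum = np.where(u < config.frac_hypo, "hypo",
                       np.where(u < config.frac_hypo + config.frac_hyper,
                                "hyper", "intermediate"))
    target_mean = np.empty(m)
    hypo = stratum == "hypo"
    hyper = stratum == "hyper"
    inter = stratum == "intermediate"
    target_mean[hypo] = rng.uniform(0.02, 0.10, hypo.sum())
    target_mean[hyper] = rng.uniform(0.90, 0.98, hyper.sum())
    target_mean[inter] = rng.uniform(0.12, 0.88, inter.sum())

    target_sd = np.empty(m)
    lo, hi = config.sd_beta_range_hypo_hyper
    target_sd[~inter] = rng.uniform(lo, hi, (~inter).sum())
    lo, hi = config.sd_beta_range_intermediate
    target_sd[inter] = rng.uniform(lo, hi, inter.sum())
    # delta method: SD(Beta) ~= SD(latent) * mu (1 - mu)
    dispersion = target_sd / (target_mean * (1.0 - target_mean))

    mqtl = rng.random(m) < config.frac_mqtl
    maf = np.full(m, np.nan)
    mqtl_r2 = np.full(m, np.nan)
    maf[mqtl] = rng.uniform(*config.maf_range, mqtl.sum())
    mqtl_r2[mqtl] = rng.uniform(*config.mqtl_r2_range, mqtl.sum())

    age_r2 = np.zeros(m)
    age_probes = rng.random(m) < config.frac_age_probes
    age_r2[age_probes] = rng.uniform(*config.age_r2_range, age_probes.sum())
    sex_r2 = np.zeros(m)
    sex_probes = rng.random(m) < config.frac_sex_probes
    sex_r2[sex_probes] = rng.uniform(*config.sex_r2_range, sex_probes.sum())

    feature = _feature_draw(rng, m, config.feature_probs)
    if config.feature_highvar_frac > 0 and config.feature_highvar_probs:
        n_hi = int(round(config.feature_highvar_frac * m))
        if n_hi > 0:
            hi_idx = np.argsort(-target_sd, kind="stable")[:n_hi]
            feature[hi_idx] = _feature_draw(rng, n_hi, config.feature_highvar_probs)

    probe_class = np.where(~inter, "hypo_or_hyper",
                           np.where(mqtl, "variable_mqtl", "variable_non_mqtl"))
    p_cat = np.array([config.ewas_catalog_probs.get(c, 0.0) for c in probe_class])
    ewas = rng.random(m) < p_cat

    ann = pd.DataFrame({
        "on_450k": True,
        "on_epic": True,
        "cross_hybridising": False,
        "polymorphic_target": False,
        "mqtl": mqtl,
        "ewas_catalog": ewas,
        "genomic_feature": feature,
        "stratum": stratum,
        "target_mean": target_mean,
        "target_sd_beta": target_sd,
        "dispersion_latent": dispersion,
        "maf": maf,
        "mqtl_r2": mqtl_r2,
        "age_r2": age_r2,
        "sex_r2": sex_r2,
    }, index=pd.Index(probe_ids, name="probe_id"))
    return ann


def simulate_genotypes(n_samples: int, annotation: pd.DataFrame,
                       config: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Biallelic dosages (0/1/2) for every mQTL-flagged probe.

    One additive cis-variant per mQTL probe; the per-probe allele frequency
    is a probe-level parameter stored in the annotation, so independent
    cohorts drawn from the same annotation share allele frequencies.
    """
    if rng is None:
        rng = _rng(config.seed, _S_GENO_TR)
    if sample_ids is None:
        sample_ids = [f"s{i:06d}" for i in range(n_samples)]
    mqtl_ids = annotation.index[annotation["mqtl"].astype(bool)]
    p = annotation.loc[mqtl_ids, "maf"].to_numpy()
    dosages = rng.binomial(2, p[None, :], size=(n_samples, len(mqtl_ids)))
    return pd.DataFrame(dosages, index=pd.Index(sample_ids, name="sample_id"),
                        columns=mqtl_ids)


def simulate_covariates(n_samples: int, config: SimulationConfig,
                        rng: np.random.Generator,
                        batch_labels: Sequence[str],
                        sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Age, sex, height and batch for one cohort arm."""
    if sample_ids is None:
        sample_ids = [f"s{i:06d}" for i in range(n_samples)]
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n_samples), 18.0, 95.0)
    sex = (rng.random(n_samples) < config.p_female).astype(int)  # 1 = female
    height = 175.0 - 13.0 * sex + rng.normal(0.0, 7.0, n_samples)
    batch = rng.choice(np.asarray(batch_labels, dtype=object), size=n_samples)
    return pd.DataFrame({"age": age, "sex": sex, "height": height, "batch": batch},
                        index=pd.Index(sample_ids, name="sample_id"))


def simulate_methylation(annotation: pd.DataFrame, genotypes: pd.DataFrame,
                         covariates: pd.DataFrame, config: SimulationConfig,
                         rng: np.random.Generator | None = None,
                         return_biological: bool = False):
    """Generate a raw Beta-value matrix from probe-level parameters.

    Latent value per sample i and probe j::

        l_ij = logit(mu_j) + b_g g_ij + b_age age_i + b_sex sex_i
               + batch_shift(batch_i, j) + eps_ij

    Age and sex explain the per-probe fractions ``age_r2``/``sex_r2`` of the
    probe's core latent variance ``dispersion_latent**2``.  The genetic
    component is *additive on top* of the core variance, scaled so the
    genotype explains the fraction ``mqtl_r2`` of the resulting total
    (core + genetic) variance — mQTL probes are therefore systematically
    more variable than their non-mQTL counterparts, as on real arrays,
    where genetic control adds inter-individual spread.  Beta = expit(latent).

    The batch shift is a technical measurement artifact: with
    ``return_biological=True`` a second, batch-free matrix is returned as
    well (same biological draws), which is what traits are generated from.
    """
    if rng is None:
        rng = _rng(config.seed, _S_METH_TR)
    if not genotypes.empty and not genotypes.index.equals(covariates.index):
        from .containers import AlignmentError
        raise AlignmentError("genotype and covariate sample ids differ")

    n = len(covariates)
    m = len(annotation)
    mu = annotation["target_mean"].to_numpy()
    sigma = annotation["dispersion_latent"].to_numpy()
    sigma2 = sigma ** 2

    r2_g = np.nan_to_num(annotation["mqtl_r2"].to_numpy())
    r2_age = annotation["age_r2"].to_numpy()
    r2_sex = annotation["sex_r2"].to_numpy()
    # age/sex shares are carved out of the core variance; cap their sum
    total_cov = r2_age + r2_sex
    scale_down = np.where(total_cov > 0.95, 0.95 / np.maximum(total_cov, 1e-12),
                          1.0)
    r2_age, r2_sex = r2_age * scale_down, r2_sex * scale_down

    latent = np.tile(logit(mu), (n, 1))

    # genotype effects: additive genetic variance sigma2 r2/(1-r2) on top of
    # the core, so the genotype explains r2 of the probe's total variance
    mqtl_mask = annotation["mqtl"].astype(bool).to_numpy()
    if mqtl_mask.any():
        g_ids = annotation.index[mqtl_mask]
        g = genotypes.loc[:, g_ids].to_numpy(dtype=float)
        p = annotation.loc[g_ids, "maf"].to_numpy()
        var_dosage = 2.0 * p * (1.0 - p)
        r2 = r2_g[mqtl_mask]
        var_genetic = sigma2[mqtl_mask] * r2 / (1.0 - r2)
        b_g = np.sqrt(var_genetic / var_dosage)
        latent[:, mqtl_mask] += (g - 2.0 * p[None, :]) * b_g[None, :]

    age_c = covariates["age"].to_numpy() - config.age_mean
    b_age = np.sqrt(r2_age * sigma2) / config.age_sd
    latent += age_c[:, None] * b_age[None, :]

    sex = covariates["sex"].to_numpy(dtype=float)
    var_sex = config.p_female * (1.0 - config.p_female)
    b_sex = np.sqrt(r2_sex * sigma2 / var_sex)
    latent += (sex - config.p_female)[:, None] * b_sex[None, :]

    # probe-specific additive shift per batch (technical, measurement-only)
    batches = pd.Categorical(covariates["batch"])
    shifts = rng.normal(0.0, config.batch_shift_sd, size=(len(batches.categories), m))
    batch_component = shifts[batches.codes, :]

    eps_sd = np.sqrt(np.maximum(1.0 - r2_age - r2_sex, 0.0) * sigma2)
    latent += rng.standard_normal((n, m)) * eps_sd[None, :]

    measured = expit(np.clip(latent + batch_component, -35.0, 35.0))
    meas = MethylationMatrix(
        pd.DataFrame(measured, index=covariates.index, columns=annotation.index),
        state="raw")
    if not return_biological:
        return meas
    biological = expit(np.clip(latent, -35.0, 35.0))
    bio = MethylationMatrix(
        pd.DataFrame(biological, index=covariates.index, columns=annotation.index),
        state="raw")
    return meas, bio


def _causal_pool_ids(annotation: pd.DataFrame, pool: CausalPool) -> pd.Index:
    inter = (annotation["target_mean"] > 0.10) & (annotation["target_mean"] < 0.90)
    mqtl = annotation["mqtl"].astype(bool)
    if pool == "any":
        return annotation.index
    if pool == "variable":
        return annotation.index[inter]
    if pool == "non_mqtl_variable":
        return annotation.index[inter & ~mqtl]
    if pool == "mqtl_variable":
        return annotation.index[inter & mqtl]
    if pool == "hypo_hyper":
        return annotation.index[~inter]
    raise ConfigurationError(f"unknown causal pool {pool!r}")


def simulate_phenotypes(meth: MethylationMatrix, annotation: pd.DataFrame,
                        trait_specs: Sequence[TraitSpec],
                        covariates: pd.DataFrame, config: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        truth: dict | None = None) -> PhenotypeTable:
    """Draw trait values on top of a generated methylation matrix.

    Non-age traits are ``y = sum_j w_j z_j + covariate part + e`` with the
    causal contribution scaled so that its variance over the supplied sample
    is exactly ``h2m`` and ``Var(e) = 1 - h2m`` (the non-covariate variance
    is 1 by construction).  ``z`` are probe values standardized over the
    supplied sample.  The ``age_like`` trait is chronological age itself.

    If ``truth`` is a dict it is filled with per-trait generative components
    (causal ids, weights, genetic values, realized h2m).
    """
    if rng is None:
        rng = _rng(config.seed, _S_PHENO)
    data = covariates.copy()
    traits: list[str] = []
    X = meth.values.to_numpy()
    col_mean = X.mean(axis=0)
    col_sd = X.std(axis=0, ddof=1)
    col_sd = np.where(col_sd > 0, col_sd, 1.0)

    for spec in trait_specs:
        traits.append(spec.name)
        if spec.archetype == "age_like":
            data[spec.name] = covariates["age"].to_numpy()
            if truth is not None:
                truth[spec.name] = {"archetype": "age_like", "h2m_target": None,
                                    "causal_probes": [], "weights": []}
            continue

        pool_ids = _causal_pool_ids(annotation, spec.causal_pool)
        if len(pool_ids) == 0:
            raise ConfigurationError(
                f"trait {spec.name!r}: causal pool {spec.causal_pool!r} is empty")
        if spec.n_causal > len(pool_ids):
            raise ConfigurationError(
                f"trait {spec.name!r}: n_causal={spec.n_causal} exceeds pool "
                f"size {len(pool_ids)}")

        def _component(ids: np.ndarray, var_target: float):
            """Causal contribution with exact sample variance ``var_target``."""
            if len(ids) == 0 or var_target <= 0:
                return np.zeros(X.shape[0]), ids, np.zeros(len(ids))
            idx = meth.probe_ids.get_indexer(ids)
            w = rng.standard_normal(len(ids))
            Z = (X[:, idx] - col_mean[idx]) / col_sd[idx]
            raw = Z @ w
            sd = raw.std(ddof=1)
            scale = math.sqrt(var_target) / sd if sd > 0 else 0.0
            return (raw - raw.mean()) * scale, ids, w * scale

        mqtl_flag = annotation["mqtl"].astype(bool)
        # trait-associated probes are preferentially the variable ones: a
        # probe must vary between individuals to track a varying trait, so
        # causal sampling is weighted by total biological Beta-scale SD
        r2_all = np.nan_to_num(annotation["mqtl_r2"].to_numpy())
        sd_total = pd.Series(
            annotation["target_sd_beta"].to_numpy() / np.sqrt(1.0 - r2_all),
            index=annotation.index)

        def _weights(ids: pd.Index) -> np.ndarray | None:
            w = sd_total.loc[ids].to_numpy()
            return w / w.sum() if w.sum() > 0 else None

        if spec.mqtl_signal_share is None:
            causal = rng.choice(pool_ids.to_numpy(), size=spec.n_causal,
                                replace=False, p=_weights(pool_ids))
            g, causal, w_scaled = _component(causal, spec.h2m)
        else:
            share = spec.mqtl_signal_share
            n_m = spec.n_causal_mqtl
            if n_m is None:
                n_m = max(1, spec.n_causal // 10)
            pool_m = pool_ids[mqtl_flag.loc[pool_ids]]
            pool_nm = pool_ids[~mqtl_flag.loc[pool_ids]]
            n_nm = spec.n_causal - n_m
            if n_m > len(pool_m) or n_nm > len(pool_nm):
                raise ConfigurationError(
                    f"trait {spec.name!r}: causal split ({n_m} mQTL, {n_nm} "
                    f"non-mQTL) exceeds pool sizes ({len(pool_m)}, {len(pool_nm)})")
            # strongly genetically controlled probes are the likelier trait
            # associations: concentrated causal mQTL probes are sampled with
            # probability proportional to their genetic variance share
            r2w = annotation.loc[pool_m, "mqtl_r2"].to_numpy()
            pw = r2w / r2w.sum() if r2w.sum() > 0 else None
            c_m = rng.choice(pool_m.to_numpy(), size=n_m, replace=False, p=pw)
            c_nm = rng.choice(pool_nm.to_numpy(), size=n_nm, replace=False,
                              p=_weights(pool_nm))
            g_m, c_m, w_m = _component(c_m, share * spec.h2m)
            g_nm, c_nm, w_nm = _component(c_nm, (1.0 - share) * spec.h2m)
            g = g_m + g_nm
            sd_g = g.std(ddof=1)
            rescale = math.sqrt(spec.h2m) / sd_g if (sd_g > 0 and spec.h2m > 0) \
                else 0.0
            g = (g - g.mean()) * rescale
            causal = np.concatenate([c_m, c_nm])
            w_scaled = np.concatenate([w_m, w_nm]) * rescale
        e = rng.standard_normal(len(g)) * math.sqrt(max(1.0 - spec.h2m, 0.0))

        cov_part = np.zeros(len(g))
        eff = spec.covariate_effects
        if eff.get("age"):
            cov_part += eff["age"] * (covariates["age"].to_numpy() - config.age_mean)
        if eff.get("sex"):
            cov_part += eff["sex"] * covariates["sex"].to_numpy(dtype=float)
        if eff.get("height"):
            cov_part += eff["height"] * (covariates["height"].to_numpy() - 170.0)

        y = g + e + cov_part
        data[spec.name] = y
        if truth is not None:
            resid = g + e
            realized = float(np.var(g, ddof=1) / np.var(resid, ddof=1))
            truth[spec.name] = {
                "archetype": spec.archetype,
                "h2m_target": spec.h2m,
                "h2m_realized": realized,
                "causal_probes": [str(c) for c in causal],
                "weights": np.asarray(w_scaled).tolist(),
                "sigma_e": math.sqrt(max(1.0 - spec.h2m, 0.0)),
                "genetic_values": g.tolist(),
            }
    return PhenotypeTable(data, traits=traits)


@dataclass
class CohortArm:
    """One arm (training or test) of a simulated cohort."""

    methylation: MethylationMatrix
    phenotypes: PhenotypeTable
    genotypes: pd.DataFrame


@dataclass
class Cohort:
    """Training and test arms sharing probe-level generative parameters."""

    train: CohortArm
    test: CohortArm
    annotation: pd.DataFrame
    truth: dict

    def validate(self) -> None:
        if len(self.train.methylation.sample_ids.intersection(
                self.test.methylation.sample_ids)):
            raise ValueError("train and test sample ids overlap")
        for arm in (self.train, self.test):
            if not arm.methylation.probe_ids.equals(self.annotation.index):
                raise ValueError("annotation does not cover matrix probes")
            arm.methylation.validate()


def make_cohort(config: SimulationConfig) -> Cohort:
    """Simulate independent training and test arms from one configuration.

    Both arms share probe-level parameters (target means, dispersions,
    allele frequencies, causal probes and weights); sample-level draws are
    independent and batch labels are disjoint, mimicking two separately
    processed measurement sets.  Fully reproducible from ``config.seed``.
    """
    config.validate()
    annotation = simulate_probe_annotation(config)

    train_batches = [f"train_b{i:02d}" for i in range(config.batch_count)]
    test_batches = [f"test_b{i:02d}" for i in range(config.batch_count)]
    train_ids = [f"tr{i:06d}" for i in range(config.n_train)]
    test_ids = [f"te{i:06d}" for i in range(config.n_test)]

    cov_tr = simulate_covariates(config.n_train, config, _rng(config.seed, _S_COV_TR),
                                 train_batches, train_ids)
    cov_te = simulate_covariates(config.n_test, config, _rng(config.seed, _S_COV_TE),
                                 test_batches, test_ids)
    gen_tr = simulate_genotypes(config.n_train, annotation, config,
                                _rng(config.seed, _S_GENO_TR), train_ids)
    gen_te = simulate_genotypes(config.n_test, annotation, config,
                                _rng(config.seed, _S_GENO_TE), test_ids)
    meth_tr, bio_tr = simulate_methylation(annotation, gen_tr, cov_tr, config,
                                           _rng(config.seed, _S_METH_TR),
                                           return_biological=True)
    meth_te, bio_te = simulate_methylation(annotation, gen_te, cov_te, config,
                                           _rng(config.seed, _S_METH_TE),
                                           return_biological=True)

    # phenotypes: causal structure shared across arms, drawn on the pooled
    # sample so the population-scale h2m calibration applies to both; traits
    # depend on the batch-free biological values, never the batch artifact
    pooled = MethylationMatrix(pd.concat([bio_tr.values, bio_te.values]), "raw")
    cov_all = pd.concat([cov_tr, cov_te])
    truth: dict = {"config": _config_to_dict(config), "traits": {}}
    pheno_all = simulate_phenotypes(pooled, annotation, config.trait_specs,
                                    cov_all, config, _rng(config.seed, _S_PHENO),
                                    truth=truth["traits"])
    pheno_tr = PhenotypeTable(pheno_all.data.loc[train_ids], pheno_all.traits)
    pheno_te = PhenotypeTable(pheno_all.data.loc[test_ids], pheno_all.traits)

    # record realized h2m per arm from stored generative components
    n_tr = config.n_train
    for name, t in truth["traits"].items():
        if t.get("genetic_values"):
            g = np.asarray(t["genetic_values"])
            for arm, sl in (("train", slice(0, n_tr)), ("test", slice(n_tr, None))):
                ga = g[sl]
                ya = pheno_all.data[name].to_numpy()[sl]
                cov_removed = ya - _covariate_part(config, cov_all.iloc[sl],
                                                  _trait_spec(config, name))
                t[f"h2m_realized_{arm}"] = float(
                    np.var(ga, ddof=1) / np.var(cov_removed, ddof=1))

    cohort = Cohort(
        train=CohortArm(meth_tr, pheno_tr, gen_tr),
        test=CohortArm(meth_te, pheno_te, gen_te),
        annotation=annotation,
        truth=truth,
    )
    cohort.validate()
    return cohort


def _trait_spec(config: SimulationConfig, name: str) -> TraitSpec:
    for spec in config.trait_specs:
        if spec.name == name:
            return spec
    raise KeyError(name)


def _covariate_part(config: SimulationConfig, covariates: pd.DataFrame,
                    spec: TraitSpec) -> np.ndarray:
    part = np.zeros(len(covariates))
    eff = spec.covariate_effects
    if eff.get("age"):
        part += eff["age"] * (covariates["age"].to_numpy() - config.age_mean)
    if eff.get("sex"):
        part += eff["sex"] * covariates["sex"].to_numpy(dtype=float)
    if eff.get("height"):
        part += eff["height"] * (covariates["height"].to_numpy() - 170.0)
    return part


def _config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["trait_specs"] = [asdict(t) for t in config.trait_specs]
    return d
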