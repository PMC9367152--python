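"""End-to-end experiment: simulate -> preprocess -> probe sets -> REML & LASSO
-> sub-sampling nulls -> enrichment, with deterministic seeding throughout.

The orchestrator reproduces, on synthetic data, the comparison of probe
subsets by probe count, mean Beta-value band and mQTL status: for every
(trait, probe set) pair it records a REML variance proportion and an
out-of-sample incremental R2, averages them across traits (excluding the
age-like trait), and summarises relative effect sizes between strata at
matched subset sizes.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import MethylationMatrix, ProbeSet
from .preprocess import prepare_phenotype, residualize_probes
from .predict import compute_score, fit_lasso_cv, incremental_r2
from .probesets import build_probe_sets, compute_probe_stats
from .resample import enrichment_test, subsample_statistic_null
from .simulate import Cohort, SimulationConfig, make_cohort
from .varcomp import build_orm, reml_fit

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment",
           "summarize_relative_effects", "run_stratum_dissociation",
           "dissociation_traits"]

logger = logging.getLogger(__name__)

#: nested subset sizes as fractions of the variable non-mQTL class
DEFAULT_SUBSET_FRACS = (1.0, 0.4, 0.16, 0.08)


@dataclass
class ExperimentConfig:
    """Configuration of one full experiment run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    subset_fracs: tuple[float, ...] = DEFAULT_SUBSET_FRACS
    traits: tuple[str, ...] | None = None  # None = all simulated traits
    run_reml: bool = True
    run_lasso: bool = True
    run_nulls: bool = False
    run_enrichment: bool = True
    n_folds: int = 10
    n_lambda: int = 100
    reml_null_draws: int = 1000
    lasso_null_draws: int = 100
    enrichment_draws: int = 1000
    seed: int | None = None  # overrides sim.seed when set

    def master_seed(self) -> int:
        return self.sim.seed if self.seed is None else self.seed


def _child_seed(master: int, label: str) -> int:
    """Deterministic child seed below 2**31 from a master seed and a label."""
    h = np.random.SeedSequence([int(master), zlib.crc32(label.encode())])
    return int(h.generate_state(1)[0] % (2 ** 31))


@dataclass
class ExperimentReport:
    """All result tables of one experiment, regenerable from config + seed."""

    varcomp_table: pd.DataFrame
    prediction_table: pd.DataFrame
    probeset_table: pd.DataFrame
    varcomp_means: pd.DataFrame
    prediction_means: pd.DataFrame
    relative_effects: pd.DataFrame
    enrichment_table: pd.DataFrame | None
    null_table: pd.DataFrame | None
    config_echo: dict
    seed_registry: dict
    version: str = __version__

    def check_consistency(self) -> None:
        """Cross-set trait averages must equal recomputation from the rows."""
        for table, means, col in ((self.varcomp_table, self.varcomp_means, "prop"),
                                  (self.prediction_table, self.prediction_means,
                                   "incremental_r2")):
            if table.empty or means.empty:
                continue
            sub = table[table["trait"] != "age"]
            recomputed = sub.groupby("probe_set")[col].mean()
            for _, row in means.iterrows():
                expect = recomputed.get(row["probe_set"])
                if expect is None or not np.isclose(expect, row[f"mean_{col}"]):
                    raise AssertionError(
                        f"report average for {row['probe_set']} inconsistent")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.check_consistency()
        self.varcomp_table.to_csv(outdir / "varcomp.tsv", sep="\t", index=False)
        self.prediction_table.to_csv(outdir / "prediction.tsv", sep="\t",
                                     index=False)
        self.probeset_table.to_csv(outdir / "probesets.tsv", sep="\t",
                                   index=False)
        self.varcomp_means.to_csv(outdir / "varcomp_means.tsv", sep="\t",
                                  index=False)
        self.prediction_means.to_csv(outdir / "prediction_means.tsv", sep="\t",
                                     index=False)
        self.relative_effects.to_csv(outdir / "relative_effects.tsv", sep="\t",
                                     index=False)
        if self.enrichment_table is not None:
            self.enrichment_table.to_csv(outdir / "enrichment.tsv", sep="\t",
                                         index=False)
        if self.null_table is not None:
            self.null_table.to_csv(outdir / "nulls.tsv", sep="\t", index=False)
        summary = {"version": self.version, "config": self.config_echo,
                   "seeds": self.seed_registry}
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                        default=str))


def _scaled_sizes(fracs: tuple[float, ...], base: int) -> list[int]:
    sizes = sorted({max(int(round(f * base)), 1) for f in fracs}, reverse=True)
    return sizes


def run_experiment(config: ExperimentConfig,
                   outdir: str | Path | None = None,
                   cohort: Cohort | None = None) -> ExperimentReport:
    """Execute every stage and assemble the experiment report.

    Training data are used for probe statistics, ORMs and LASSO training
    only; evaluation always happens on the held-out test arm.  A supplied
    ``cohort`` skips simulation (it must match ``config.sim``).
    """
    master = config.master_seed()
    sim = config.sim
    if config.seed is not None and sim.seed != config.seed:
        sim = SimulationConfig(**{**sim.__dict__, "seed": config.seed})
    if cohort is None:
        logger.info("simulating cohort (n_train=%d, n_test=%d, m=%d)",
                    sim.n_train, sim.n_test, sim.m_probes)
        cohort = make_cohort(sim)

    train, test = cohort.train, cohort.test
    stats = compute_probe_stats(train.methylation)
    logger.info("residualizing probes (train and test independently)")
    meth_tr = residualize_probes(train.methylation, train.phenotypes.covariates())
    meth_te = residualize_probes(test.methylation, test.phenotypes.covariates())

    base = int((stats.reindex(cohort.annotation.index)
                .assign(mqtl=cohort.annotation["mqtl"])
                .pipe(lambda df: ((df["mean_beta"] > 0.10)
                                  & (df["mean_beta"] < 0.90)
                                  & ~df["mqtl"].astype(bool)))).sum())
    sizes = _scaled_sizes(config.subset_fracs, base)
    probe_sets = build_probe_sets(cohort.annotation, stats, subset_sizes=sizes)
    set_by_name = {s.name: s for s in probe_sets}

    trait_names = list(config.traits) if config.traits else train.phenotypes.traits
    prepared_tr = {t: prepare_phenotype(train.phenotypes, t) for t in trait_names}

    probeset_rows = []
    for s in probe_sets:
        sd = stats.loc[s.probe_ids, "sd_beta"]
        probeset_rows.append({"probe_set": s.name, "n_probes": len(s),
                              "mean_sd": float(sd.mean()) if len(s) else np.nan,
                              "criteria": json.dumps(dict(s.criteria))})
    probeset_table = pd.DataFrame(probeset_rows)

    var_rows, pred_rows = [], []
    orm_cache: dict[tuple[str, bool], object] = {}
    for s in probe_sets:
        if len(s) == 0:
            continue
        # pre-filter probes that became constant after residualization
        res_sd = meth_tr.values[s.probe_ids].std(axis=0, ddof=1)
        usable = [p for p in s.probe_ids if res_sd[p] > 0]
        if len(usable) < len(s):
            logger.warning("set %s: dropped %d zero-SD probes", s.name,
                           len(s) - len(usable))
        work_set = ProbeSet(s.name, dict(s.criteria), usable)

        for t in trait_names:
            # age models use unadjusted probe values: adjusting probes for
            # age would remove the signal under study
            is_age = t == "age"
            mat_tr = train.methylation if is_age else meth_tr
            mat_te = test.methylation if is_age else meth_te
            if config.run_reml:
                key = (s.name, is_age)
                orm = orm_cache.get(key)
                if orm is None:
                    orm = build_orm(mat_tr, work_set, allow_raw=is_age)
                    orm_cache[key] = orm
                y = prepared_tr[t].values.reindex(orm.sample_ids)
                fit = reml_fit(orm, y)
                var_rows.append({"trait": t, "probe_set": s.name,
                                 "n_probes": orm.m_probes, "prop": fit.prop,
                                 "se_prop": fit.se_prop,
                                 "converged": fit.converged,
                                 "boundary": fit.boundary})
            if config.run_lasso:
                seed = _child_seed(master, f"lasso/{s.name}/{t}")
                fit = fit_lasso_cv(mat_tr.subset_probes(usable),
                                   prepared_tr[t].values, trait=t,
                                   probe_set_name=s.name,
                                   n_folds=config.n_folds,
                                   folds_seed=seed,
                                   n_lambda=config.n_lambda)
                score = compute_score(fit, mat_te.subset_probes(usable))
                res = incremental_r2(score, test.phenotypes, t)
                pred_rows.append({"trait": t, "probe_set": s.name,
                                  "n_probes": len(usable),
                                  "n_nonzero": fit.n_nonzero,
                                  "lambda_selected": fit.lambda_selected,
                                  "r2_null": res.r2_null,
                                  "r2_full": res.r2_full,
                                  "incremental_r2": res.incremental_r2,
                                  "n_test": res.n_test})

    varcomp_table = pd.DataFrame(
        var_rows, columns=["trait", "probe_set", "n_probes", "prop", "se_prop",
                           "converged", "boundary"])
    prediction_table = pd.DataFrame(
        pred_rows, columns=["trait", "probe_set", "n_probes", "n_nonzero",
                            "lambda_selected", "r2_null", "r2_full",
                            "incremental_r2", "n_test"])

    # trait-mean rows, excluding the age-like trait as in cross-trait averages
    def _means(table: pd.DataFrame, col: str) -> pd.DataFrame:
        if table.empty:
            return pd.DataFrame(columns=["probe_set", f"mean_{col}", "n_traits"])
        sub = table[table["trait"] != "age"]
        g = sub.groupby("probe_set", sort=False)[col]
        return g.mean().rename(f"mean_{col}").to_frame().assign(
            n_traits=g.count()).reset_index()

    varcomp_means = _means(varcomp_table, "prop")
    prediction_means = _means(prediction_table, "incremental_r2")

    report = ExperimentReport(
        varcomp_table=varcomp_table,
        prediction_table=prediction_table,
        probeset_table=probeset_table,
        varcomp_means=varcomp_means,
        prediction_means=prediction_means,
        relative_effects=pd.DataFrame(),
        enrichment_table=None,
        null_table=None,
        config_echo={"sim": cohort.truth.get("config", {}),
                     "subset_sizes": sizes,
                     "traits": trait_names},
        seed_registry={"master": master,
                       "scheme": "SeedSequence([master, hash(label)])"},
    )
    rel_frames = []
    for a, b in (("mqtl_variable", "non_mqtl_variable"),
                 ("non_mqtl_variable", "hypo_hyper"),
                 ("mqtl_variable", "hypo_hyper")):
        rel_frames.append(summarize_relative_effects(report, a, b))
    report.relative_effects = pd.concat(rel_frames, ignore_index=True) \
        if rel_frames else pd.DataFrame()

    if config.run_enrichment and "non_mqtl_variable" in set_by_name:
        pool = set_by_name["non_mqtl_variable"]
        target_name = f"non_mqtl_variable_top{sizes[-1]}"
        target = set_by_name.get(target_name)
        if target is not None and len(pool) > len(target):
            enr = enrichment_test(target, pool, cohort.annotation,
                                  n_draws=config.enrichment_draws,
                                  seed=_child_seed(master, "enrichment"))
            report.enrichment_table = enr.table.assign(target=enr.target,
                                                       pool=enr.pool)

    if config.run_nulls and config.run_reml and "all_available" in set_by_name:
        null_rows = []
        pool = set_by_name["all_available"]
        for t in trait_names:
            y = prepared_tr[t].values

            def reml_stat(subset: ProbeSet) -> float:
                orm = build_orm(meth_tr, subset)
                return reml_fit(orm, y.reindex(orm.sample_ids)).prop

            for k in sizes:
                if k > len(pool):
                    continue
                obs_row = varcomp_table[
                    (varcomp_table["trait"] == t)
                    & (varcomp_table["probe_set"] == f"non_mqtl_variable_top{k}")]
                if obs_row.empty:
                    continue
                null = subsample_statistic_null(
                    pool, k, config.reml_null_draws, reml_stat,
                    seed=_child_seed(master, f"null/reml/{t}/{k}"),
                    observed=float(obs_row["prop"].iloc[0]),
                    statistic="prop")
                null_rows.append({"trait": t, "statistic": "prop",
                                  "subset_size": k,
                                  "observed": null.observed,
                                  "null_mean": float(null.null_draws.mean()),
                                  "p_empirical": null.p_empirical,
                                  "n_draws": null.n_draws})
        report.null_table = pd.DataFrame(null_rows)

    report.check_consistency()
    if outdir is not None:
        report.write(outdir)
    return report


def dissociation_traits() -> list:
    """Trait panel for the stratum-comparison experiment.

    Three non-age traits with decreasing DNAm variance fractions (a strong
    smoking-like exposure trait, a complex trait and a biochemical trait).
    Causal architectures are deliberately compact — a concentrated mQTL
    component plus a semi-diffuse non-mQTL component of equal total variance
    — so that penalised regression at cohort scale has realistic power while
    the two intermediate-Beta strata carry matched REML signal.
    """
    from .simulate import TraitSpec
    return [
        TraitSpec.complex_like("smoking_like", h2m=0.796, n_causal=40,
                               n_causal_mqtl=10,
                               covariate_effects={"age": 0.015, "sex": 0.2}),
        TraitSpec.complex_like("complex_1", h2m=0.61, n_causal=40,
                               n_causal_mqtl=10,
                               covariate_effects={"age": 0.01, "sex": 0.3}),
        TraitSpec.biochemical_like("biochem_1", h2m=0.441, n_causal=30,
                                   n_causal_mqtl=8,
                                   covariate_effects={"age": 0.01, "sex": 0.1}),
    ]


def run_stratum_dissociation(n_train: int = 1500, n_test: int = 750,
                             m_probes: int = 20000, seed: int = 0,
                             subset_fracs: tuple[float, ...] = DEFAULT_SUBSET_FRACS,
                             n_folds: int = 10, n_lambda: int = 100,
                             traits: list | None = None,
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probe-count / mean-Beta-band / mQTL-status comparison on one cohort.

    Runs REML and LASSO prediction for nested top-k subsets (sizes are
    ``subset_fracs`` of the variable non-mQTL class) of the variable
    non-mQTL and variable mQTL strata, plus the hypo/hyper stratum at the
    largest matched size.  Returns (varcomp table, prediction table) with
    one row per (trait, probe set).
    """
    cfg = SimulationConfig(
        n_train=n_train, n_test=n_test, m_probes=m_probes,
        batch_count=8, seed=seed,
        trait_specs=traits if traits is not None else dissociation_traits())
    cohort = make_cohort(cfg)
    train, test = cohort.train, cohort.test
    stats = compute_probe_stats(train.methylation)
    meth_tr = residualize_probes(train.methylation, train.phenotypes.covariates())
    meth_te = residualize_probes(test.methylation, test.phenotypes.covariates())

    labels = pd.Series(
        np.where((stats["mean_beta"] <= 0.10) | (stats["mean_beta"] >= 0.90),
                 "hypo_hyper",
                 np.where(cohort.annotation["mqtl"].astype(bool),
                          "mqtl_variable", "non_mqtl_variable")),
        index=stats.index)
    base = int((labels == "non_mqtl_variable").sum())
    sizes = _scaled_sizes(subset_fracs, base)

    from .probesets import select_top_variable
    sets: list[ProbeSet] = []
    for cls in ("non_mqtl_variable", "mqtl_variable"):
        pool = [str(p) for p in labels.index[labels == cls]]
        for k in sizes:
            if k <= len(pool):
                sets.append(select_top_variable(
                    stats, pool, k, name=f"{cls}_top{k}",
                    criteria={"class": cls, "rank_by": "sd_beta", "k": k}))
    hh_pool = [str(p) for p in labels.index[labels == "hypo_hyper"]]
    if sizes[0] <= len(hh_pool):
        sets.append(select_top_variable(
            stats, hh_pool, sizes[0], name=f"hypo_hyper_top{sizes[0]}",
            criteria={"class": "hypo_hyper", "rank_by": "sd_beta",
                      "k": sizes[0]}))

    trait_names = [t.name for t in cfg.trait_specs]
    prepared = {t: prepare_phenotype(train.phenotypes, t) for t in trait_names}
    var_rows, pred_rows = [], []
    for s in sets:
        logger.info("stratum comparison: set %s (%d probes)", s.name, len(s))
        orm = build_orm(meth_tr, s)
        sub_tr = meth_tr.subset_probes(s.probe_ids)
        sub_te = meth_te.subset_probes(s.probe_ids)
        for t in trait_names:
            fit = reml_fit(orm, prepared[t].values.reindex(orm.sample_ids))
            var_rows.append({"trait": t, "probe_set": s.name,
                             "class": s.criteria["class"],
                             "n_probes": len(s), "prop": fit.prop,
                             "se_prop": fit.se_prop})
            lfit = fit_lasso_cv(sub_tr, prepared[t].values, trait=t,
                                probe_set_name=s.name, n_folds=n_folds,
                                folds_seed=_child_seed(seed, f"dis/{s.name}/{t}"),
                                n_lambda=n_lambda)
            res = incremental_r2(compute_score(lfit, sub_te),
                                 test.phenotypes, t)
            pred_rows.append({"trait": t, "probe_set": s.name,
                              "class": s.criteria["class"],
                              "n_probes": len(s),
                              "n_nonzero": lfit.n_nonzero,
                              "incremental_r2": res.incremental_r2})
    return pd.DataFrame(var_rows), pd.DataFrame(pred_rows)


def summarize_relative_effects(report: ExperimentReport, class_a: str,
                               class_b: str) -> pd.DataFrame:
    """Ratios of trait-mean estimates between two strata at matched sizes.

    For every subset size present in both strata, the ratio of the mean
    incremental R2 (and of the mean REML proportion) of class_a over
    class_b, averaged across traits; sizes present in only one stratum are
    skipped.  Identical strata give ratios of exactly 1.
    """

    def _sizes(table: pd.DataFrame, cls: str) -> dict[int, float]:
        if table.empty:
            return {}
        col = "incremental_r2" if "incremental_r2" in table.columns else "prop"
        sub = table[(table["trait"] != "age")
                    & table["probe_set"].str.match(f"^{cls}(_top[0-9]+)?$")]
        out = {}
        for name, grp in sub.groupby("probe_set"):
            k = int(grp["n_probes"].iloc[0])
            out[k] = float(grp[col].mean())
        return out

    pred_a = _sizes(report.prediction_table, class_a)
    pred_b = _sizes(report.prediction_table, class_b)
    var_a = _sizes(report.varcomp_table, class_a)
    var_b = _sizes(report.varcomp_table, class_b)

    rows = []
    for k in sorted(set(pred_a) & set(pred_b) | set(var_a) & set(var_b),
                    reverse=True):
        row = {"class_a": class_a, "class_b": class_b, "size": k}
        if k in pred_a and k in pred_b and pred_b[k] != 0:
            row["ratio_incremental_r2"] = pred_a[k] / pred_b[k]
        else:
            row["ratio_incremental_r2"] = np.nan
        if k in var_a and k in var_b and var_b[k] != 0:
            row["ratio_prop"] = var_a[k] / var_b[k]
        else:
            row["ratio_prop"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=["class_a", "class_b", "size",
                                       "ratio_incremental_r2", "ratio_prop"])
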