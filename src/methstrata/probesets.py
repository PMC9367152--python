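"""Per-probe statistics and construction of probe strata and top-k subsets.

Probes passing QC on both the 450K and EPIC arrays form the "all available"
reference pool.  Within it, three classes partition the pool: hypo- or
hypermethylated probes (training-sample mean Beta <= 10% or >= 90%, bounds
inclusive), variable probes with a reported mQTL, and variable probes
without one.  From each class, nested subsets of the most variable probes
(highest training-sample SD) are extracted; an EWAS-catalog set and its
top-k subsets are built alongside.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import MethylationMatrix, ProbeSet, check_annotation

__all__ = [
    "compute_probe_stats",
    "classify_probe",
    "select_top_variable",
    "build_probe_sets",
    "apply_criteria",
    "DEFAULT_SUBSET_SIZES",
    "CLASS_NAMES",
]

logger = logging.getLogger(__name__)

#: array-scale nested subset sizes; scale down for smaller simulations
DEFAULT_SUBSET_SIZES = (115746, 50000, 20000, 10000)

CLASS_NAMES = ("non_mqtl_variable", "mqtl_variable", "hypo_hyper")


def compute_probe_stats(meth: MethylationMatrix) -> pd.DataFrame:
    """Per-probe mean and sample SD (n-1 denominator) of raw Beta-values.

    Probes with fewer than two non-missing observations get an undefined SD
    and are flagged in the ``sd_defined`` column.
    """
    if meth.state != "raw":
        raise ValueError("probe statistics are computed on raw Beta-values")
    if meth.n_samples < 2:
        raise ValueError("need at least 2 samples for probe statistics")
    vals = meth.values
    n_obs = vals.notna().sum(axis=0)
    stats = pd.DataFrame({
        "mean_beta": vals.mean(axis=0),
        "sd_beta": vals.std(axis=0, ddof=1),
        "n_obs": n_obs,
        "sd_defined": n_obs >= 2,
    })
    stats.index.name = "probe_id"
    return stats


def classify_probe(mean_beta, mqtl_flag):
    """Class label(s) from mean Beta and mQTL status (vectorised).

    ``hypo_or_hyper`` for mean Beta <= 0.10 or >= 0.90 (bounds inclusive),
    otherwise ``variable_mqtl`` / ``variable_non_mqtl`` by the mQTL flag.
    """
    mean_beta = np.asarray(mean_beta, dtype=float)
    mqtl_flag = np.asarray(mqtl_flag, dtype=bool)
    if np.any((mean_beta < 0) | (mean_beta > 1)):
        raise ValueError("mean Beta outside [0, 1]")
    out = np.where((mean_beta <= 0.10) | (mean_beta >= 0.90), "hypo_or_hyper",
                   np.where(mqtl_flag, "variable_mqtl", "variable_non_mqtl"))
    return out if out.ndim else out.item()


def _rank_by_sd(stats: pd.DataFrame, pool: Sequence[str]) -> list[str]:
    """Pool probes ordered by descending SD, ties broken by probe id."""
    sub = stats.loc[list(pool)]
    order = np.lexsort((sub.index.to_numpy(), -sub["sd_beta"].to_numpy()))
    return [str(p) for p in sub.index.to_numpy()[order]]


def select_top_variable(stats: pd.DataFrame, pool: Sequence[str], k: int,
                        name: str | None = None,
                        criteria: Mapping[str, object] | None = None) -> ProbeSet:
    """The ``k`` pool probes with the largest SD, ordered by descending SD.

    Ties are broken lexicographically by probe id so the selection is
    deterministic.
    """
    pool = list(pool)
    if k > len(pool):
        raise ValueError(f"requested k={k} exceeds pool size {len(pool)}")
    ranked = _rank_by_sd(stats, pool)[:k]
    if name is None:
        name = f"top{k}"
    if criteria is None:
        criteria = {"rank_by": "sd_beta", "k": k}
    return ProbeSet(name=name, criteria=dict(criteria), probe_ids=ranked)


def _class_masks(annotation: pd.DataFrame, stats: pd.DataFrame) -> dict[str, pd.Series]:
    available = (annotation["on_450k"] & annotation["on_epic"]
                 & ~annotation["cross_hybridising"]
                 & ~annotation["polymorphic_target"]).astype(bool)
    mean_beta = stats["mean_beta"].reindex(annotation.index)
    labels = classify_probe(mean_beta.to_numpy(),
                            annotation["mqtl"].to_numpy(dtype=bool))
    labels = pd.Series(labels, index=annotation.index)
    return {
        "all_available": available,
        "non_mqtl_variable": available & (labels == "variable_non_mqtl"),
        "mqtl_variable": available & (labels == "variable_mqtl"),
        "hypo_hyper": available & (labels == "hypo_or_hyper"),
        "ewas_catalog": available & annotation["ewas_catalog"].astype(bool),
    }


def build_probe_sets(annotation: pd.DataFrame, stats: pd.DataFrame,
                     subset_sizes: Sequence[int] = DEFAULT_SUBSET_SIZES,
                     ) -> list[ProbeSet]:
    """Construct every stratum and nested top-k subset compared downstream.

    Emits, in order: the ``all_available`` reference set; the three classes
    partitioning it (hypo/hyper, variable mQTL, variable non-mQTL); per
    class, nested top-k subsets at ``subset_sizes`` (the first size is
    capped at the class size, later sizes exceeding the class are skipped
    with a warning); and the EWAS-catalog set with top-k subsets at the two
    smallest sizes.  Probe statistics must come from the training sample.
    """
    check_annotation(annotation)
    if not annotation.index.equals(stats.index):
        stats = stats.reindex(annotation.index)
    if stats["mean_beta"].isna().any():
        raise ValueError("statistics missing for some annotated probes")
    masks = _class_masks(annotation, stats)
    if not masks["all_available"].any():
        raise ValueError("no probes pass QC: 'all available probes' is empty")

    sizes = list(subset_sizes)
    sets: list[ProbeSet] = []
    sets.append(ProbeSet("all_available",
                         {"class": "all_available"},
                         [str(p) for p in annotation.index[masks["all_available"]]]))

    for cls in CLASS_NAMES:
        pool = [str(p) for p in annotation.index[masks[cls]]]
        sets.append(ProbeSet(cls, {"class": cls}, pool))
        if not pool:
            logger.warning("class %s is empty; no subsets built", cls)
            continue
        ks = [min(sizes[0], len(pool))] if sizes else []
        for k in sizes[1:]:
            if k > len(pool):
                logger.warning("subset size %d exceeds class %s size %d; skipped",
                               k, cls, len(pool))
            else:
                ks.append(k)
        for k in ks:
            sets.append(select_top_variable(
                stats, pool, k, name=f"{cls}_top{k}",
                criteria={"class": cls, "rank_by": "sd_beta", "k": k}))

    ewas_pool = [str(p) for p in annotation.index[masks["ewas_catalog"]]]
    sets.append(ProbeSet("ewas_catalog", {"class": "ewas_catalog"}, ewas_pool))
    for k in sizes[2:]:
        if k > len(ewas_pool):
            logger.warning("subset size %d exceeds EWAS catalog size %d; skipped",
                           k, len(ewas_pool))
        else:
            sets.append(select_top_variable(
                stats, ewas_pool, k, name=f"ewas_catalog_top{k}",
                criteria={"class": "ewas_catalog", "rank_by": "sd_beta", "k": k}))
    return sets


def apply_criteria(annotation: pd.DataFrame, stats: pd.DataFrame,
                   criteria: Mapping[str, object]) -> list[str]:
    """Re-apply a probe set's recorded criteria; must reproduce it exactly."""
    masks = _class_masks(annotation, stats)
    cls = str(criteria["class"])
    pool = [str(p) for p in annotation.index[masks[cls]]]
    if "k" in criteria:
        return select_top_variable(stats, pool, int(criteria["k"])).probe_ids
    return pool
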