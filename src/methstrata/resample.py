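"""Size-matched sub-sampling nulls, empirical p-values and feature enrichment.

A probe-set statistic (a REML variance proportion, an incremental R2, or any
cheap summary) is compared against its distribution over uniform
without-replacement draws of the same size from a reference pool.  Empirical
p-values use the add-one estimator (r + 1) / (B + 1), whose floor with 1000
draws is 1/1001.  Genomic-feature enrichment compares category counts in a
target set against size-matched draws, with Benjamini-Hochberg adjustment
across categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .containers import ProbeSet

__all__ = [
    "SubsamplingNull",
    "EnrichmentResult",
    "subsample_statistic_null",
    "empirical_p",
    "enrichment_test",
    "bh_fdr",
]

logger = logging.getLogger(__name__)


def _draw_rngs(seed: int, n_draws: int) -> list[np.random.Generator]:
    """Per-draw generators from disjoint spawns of the seed.

    Spawn keys are indexed by draw number, so extending ``n_draws`` later
    reproduces the earlier draws unchanged.
    """
    children = np.random.SeedSequence(seed).spawn(n_draws)
    return [np.random.default_rng(c) for c in children]


def empirical_p(observed: float, null_draws: Sequence[float],
                sidedness: str = "two_sided") -> float:
    """Add-one empirical p-value (r + 1) / (B + 1).

    ``greater`` counts draws >= observed, ``less`` draws <= observed, and
    ``two_sided`` doubles the smaller one-sided value (capped at 1).
    """
    draws = np.asarray(null_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empirical_p needs at least one null draw")
    b = draws.size
    p_greater = (np.sum(draws >= observed) + 1.0) / (b + 1.0)
    p_less = (np.sum(draws <= observed) + 1.0) / (b + 1.0)
    if sidedness == "greater":
        return float(p_greater)
    if sidedness == "less":
        return float(p_less)
    if sidedness == "two_sided":
        return float(min(1.0, 2.0 * min(p_greater, p_less)))
    raise ValueError(f"unknown sidedness {sidedness!r}")


@dataclass
class SubsamplingNull:
    """Null distribution of a probe-set statistic under size-matched draws."""

    statistic: str
    observed: float
    null_draws: np.ndarray
    n_draws: int
    n_failed: int
    subset_size: int
    pool: str
    seed: int
    sidedness: str
    p_empirical: float


def subsample_statistic_null(pool: ProbeSet, k: int, n_draws: int,
                             stat_fn: Callable[[ProbeSet], float],
                             seed: int, observed: float | None = None,
                             statistic: str = "statistic",
                             sidedness: str = "two_sided") -> SubsamplingNull:
    """Evaluate ``stat_fn`` on ``n_draws`` uniform size-``k`` draws from ``pool``.

    ``observed`` is the statistic of the set under test; if None it is
    computed as ``stat_fn(pool)``, which is only meaningful when the pool
    itself is the set under test.  Draws that raise are recorded as failed
    and excluded, with a logged count.
    """
    ids = np.asarray(pool.probe_ids)
    if k > len(ids):
        raise ValueError(f"subset size k={k} exceeds pool size {len(ids)}")
    draws = np.full(n_draws, np.nan)
    n_failed = 0
    for i, rng in enumerate(_draw_rngs(seed, n_draws)):
        sample = rng.choice(ids, size=k, replace=False)
        subset = ProbeSet(name=f"{pool.name}_draw{i}",
                          criteria={"draw": i, "k": k, "pool": pool.name},
                          probe_ids=[str(s) for s in sample])
        try:
            draws[i] = float(stat_fn(subset))
        except Exception as exc:  # noqa: BLE001 - draw failures are data, not bugs
            n_failed += 1
            logger.warning("draw %d failed: %s", i, exc)
    if n_failed:
        logger.warning("%d/%d null draws failed and were excluded",
                       n_failed, n_draws)
    ok = draws[~np.isnan(draws)]
    if observed is None:
        observed = float(stat_fn(pool))
    p = empirical_p(observed, ok, sidedness=sidedness)
    return SubsamplingNull(statistic=statistic, observed=float(observed),
                           null_draws=ok, n_draws=int(ok.size),
                           n_failed=n_failed, subset_size=k, pool=pool.name,
                           seed=seed, sidedness=sidedness, p_empirical=p)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, monotonicity enforced."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr needs at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class EnrichmentResult:
    """Per-category fold enrichment of a target set against a pool null."""

    table: pd.DataFrame  # category, observed, expected, fold_enrichment, p, q
    n_draws: int
    target: str
    pool: str
    seed: int


def enrichment_test(target: ProbeSet, pool: ProbeSet,
                    annotation: pd.DataFrame, n_draws: int = 1000,
                    seed: int = 0,
                    stratify_by: str | None = None) -> EnrichmentResult:
    """Genomic-feature enrichment of ``target`` vs size-matched pool draws.

    Fold enrichment per category is the observed count divided by the mean
    null count; p-values are two-sided add-one empirical, BH-adjusted across
    categories.  By default the null preserves only the set size; pass
    ``stratify_by`` (an annotation column) to preserve its per-stratum
    composition as well.
    """
    target_set = set(target.probe_ids)
    if not target_set.issubset(set(pool.probe_ids)):
        raise ValueError("target probe set is not contained in the pool")
    all_cats = sorted(pd.unique(annotation["genomic_feature"].astype(str)))
    feats = annotation.loc[list(pool.probe_ids), "genomic_feature"]
    cat = pd.Categorical(feats, categories=all_cats)
    codes = cat.codes.to_numpy() if hasattr(cat.codes, "to_numpy") else np.asarray(cat.codes)
    n_cat = len(cat.categories)
    k = len(target.probe_ids)

    tgt_feats = annotation.loc[list(target.probe_ids), "genomic_feature"]
    observed = pd.Series(tgt_feats).value_counts().reindex(cat.categories,
                                                           fill_value=0)

    pool_ids = np.asarray(pool.probe_ids)
    strata = None
    if stratify_by is not None:
        strata_all = annotation.loc[list(pool.probe_ids), stratify_by]
        tgt_strata = annotation.loc[list(target.probe_ids), stratify_by]
        strata = (pd.Categorical(strata_all),
                  pd.Series(tgt_strata).value_counts())

    null_counts = np.zeros((n_draws, n_cat))
    for i, rng in enumerate(_draw_rngs(seed, n_draws)):
        if strata is None:
            idx = rng.choice(len(pool_ids), size=k, replace=False)
        else:
            strat_cat, tgt_counts = strata
            parts = []
            for s, cnt in tgt_counts.items():
                pool_s = np.flatnonzero(np.asarray(strat_cat) == s)
                parts.append(rng.choice(pool_s, size=int(cnt), replace=False))
            idx = np.concatenate(parts)
        null_counts[i] = np.bincount(codes[idx], minlength=n_cat)

    mean_null = null_counts.mean(axis=0)
    rows = []
    for j, category in enumerate(cat.categories):
        obs = int(observed.iloc[j])
        if mean_null[j] == 0 and obs == 0:
            fe, p = np.nan, np.nan
        else:
            fe = obs / mean_null[j] if mean_null[j] > 0 else np.inf
            p = empirical_p(obs, null_counts[:, j], sidedness="two_sided")
        rows.append({"category": category, "observed": obs,
                     "expected": mean_null[j], "fold_enrichment": fe,
                     "p_empirical": p})
    table = pd.DataFrame(rows)
    valid = table["p_empirical"].notna()
    q = np.full(len(table), np.nan)
    if valid.any():
        q[valid.to_numpy()] = bh_fdr(table.loc[valid, "p_empirical"].to_numpy())
    table["q_fdr"] = q
    return EnrichmentResult(table=table, n_draws=n_draws, target=target.name,
                            pool=pool.name, seed=seed)
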