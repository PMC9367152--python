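"""Empirical p-values, sub-sampling nulls, BH-FDR and enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import methstrata as ms
from methstrata.containers import ProbeSet
from methstrata.resample import bh_fdr, empirical_p, subsample_statistic_null


class TestEmpiricalP:
    def test_add_one_floor(self):
        draws = np.arange(999, dtype=float)
        assert empirical_p(2000.0, draws, "greater") == pytest.approx(1 / 1000)

    def test_observed_below_all_draws_greater_sided(self):
        assert empirical_p(-5.0, np.arange(10.0), "greater") == 1.0

    def test_two_sided_at_median_is_one(self):
        draws = np.arange(101, dtype=float)
        assert empirical_p(50.0, draws, "two_sided") == 1.0

    def test_formula_hand_case(self):
        draws = np.array([1.0, 2.0, 3.0, 4.0])
        # 2 draws >= 2.5 -> greater p = 3/5; 2 draws <= 2.5 -> less p = 3/5
        assert empirical_p(2.5, draws, "greater") == pytest.approx(3 / 5)
        assert empirical_p(2.5, draws, "two_sided") == 1.0

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            empirical_p(1.0, [])


class TestSubsamplingNull:
    def _pool(self, m=400, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"cg{j:04d}" for j in range(m)]
        sds = pd.Series(rng.uniform(0.0, 0.1, m), index=ids)
        return ProbeSet("pool", {"class": "pool"}, ids), sds

    def test_null_mean_matches_pool_mean(self):
        pool, sds = self._pool()
        stat = lambda s: float(sds.loc[s.probe_ids].mean())
        null = subsample_statistic_null(pool, 50, 400, stat, seed=1,
                                        observed=stat(pool))
        # expectation of a uniform-subsample mean is the pool mean
        assert null.null_draws.mean() == pytest.approx(float(sds.mean()),
                                                       abs=0.002)

    def test_p_floor_is_one_over_b_plus_one(self):
        pool, sds = self._pool()
        stat = lambda s: float(sds.loc[s.probe_ids].mean())
        null = subsample_statistic_null(pool, 50, 200, stat, seed=2,
                                        observed=10.0, sidedness="greater")
        assert null.p_empirical == pytest.approx(1 / 201)

    def test_draws_prefix_stable_when_extended(self):
        pool, sds = self._pool(seed=3)
        stat = lambda s: float(sds.loc[s.probe_ids].mean())
        short = subsample_statistic_null(pool, 30, 20, stat, seed=7,
                                        observed=0.0)
        long = subsample_statistic_null(pool, 30, 35, stat, seed=7,
                                        observed=0.0)
        assert np.array_equal(short.null_draws, long.null_draws[:20])

    def test_failed_draws_excluded_and_counted(self):
        pool, sds = self._pool(seed=4)
        calls = {"n": 0}

        def flaky(s):
            calls["n"] += 1
            if calls["n"] % 5 == 0:
                raise RuntimeError("boom")
            return float(sds.loc[s.probe_ids].mean())

        null = subsample_statistic_null(pool, 20, 50, flaky, seed=5,
                                        observed=0.05)
        assert null.n_failed == 10
        assert null.n_draws == 40

    def test_oversized_subset_rejected(self):
        pool, sds = self._pool(m=10)
        with pytest.raises(ValueError):
            subsample_statistic_null(pool, 11, 5, lambda s: 0.0, seed=0,
                                     observed=0.0)


class TestBHFDR:
    def test_hand_applied_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        assert np.all(bh_fdr([1.0, 1.0, 1.0]) == 1.0)

    def test_matches_statsmodels(self):
        sm_multi = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(6)
        p = rng.uniform(0.001, 1.0, 40)
        ref = sm_multi.multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_fdr(p), ref, atol=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([])
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1,
                    max_size=30))
    def test_stepup_properties(self, p):
        """q-values never fall below their p, never exceed 1, and keep the
        p-value ordering (monotone step-up)."""
        p = np.asarray(p)
        q = bh_fdr(p)
        assert np.all(q <= 1.0)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=-5, max_value=5),
           st.lists(st.floats(min_value=-5, max_value=5), min_size=1,
                    max_size=50))
    def test_empirical_p_bounds_and_sidedness(self, obs, draws):
        """All p-values live in (0, 1]; the two-sided value is at most twice
        the smaller one-sided value."""
        b = len(draws)
        pg = empirical_p(obs, draws, "greater")
        pl = empirical_p(obs, draws, "less")
        pt = empirical_p(obs, draws, "two_sided")
        for p in (pg, pl, pt):
            assert 1.0 / (b + 1) <= p <= 1.0
        assert pt <= 2.0 * min(pg, pl) + 1e-12


class TestEnrichment:
    def _annotated_pool(self, m=2000, seed=8, categories=None):
        rng = np.random.default_rng(seed)
        cats = categories or ["Body", "Intergenic", "TSS200"]
        ids = [f"cg{j:05d}" for j in range(m)]
        ann = pd.DataFrame({"genomic_feature": rng.choice(cats, m)},
                           index=pd.Index(ids, name="probe_id"))
        return ProbeSet("pool", {}, ids), ann

    def test_uniform_target_fe_near_one(self):
        pool, ann = self._annotated_pool()
        rng = np.random.default_rng(9)
        target = ProbeSet("target", {}, list(
            rng.choice(pool.probe_ids, 300, replace=False)))
        res = ms.enrichment_test(target, pool, ann, n_draws=300, seed=10)
        fe = res.table["fold_enrichment"].dropna()
        assert np.all((fe > 0.8) & (fe < 1.2))
        assert res.table["q_fdr"].min() > 0.05

    def test_single_category_pool_fe_exactly_one(self):
        pool, ann = self._annotated_pool(m=200, categories=["Body"])
        target = ProbeSet("target", {}, pool.probe_ids[:40])
        res = ms.enrichment_test(target, pool, ann, n_draws=50, seed=11)
        row = res.table[res.table["category"] == "Body"].iloc[0]
        assert row["fold_enrichment"] == pytest.approx(1.0)

    def test_category_absent_from_pool_flagged(self):
        pool, ann = self._annotated_pool(m=300)
        # an extra annotated probe outside the pool carries a new category
        extra = pd.DataFrame({"genomic_feature": ["5'UTR"]},
                             index=pd.Index(["cg99999"], name="probe_id"))
        ann_plus = pd.concat([ann, extra])
        target = ProbeSet("target", {}, pool.probe_ids[:30])
        res = ms.enrichment_test(target, pool, ann_plus, n_draws=50, seed=12)
        row = res.table[res.table["category"] == "5'UTR"].iloc[0]
        assert np.isnan(row["fold_enrichment"])

    def test_target_outside_pool_rejected(self):
        pool, ann = self._annotated_pool(m=100)
        target = ProbeSet("target", {}, ["cg_not_in_pool"])
        with pytest.raises(ValueError):
            ms.enrichment_test(target, pool, ann, n_draws=10, seed=0)

    def test_injected_intergenic_concentration_detected(self):
        # simulator places intergenic features on the most variable probes;
        # the top-SD subset must show intergenic FE > 1 at FDR 0.05
        cfg = ms.SimulationConfig(
            n_train=150, n_test=60, m_probes=3000, batch_count=3, seed=21,
            feature_highvar_frac=0.10,
            feature_highvar_probs={"Intergenic": 0.6, "5'UTR": 0.2,
                                   "TSS1500": 0.2},
            trait_specs=[ms.TraitSpec.complex_like("t", n_causal=50)])
        cohort = ms.make_cohort(cfg)
        stats = ms.compute_probe_stats(cohort.train.methylation)
        ann = cohort.annotation
        inter = (stats["mean_beta"] > 0.1) & (stats["mean_beta"] < 0.9)
        pool_ids = [str(p) for p in ann.index[inter & ~ann["mqtl"]]]
        pool = ProbeSet("non_mqtl_variable", {}, pool_ids)
        target = ms.select_top_variable(stats, pool_ids,
                                        max(len(pool_ids) // 10, 50))
        res = ms.enrichment_test(target, pool, ann, n_draws=300, seed=22)
        row = res.table.set_index("category").loc["Intergenic"]
        assert row["fold_enrichment"] > 1.1
        assert row["q_fdr"] < 0.05
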