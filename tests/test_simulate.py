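"""Generator contracts: stratum mixtures, mQTL effects, trait calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import methstrata as ms
from methstrata.simulate import (
    ConfigurationError,
    simulate_genotypes,
    simulate_probe_annotation,
)


def _cfg(**kw) -> ms.SimulationConfig:
    base = dict(n_train=100, n_test=60, m_probes=2000, batch_count=3, seed=1,
                trait_specs=[ms.TraitSpec.complex_like("t", n_causal=50)])
    base.update(kw)
    return ms.SimulationConfig(**base)


class TestAnnotation:
    def test_stratum_fractions_within_binomial_bounds(self):
        # binomial 99% bound for p=0.3, m=10000: 3000 +/- 2.58*sqrt(m p(1-p))
        ann = simulate_probe_annotation(_cfg(m_probes=10000, frac_hypo=0.3,
                                             frac_hyper=0.3, seed=11))
        n_hypo = int((ann["target_mean"] <= 0.10).sum())
        assert 2800 <= n_hypo <= 3200

    def test_no_mqtl_when_fraction_zero(self):
        ann = simulate_probe_annotation(_cfg(frac_mqtl=0.0))
        assert not ann["mqtl"].any()
        geno = simulate_genotypes(50, ann, _cfg(frac_mqtl=0.0))
        assert geno.shape == (50, 0)

    def test_array_scale_hypo_hyper_mix(self):
        # hypo+hyper together are ~36.6% of the probe pool at array scale
        ann = simulate_probe_annotation(_cfg(m_probes=20000, frac_hypo=0.183,
                                             frac_hyper=0.183, seed=2))
        frac = ((ann["target_mean"] <= 0.10) | (ann["target_mean"] >= 0.90)).mean()
        assert abs(frac - 0.366) < 0.02

    @pytest.mark.parametrize("bad", [
        dict(frac_hypo=0.7, frac_hyper=0.6),
        dict(maf_range=(0.0, 0.5)),
        dict(maf_range=(0.1, 0.7)),
        dict(m_probes=0),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            _cfg(**bad).validate()

    def test_n_causal_exceeding_probes_rejected(self):
        cfg = _cfg(trait_specs=[ms.TraitSpec.complex_like("t", n_causal=5000)])
        with pytest.raises(ConfigurationError):
            cfg.validate()


class TestGenotypes:
    def test_dosage_variance_matches_binomial(self):
        cfg = _cfg(maf_range=(0.2, 0.2), frac_mqtl=1.0, m_probes=300)
        ann = simulate_probe_annotation(cfg)
        geno = simulate_genotypes(2000, ann, cfg,
                                  rng=np.random.default_rng(3))
        var = geno.to_numpy().var(axis=0, ddof=1)
        assert abs(var.mean() - 0.32) / 0.32 < 0.1

    def test_symmetric_maf_gives_mean_one(self):
        cfg = _cfg(maf_range=(0.5, 0.5), frac_mqtl=1.0, m_probes=200)
        ann = simulate_probe_annotation(cfg)
        geno = simulate_genotypes(3000, ann, cfg,
                                  rng=np.random.default_rng(4))
        assert abs(geno.to_numpy().mean() - 1.0) < 0.02


class TestMethylation:
    def test_beta_strictly_inside_unit_interval(self, small_cohort):
        for arm in (small_cohort.train, small_cohort.test):
            v = arm.methylation.values.to_numpy()
            assert v.min() > 0.0 and v.max() < 1.0

    def test_stratum_sd_calibration(self, small_cohort):
        # hypo/hyper probes ~0.01 mean SD, intermediate ~0.03
        stats = ms.compute_probe_stats(small_cohort.train.methylation)
        strat = small_cohort.annotation["stratum"]
        sd_hh = stats.loc[strat != "intermediate", "sd_beta"].mean()
        sd_int = stats.loc[strat == "intermediate", "sd_beta"].mean()
        assert sd_hh < sd_int
        assert 0.005 < sd_hh < 0.02
        assert 0.02 < sd_int < 0.045

    def test_mqtl_latent_r2_calibration(self):
        # with no covariate effects, genotype explains the configured share
        cfg = _cfg(n_train=2000, m_probes=150, frac_mqtl=1.0,
                   mqtl_r2_range=(0.15, 0.15), frac_age_probes=0.0,
                   frac_sex_probes=0.0, batch_shift_sd=0.0,
                   trait_specs=[ms.TraitSpec("t", n_causal=20,
                                             causal_pool="mqtl_variable")])
        cohort = ms.make_cohort(cfg)
        latent = logit(cohort.train.methylation.values.to_numpy())
        g = cohort.train.genotypes.to_numpy(dtype=float)
        r2 = []
        for j in range(latent.shape[1]):
            c = np.corrcoef(latent[:, j], g[:, j])[0, 1]
            r2.append(c * c)
        assert abs(np.mean(r2) - 0.15) < 0.03


class TestPhenotypes:
    def test_h2m_realized_near_target(self):
        for seed in (5, 6):
            cfg = _cfg(n_train=1000, n_test=100, m_probes=800, seed=seed,
                       trait_specs=[ms.TraitSpec.complex_like(
                           "c", h2m=0.6, n_causal=200)])
            cohort = ms.make_cohort(cfg)
            realized = cohort.truth["traits"]["c"]["h2m_realized"]
            assert 0.55 <= realized <= 0.65

    def test_h2m_zero_gives_unrelated_trait(self):
        cfg = _cfg(trait_specs=[ms.TraitSpec.complex_like("c", h2m=0.0,
                                                          n_causal=50)])
        cohort = ms.make_cohort(cfg)
        t = cohort.truth["traits"]["c"]
        assert np.allclose(t["weights"], 0.0)
        assert t["h2m_realized"] == 0.0

    def test_h2m_one_is_exact_probe_combination(self):
        cfg = _cfg(trait_specs=[ms.TraitSpec.complex_like(
            "c", h2m=1.0, n_causal=40, covariate_effects={})])
        cohort = ms.make_cohort(cfg)
        t = cohort.truth["traits"]["c"]
        y = np.concatenate([
            cohort.train.phenotypes.data["c"].to_numpy(),
            cohort.test.phenotypes.data["c"].to_numpy()])
        g = np.asarray(t["genetic_values"])
        assert np.allclose(y, g, atol=1e-10)

    def test_age_like_trait_is_chronological_age(self):
        cfg = _cfg(trait_specs=[ms.TraitSpec.age_like("age_trait")])
        cohort = ms.make_cohort(cfg)
        data = cohort.train.phenotypes.data
        assert np.array_equal(data["age_trait"].to_numpy(),
                              data["age"].to_numpy())

    def test_empty_causal_pool_raises(self):
        cfg = _cfg(frac_mqtl=0.0,
                   trait_specs=[ms.TraitSpec("t", causal_pool="mqtl_variable",
                                             n_causal=10,
                                             mqtl_signal_share=None)])
        with pytest.raises(ConfigurationError):
            ms.make_cohort(cfg)

    def test_mqtl_signal_share_split(self):
        cfg = _cfg(n_train=500, m_probes=1000,
                   trait_specs=[ms.TraitSpec.complex_like(
                       "c", h2m=0.6, n_causal=100, n_causal_mqtl=10)])
        cohort = ms.make_cohort(cfg)
        t = cohort.truth["traits"]["c"]
        causal = pd.Index(t["causal_probes"])
        mqtl = cohort.annotation.loc[causal, "mqtl"]
        assert mqtl.sum() == 10
        # concentrated mQTL probes carry larger per-probe weights
        w = np.abs(np.asarray(t["weights"]))
        assert np.mean(w[:10]) > 2 * np.mean(w[10:])


class TestCohort:
    def test_determinism_same_seed(self, small_config, small_cohort):
        again = ms.make_cohort(small_config)
        pd.testing.assert_frame_equal(again.train.methylation.values,
                                      small_cohort.train.methylation.values)
        pd.testing.assert_frame_equal(again.test.phenotypes.data,
                                      small_cohort.test.phenotypes.data)
        pd.testing.assert_frame_equal(again.annotation,
                                      small_cohort.annotation)

    def test_arms_disjoint_and_annotation_covers(self, small_cohort):
        small_cohort.validate()
        tr = small_cohort.train.methylation.sample_ids
        te = small_cohort.test.methylation.sample_ids
        assert len(tr.intersection(te)) == 0

    def test_arms_share_probe_level_parameters(self, small_cohort):
        # realized stratum means agree across arms up to sampling error
        m_tr = small_cohort.train.methylation.values.mean(axis=0)
        m_te = small_cohort.test.methylation.values.mean(axis=0)
        assert np.abs(m_tr - m_te).mean() < 0.01

    def test_batch_labels_disjoint(self, small_cohort):
        btr = set(small_cohort.train.phenotypes.data["batch"])
        bte = set(small_cohort.test.phenotypes.data["batch"])
        assert not btr & bte
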