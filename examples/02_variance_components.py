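"""Estimate the trait variance captured by DNAm with an ORM + REML.

Residualizes probes for age/sex/batch, builds omics relationship matrices
from nested probe subsets of decreasing size, and fits the variance
proportion for a complex trait.  The estimate falls as probes are dropped:
the ORM of a subset can only tag the causal signal its probes carry.
"""

import methstrata as ms

config = ms.SimulationConfig(
    n_train=600, n_test=100, m_probes=4000, batch_count=4, seed=11,
    trait_specs=[ms.TraitSpec.complex_like("complex_1", h2m=0.6,
                                           n_causal=200)])
cohort = ms.make_cohort(config)

meth = ms.residualize_probes(cohort.train.methylation,
                             cohort.train.phenotypes.covariates())
stats = ms.compute_probe_stats(cohort.train.methylation)
trait = ms.prepare_phenotype(cohort.train.phenotypes, "complex_1")

pool = list(meth.probe_ids)
print(f"target h2m = 0.6; n = {meth.n_samples}")
for k in (4000, 1600, 640, 320):
    subset = ms.select_top_variable(stats, pool, k)
    orm = ms.build_orm(meth, subset)
    fit = ms.reml_fit(orm, trait.values)
    print(f"top {k:>5} probes: prop = {fit.prop:.3f} (se {fit.se_prop:.3f})")
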