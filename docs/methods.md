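# Methods

This note documents the models behind `methstrata`: the synthetic cohort
generator, the two estimation methods (ORM/REML variance components and
cross-validated LASSO scores), the resampling machinery, and the numerical
and design choices that were genuinely open.

## Synthetic cohorts

### Probe model

Probe values are generated on a logit-latent scale and mapped through the
inverse logit, which guarantees Beta-values strictly inside (0, 1) and lets
variance fractions be specified linearly.  Per probe *j* and sample *i*:

```
l_ij = logit(μ_j) + b_g·g_ij + b_age·(age_i − 50) + b_sex·(sex_i − p_f)
       + batch_shift(batch_i, j) + ε_ij,          Beta_ij = expit(l_ij)
```

* **Strata.**  Target means μ are drawn from a three-component mixture:
  hypomethylated (μ ∈ [0.02, 0.10], fraction `frac_hypo`, default 0.183),
  hypermethylated (μ ∈ [0.90, 0.98], default 0.183) and intermediate
  (μ ∈ [0.12, 0.88]).  The default hypo+hyper total of 0.366 matches the
  share of a blood EPIC/450K intersection excluded by a 10–90% mean-Beta
  band.
* **Dispersion.**  Rather than asserting a latent-scale distribution, each
  probe receives a *target Beta-scale SD* (hypo/hyper: U(0.004, 0.016),
  mean 0.01; intermediate: U(0.01, 0.05), mean 0.03 — the stratum means
  observed on blood arrays) which is converted to a latent SD by the delta
  method, `σ_j = sd_target / (μ_j(1 − μ_j))`.  The exact within-stratum SD
  distribution is a modelling choice, exposed through config.
* **mQTLs.**  A Bernoulli(`frac_mqtl`, default 0.5) flag assigns each probe
  at most one biallelic additive cis-variant with MAF ~ U(0.05, 0.5) —
  drawn once per probe so independent cohorts share allele frequencies.
  The genetic variance is additive *on top* of the core dispersion and
  scaled so the genotype explains a fraction r² ~ U(0.05, 0.30) of the
  probe's total latent variance.  Consequently mQTL probes are
  systematically more variable than non-mQTL probes, as genetic control
  adds inter-individual spread on real arrays.  Single-variant coding was
  chosen for identifiability of the per-probe r².
* **Covariates.**  Age drives a random 10% of probes (r² ∈ [0.01, 0.10] of
  core variance) and sex 5% (r² ∈ [0.005, 0.05]); batch is a
  probe-specific additive latent shift per batch (SD 0.05).  Batch is a
  *technical* artifact: it enters the measured matrix only, never the
  biological values that traits are generated from.  This matters — a
  batch-structured phenotype component of even ~15% variance concentrates
  enormous variance in a handful of eigendirections and collapses
  single-ORM REML estimates, a failure mode no real phenotype exhibits.

### Traits

Non-age traits are `y = Σ_causal w_j z_j + covariate part + e`, with z the
probe values standardized over the pooled generating sample (batch-free
biological values) and the causal contribution rescaled so its sample
variance is exactly `h2m` while `Var(e) = 1 − h2m` (non-covariate variance
is 1 by construction; realized per-arm h2m is recorded in `Cohort.truth`).
Archetype defaults follow the magnitudes reported for blood DNAm: complex
traits `h2m = 0.61`, biochemical traits `h2m = 0.441`, a smoking-like
exposure trait `h2m ≈ 0.8`.  The age-like trait is chronological age
itself — age drives probes, not vice versa, so a sufficiently large probe
set captures (essentially) all of its variance by construction.

Two biologically motivated asymmetries shape the causal architecture:

* causal probes are sampled with probability proportional to their total
  Beta-scale SD (a probe must vary between individuals to track a varying
  trait), and
* a configurable share of the causal variance (`mqtl_signal_share`,
  default 0.5) is routed through a small number of mQTL probes
  (`n_causal_mqtl`) sampled proportionally to their genetic r², the rest
  spreading diffusely over non-mQTL probes.

The second point encodes the hypothesis that genetically controlled CpGs
carry fewer, larger trait associations (strong mQTLs are likelier to be
reliably measured and trait-associated), while environment-driven signal
is polygenic.  Total causal variance per stratum stays matched — so
variance-component estimates for the two intermediate-Beta strata are
similar — but sparse penalised regression recovers the concentrated mQTL
component far more efficiently than the diffuse one.  This is the
generative mechanism behind the dissociation the pipeline is designed to
exhibit: probe *count* limits both analyses, probe *class* mainly affects
prediction.

### What the simulator does not emulate

No idat intensities, probe-type chemistry, normalization artefacts,
cell-type composition, pedigree structure, missing values, or multi-variant
mQTLs.  Probes are conditionally independent given covariates and
genotypes — there is no spatial co-methylation, so tests passing here say
nothing about LD-like probe correlation structure in real data.

## Preprocessing

Probe Beta-values are residualized per probe on age, sex and one-hot batch
(first level as reference) by OLS, always within an arm (train and test
separately, no coefficient transfer).  Rank-deficient designs raise an
error naming the collinear columns (QR with column pivoting).  Phenotypes
are trimmed at ±4 SD — a single pass using the input mean/SD, since
re-iteration would change the SD and one trimming step is the protocol —
*before* covariate residualization on age, age², sex (plus height for
FEV/FVC-like traits).  Chronological age is never adjusted, and age models
use the unadjusted probe matrix: residualizing probes on age would remove
the very signal under study.  Missing phenotype values are dropped listwise
per trait, not imputed.

## Variance components (ORM + REML)

The ORM is `K = Z Zᵀ / m` with probes standardized to mean 0, SD 1 (n−1
denominator; mean diagonal is exactly (n−1)/n).  Writing total variance
σ²ₜ and `h = σ²ₒ/σ²ₜ`, the covariance is `σ²ₜ (h K + (1−h) I)`; after one
eigendecomposition of K the restricted likelihood profiles out σ²ₜ in
closed form and REML reduces to maximizing a 1-D function of h on [0, 1]:

```
d_i = h λ_i + (1 − h);    β̂ = Σ x̃ᵢỹᵢ/dᵢ / Σ x̃ᵢ²/dᵢ
RSS = Σ (ỹᵢ − β̂x̃ᵢ)²/dᵢ;  σ̂²ₜ = RSS/(n−1)
ℓ(h) = −½[(n−1)·log σ̂²ₜ + Σ log dᵢ + log Σ x̃ᵢ²/dᵢ + (n−1)]
```

with ỹ = Uᵀy, x̃ = Uᵀ1.  With a single relationship matrix this is
mathematically equivalent to iterative AI-REML but is robust and directly
checkable against a grid search of the exposed profile likelihood
(`reml_profile_loglik`).  Bounded scalar optimization (tolerance 1e−6 in
h, 500-evaluation budget) runs on [0, 1−1e−9] — h = 1 is singular for
rank-deficient K — and the returned optimum is compared against both
endpoints.  Fixed effects are limited to an intercept because phenotypes
and probes are pre-residualized.  Standard errors use the numerical
observed information of the profile log-likelihood (central second
difference, step 1e−4; one-sided at a boundary); estimates within 1e−5 of
1 are reported as the boundary value 1 with `boundary=True`, matching the
convention of reporting 100% estimates rather than forcing interior
values.

## LASSO scores and incremental R²

The solver minimises `(1/2n)‖y − Xw‖² + λ‖w‖₁` on standardized features by
cyclic coordinate descent with soft-thresholding, active-set cycling,
sequential strong-rule screening, and a full KKT sweep at every λ so
screening never changes the solution.  A returned solution satisfies the
subgradient conditions to 1e−7.  The path uses 100 log-spaced λ values
from λ_max down to λ_max·1e−3 (the common convention; only the selection
rule — minimum mean ten-fold CV error, MSE loss — is fixed by the
protocol).  Numerical/runtime choices: fold paths run at a relaxed
coordinate tolerance of 1e−5 (they only feed the CV error curve) and stop
once the active set exceeds half the fold-training size (the saturated
tail is never the CV optimum); the final refit at the selected λ is
polished at tolerance 1e−8 and carries the KKT certificate.  Folds are a
seeded permutation with sizes equal ±1; features are standardized within
each fold's training portion (no leakage).

Coefficients are back-transformed to the raw probe scale; scores on the
test arm are `intercept + Σ w_j x_ij` with missing predictor probes a hard
error (no silent zero-imputation).  Evaluation fits two OLS models on raw
test phenotypes — null: age + sex (+ height for lung-function-like
traits); full: + score — and reports `incremental R² = R²_full − R²_null`
(nesting guarantees non-negativity; a constant score yields 0 with a
degeneracy flag).  For age the R² is the squared correlation of score and
age, with no further covariates.  Test phenotypes are used untrimmed by
default; trimming them first is a supported variant via
`trim_outliers`.

## Resampling and enrichment

Sub-sampling nulls draw size-matched probe subsets uniformly without
replacement; each draw uses its own spawned RNG stream keyed by draw
index, so extending the number of draws reproduces earlier draws
unchanged.  Empirical p-values use the add-one estimator (r+1)/(B+1) —
with 1000 draws the floor is 1/1001 ≈ 0.001 — two-sided by doubling the
smaller tail (sidedness recorded; the protocol does not state it).
Enrichment compares per-category genomic-feature counts of a target set
against size-matched draws from its pool (FE = observed / mean null),
with Benjamini–Hochberg adjustment across categories (the field-default
FDR procedure).  The default null preserves only set size; a
stratified-null variant is available but off by default.  REML nulls
default to 1000 draws and prediction nulls to 100; in the orchestrator the
null stage is opt-in because a thousand REML draws is a cluster-scale
computation at full cohort size.

## Orchestration and problem sizes

`run_experiment` chains simulate → residualize → probe stats → probe sets
→ REML and LASSO per (trait, set) → enrichment (→ nulls), with all child
seeds derived from one master seed via `SeedSequence([master,
crc32(label)])`; identical config + seed reproduces every table exactly,
and written reports carry a consistency check that trait-mean rows equal
recomputation from row-level entries.  Trait means exclude the age-like
trait.  Nested subset sizes default to (100%, 40%, 16%, 8%) of the
variable non-mQTL class — the size ratios of the array-scale design — and
the package's own experiments run at desk scale (n ≈ 150–1500 samples,
m ≈ 600–20000 probes); array-scale n and m are accepted but not default.
The stratum-comparison experiment (`run_stratum_dissociation`) uses
n_train = 1500, n_test = 750, m = 20000 with three traits, the largest
configuration the full test suite exercises.

## Known limitations

* GREML-type estimates assume effect sizes i.i.d. across standardized
  probes; the concentrated mQTL architecture deliberately violates this,
  which inflates the sampling variability of stratum-level REML estimates
  beyond their model-based SEs (tolerances in the tests account for this).
* The profile-likelihood SE is a curvature approximation; near boundaries
  it is one-sided and can be conservative.
* Single-pass outlier trimming uses raw-trait moments; trimming after
  covariate adjustment would remove different points (the protocol's
  ordering is trim-then-regress, and that ordering is implemented).
* The CV-error curve is computed under relaxed fold tolerances; λ
  selection can in principle differ from an exact-tolerance path in
  near-tie cases, while the returned fit is always KKT-certified at the
  selected λ.
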