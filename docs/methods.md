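# Methods

## Phenotype model and outcome definition

Closure time (CT, seconds) from a platelet-function analyzer is the
quantitative response; the binary outcome HTPR (high on-treatment platelet
reactivity, i.e. inadequate clopidogrel response) is defined as CT strictly
below 106 s. A CT of exactly 106 s is classified non-HTPR. CT is modelled
as additive:

    CT_j = baseline + Σ_v effect_v · dosage_vj + Σ_c effect_c · covariate_cj + ε_j,
    ε_j ~ N(0, σ²),  CT floored at 0 s.

Gaussian noise is a modelling convenience, not a claim about the measuring
device; the floor at 0 s is the only truncation (no instrument maximum is
imposed). Risk alleles are encoded with negative CT effects (they shorten
closure time, pushing subjects below the threshold).

## Synthetic cohort generator

The generator emulates a small clinical pharmacogenomics study: 69
subjects, 98 biallelic variants with alternate-allele frequencies spanning
0.007–0.942 (geometric spectrum, shuffled), two binary clinical covariates
(stent, prevalence 0.64, +8 s; statins, 0.84, −6 s), CT noise sd 20 s and
seven causal variants with per-allele effects between −25 and +12 s.
Causal effects are placed on common variants (AF 0.2–0.6), consistent with
a panel whose informative SNPs segregate at high frequency; at rare
variants, effects of this size are undetectable at n = 69 and would make
the default conditions vacuous.

Genotypes are drawn under Hardy–Weinberg proportions (Binomial(2, AF)).
Linkage disequilibrium is induced by haplotype copying: within a declared
block each haplotype of variant *k* copies the anchor variant's allele with
probability ρ, else draws fresh at its own frequency. Realised r² increases
monotonically with ρ; this reproduces the *presence* of LD, not any
particular population history (no coalescent or recombination-map
structure, no mutation model, no relatedness).

The CT baseline is calibrated analytically so that the expected HTPR
fraction is 0.80: `baseline = 106 − sd_total·Φ⁻¹(0.80) − mean_shift`,
where `sd_total` folds the additive genetic and covariate variance into the
noise variance (normal approximation; exact only in the CLT limit, and
verified empirically to center on 0.80 across seeds at n = 69).

What passing tests on these cohorts do **not** show about real data:
genotyping error, population stratification, missingness patterns other
than the simulated call-quality failures, non-additive (dominance or
epistatic) effects, and any non-Gaussian CT error structure.

All randomness descends from one integer seed through
`numpy.random.SeedSequence` spawning; identical configs give identical
cohorts, and the pipeline's per-stage streams are independent children of
the run seed.

## Variant prioritisation

Two independent tracks, mirroring clinical panel practice, whose union is
analysed:

* **Evidence track**: keep variants with a clinical evidence tier in
  {1, 2, 3}; missing tier fails.
* **Rare/damaging track**: keep variants that are rare (reference
  MAF < 0.02) or novel (no reference MAF — treated as rare-eligible) AND
  putatively deleterious: nonsense/frameshift always; splicing with
  ensemble ADA score ≥ 0.6; missense with ≥ 3 of 6 predictor calls
  damaging. A missing predictor call is **not** a damaging vote
  (conservative choice).

Call-level quality control then requires depth ≥ 8× and, for heterozygous
calls only, alternate-allele read fraction ≥ 0.25; failing calls are set to
missing, and a variant is dropped only when no call survives. The depth
rule is applied per call rather than per site — stricter, and the natural
reading when failed calls are individually re-validated. Variants with
zero dosage variance (monomorphic in the cohort) are excluded before any
statistics.

## Population genetics

* HWE: plain Pearson χ² goodness-of-fit on the three genotype classes
  against (p², 2pq, q²) with df = 1 (two free classes minus one estimated
  allele frequency), no continuity correction; monomorphic variants return
  χ² = 0, p = 1 by convention. A conditional exact test is available as an
  option.
* Reference-frequency comparison: Yates-corrected χ² on the 2×2
  allele-count table (2n alleles per group). Allele counts, not genotype
  counts, enter the table.
* LD: two-locus haplotype frequencies by EM from unphased genotypes
  (uniform start, ≤ 100 iterations or Δ < 1e-10; only double heterozygotes
  are phase-ambiguous and their cis/trans split is re-weighted each
  iteration), then D = p_AB − p_A·p_B, D′ = D/D_max, r² = D²/(p_A p_a p_B p_b).
  A monomorphic member leaves the pair undefined (reported missing).
  Haplotype *blocks* are not inferred — only pairwise statistics.

## Genetic-model association

Three genotype groupings per variant: codominant (0/1/2), carrier
({0} vs {1,2}) and homozygote contrast ({0} vs {2}, heterozygotes
excluded). 2×2 tables get Pearson χ² (df = 1, no continuity correction)
and an odds ratio with a Woolf (log-scale) 95% CI; when exactly one cell is
zero, the Haldane–Anscombe +0.5 correction is applied and flagged; two
zero cells leave the OR undefined. 3×2 codominant tables get χ² with
df = 2 and no OR. Tables with any expected count below 5 are flagged but
still tested — small-sample χ² is the convention this analysis follows
rather than switching to exact tests.

Odds ratios are oriented as carrier (or listed) category vs homozygous
reference with HTPR as the case; because published clinical tables
sometimes print the protective orientation instead, the scan reports both
orientations explicitly labelled.

CT comparisons between genotype groups use the two-sided Mann–Whitney U
test: exact null distribution when the smaller group has ≤ 8 observations
and no ties, otherwise the normal approximation with tie and continuity
corrections (delegated to `scipy.stats.mannwhitneyu`).

No multiple-testing correction is applied to the primary per-test
statistics; a Benjamini–Hochberg column is emitted as clearly-labelled
supplementary output.

## Penalised logistic regression

The classifier minimises `(1/n)·Σ logistic deviance + λ·Σ|β_j|` with an
unpenalised intercept. Columns are standardised internally (mean 0,
population sd 1); coefficients are reported on the original scale.
Fitting is IRLS over the quadratic approximation with cyclic coordinate
descent and soft-thresholding in the inner loop (weights clipped below at
1e-5), an active-set strategy (full sweeps alternate with sweeps over the
current support, with a final full sweep confirming optimality) and warm
starts along a geometric λ path of 100 values from λ_max — the smallest λ
with an all-zero solution, `max_j |x_jᵀ(y − ȳ)|/n`, inflated by a 1e-9
relative guard so the boundary solution is exactly null rather than
floating-point-crossed — down to 1e-3·λ_max (n < p regime). Convergence:
max coefficient change < 1e-7 per sweep, capped at 1e5 sweeps. The inner
kernel is numba-compiled with a pure-Python fallback. KKT residuals are
checkable on any path point (`check_kkt`); the test suite holds them below
1e-6.

Cross-validation uses k = 3 outcome-stratified folds (refolded with a new
derived seed, with a warning, if a training fold ends up single-class),
held-out binomial deviance by default (squared error optional), and
selects λ_min; λ_1se is always computed and available. Under a pure-noise
design, λ_min keeps a few spurious features in roughly a third of seeds
(its well-known optimism) while λ_1se returns the empty model in ~90% of
seeds; both behaviours are pinned by tests. Fold membership is
deterministic given the seed.

Features default to additive dosage (0/1/2); per-variant carrier (0/1)
overrides reproduce binary genotype groupings, and binary clinical
covariates enter as 0/1. Both training ROC/AUC and out-of-fold ROC/AUC are
reported: at n = 69 with p ≈ 100 the training AUC is optimistic, so the
out-of-fold figure is the honest generalisation estimate. The ROC curve
steps tied scores simultaneously, making the trapezoidal AUC equal to the
rank (Mann–Whitney) statistic.

## Polygenic score

`PgxPRS_j = Σ_i β_i · dosage_ij` over the genetic features with nonzero
fitted coefficients. For carrier-encoded features the 0/1 indicator —
not the allele count — enters the score, keeping scoring consistent with
estimation. Clinical covariates are excluded from the score by default
(genetic-only score) with a flag to include them. Validation: Mann–Whitney
U between HTPR classes, Spearman ρ against CT (average ranks on ties,
t-approximation p), and OLS R² of CT on the score — R² is reported from a
linear fit even though the correlation test is rank-based, mirroring mixed
reporting conventions in the clinical literature.

## Problem sizes used by tests and the acceptance script

Association statistics from published contingency counts are exact
arithmetic (n = 69 subjects behind the tables). Simulation-based checks
use: null calibration at n = 300 with 500 replicates (type-I error) and
2000 replicates of n = 500 (HWE uniformity); solver oracles at n = 64–200;
parameter recovery at n = 500, 20 variants, 3 causal, 100 seeds; the
study-scale model at n = 69 with 98 variants. These sizes give stable
Monte-Carlo estimates while keeping a full run in tens of seconds.

## Known limitations

* The generator produces biallelic autosomal SNPs only; no multi-allelic
  sites, sex chromosomes, imputation, or pedigree structure.
* LD is pairwise-copying within declared blocks; no recombination maps.
* At n = 69 the cross-validated selection is unstable across seeds: some
  draws of the default cohort yield an empty selected model. This is a
  property of the sample size, not a solver defect, and is why recovery
  guarantees are stated at n = 500.
* The annotation fields (predictor calls, ADA scores, evidence tiers,
  reference MAF) are consumed as inputs; the package never computes them.
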