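# Methods

## The score

`emprs` implements an endophenotype-weighted polygenic risk score for
cognitive decline in preclinical Alzheimer's disease. For a fixed panel of
27 gene-level variants, a subject's score is

    emPRS = Σ_n RA_n · d_n

where `RA_n ∈ {0, 1}` indicates presence of variant *n*'s assigned **risk
genotype** and `d_n ≥ 0` is its effect-size weight. Unlike conventional
scores weighted by disease-risk odds ratios, the weights here are Cohen's
*d* values measuring how strongly each variant separates rates of
longitudinal **verbal episodic memory** decline in a reference sample of
amyloid-high (Aβ-high) cognitively normal older adults. Two score variants
are always computed: with the APOE entry (`emprs_with_apoe`) and without it
(`emprs_without_apoe`); their difference for an ε4 carrier is exactly the
APOE weight.

All variants are analysed under the **dominant model of the minor allele**:
genotypes collapse to carrier versus non-carrier. The risk genotype is
whichever of the two groups declines faster in the reference sample, so
weights are non-negative by construction and effect direction lives in the
risk-genotype label ("X+" for carriers, "X/X" for a homozygote group). The
packaged reference panel stores the published weights; two of its printed
risk genotypes (KIBRA C/C, CSMD1 A/A) name minor-allele homozygote groups,
and the scorer interprets every label literally against the subject's call
rather than assuming the label matches the dominant-model dichotomy.

**APOE** enters as a single ε4-carriage indicator with one weight; dosage
(one versus two ε4 alleles) does not change the contribution. The ε
genotype is resolved from unphased rs429358/rs7412 calls through the
standard haplotype table (ε2 = T-T, ε3 = T-C, ε4 = C-C). The double
heterozygote (CT, CT) is resolved as ε2/ε4 because the alternative phasing
requires the essentially non-occurring ε1 haplotype; call combinations
admitting only ε1-containing phasings are rejected and the subject is
flagged out of ε4-stratified analyses. **KL-VS** (rs9536314) homozygotes
are excluded before any analysis, since Klotho's protective/risk effect is
not gene-dosage dependent.

## Weight derivation

Per-subject slopes of the verbal-episodic-memory composite on visit month
are extracted either by per-subject ordinary least squares (`"ols"`) or as
best linear unbiased predictions from a linear mixed model with correlated
random intercepts and slopes (`"blup"`, the default — it shrinks slopes of
sparsely observed subjects toward the population mean; with a balanced
visit schedule the two orderings coincide and group effect sizes are
essentially identical, which the tests verify). Subjects with fewer than
two non-missing visits are excluded and reported. For each variant, Cohen's
*d* between carrier and non-carrier slope distributions is computed with
the pooled-SD formula; the 95% CI uses the large-sample standard error
`sqrt((n_a+n_b)/(n_a·n_b) + d²/(2(n_a+n_b−2)))` with a normal 1.96
multiplier. Weights whose CI crosses zero are retained — the panel is fixed
a priori and no CI-based pruning is applied. Exact ties (d = 0) assign the
carrier group with weight 0 and a flag. Variants with an empty or
single-subject group are skipped and reported, not scored.

## Composites

Three composites are supported, each an equal-weight mean of oriented
z-scores: global cognition (CDR-SB−, MMSE+, LMII+, CVLT-II false
positives−, Clock+), verbal episodic memory (CDR-SB−, LMII+, CVLT-II
FP−), and a preclinical composite, AIBL-PACC (CVLT-II long-delay free
recall+, LMII+, MMSE+, WAIS-III Digit Symbol-Coding+). Norms (per-test
mean/SD) come from baseline visits of the designated reference sample. The
published composites rely on cited normative constructions whose exact
weights are not public; the equal-weight z-composite is this package's
declared construction. Covariate adjustment (age, sex, education, premorbid
IQ, depressive symptoms; the PACC omits age and instead carries it as a
model covariate) is linear residualization **fitted on baseline data only
and applied unchanged to every visit** — the only choice that cannot absorb
within-subject change into the correction, which the tests verify by
checking slope preservation.

Amyloid status is classified per subject as Aβ-high if **any** PET SUVR
record meets or exceeds its tracer's threshold — PiB ≥ 1.4, florbetapir
≥ 1.05, flutemetamol ≥ 0.55, all inclusive.

## Evaluation model

Associations are estimated per composite with a random-intercept linear
mixed model

    composite ~ emPRS + time + emPRS×time  (+ age for the PACC)

fitted by REML (statsmodels `MixedLM`). The emPRS main effect α is the
baseline association; the interaction β is the effect on the rate of
change (composite units per unit score per month). Main effects accompany
the interaction because a baseline coefficient is reported alongside it; a
model with the interaction alone would leave α undefined. "Baseline scores
as random factors" is implemented as subject random intercepts — the
standard estimable reading. Fixed effects are tested with Wald z
statistics and raw p-values are reported without multiplicity correction.
Stratified analyses refit the model per APOE ε4 stratum using the
APOE-free score; the default strata are non-carrier versus carrier
({0} vs {1,2} alleles), with per-dosage strata available. Strata below a
configurable minimum size (default 10) are reported as skipped rather
than fitted. α is taken from the same longitudinal model as β, and the
report records the covariates used per fit.

## Synthetic cohort generator

The generator supplies cohorts with the structure the analysis assumes, so
every stage is testable without access to the original study data:

* **Genotypes.** Hardy-Weinberg draws at per-gene MAFs (defaults are
  typical European-ancestry frequencies). APOE is drawn as two phased ε
  haplotypes (defaults ε2/ε3/ε4 = 0.06/0.70/0.24, putting ε4 carriage near
  42% as seen in amyloid-enriched normal samples) and exported unphased, so
  the haplotype-resolution code is exercised against known truth (ε1 is
  never generated, making resolution exact). The KL MAF is the square root
  of the configured VS/VS fraction (default 6/232, the exclusion count the
  pipeline is expected to reproduce), so the homozygote fraction is matched
  in expectation under HWE.
* **Trajectories.** y_ij = b_i + slope_i·t_j + ε_ij with
  b_i ~ N(0, intercept_sd²), ε_ij ~ N(0, residual_sd²); default visits at
  months 0, 18, 36, 54, 72, 90. Risk-group membership subtracts a per-gene
  decrement from slope_i and never moves the intercept, mirroring the
  longitudinal-only associations the analysis is designed to detect.
  Default decrements are calibrated so that each gene's analytic Cohen's d
  between carrier and non-carrier OLS slopes equals its packaged panel
  weight: δ = d · residual_sd/√Sxx, with Sxx the centered sum of squares
  of the visit months (`slope_effect_for_d` exposes the calibration).
  Defaults base_slope = −0.004/month, intercept_sd = 0.8, residual_sd =
  0.4 place decline and noise on the scale of a z-scored composite in
  amyloid-high normal ageing (≈0.05 SD/year mean decline).
* **Covariates and SUVR.** Age ~ N(72.2, 6.6) truncated at 60, 51% female,
  four education bands, FSIQ ~ N(108, 7.5), GDS ~ Poisson(1); tracer mix
  60/25/15 PiB/flutemetamol/florbetapir with a configurable Aβ-high
  fraction (default 1.0 — the analysis population is Aβ-high by design).
* **Missingness.** Visits after baseline are dropped independently with
  probability `dropout_rate` (default 0.12); the retention profile of a
  real cohort is not asserted. Missingness is completely at random.

What the generator does **not** emulate: linkage disequilibrium between
panel variants, recruitment/ascertainment effects, practice effects and
floor/ceiling behaviour of real neuropsychological tests (composites are
simulated directly, not built from subtests), informative dropout, and
genotype effects on baseline level. Passing tests therefore demonstrate
correctness of the machinery and its operating characteristics under the
assumed generative model, not validity of the score on real data.

## Pipeline

`run_pipeline` executes: amyloid filter → KL-VS exclusion → random
reference/test split (sizes round(fraction·n) and remainder; the default
fraction 151/226 reproduces the 151/75 split on a 226-subject cohort) →
weight derivation on the reference sample → scoring of the test sample
with the derived panel → evaluation, overall and stratified. Every output
table embeds the seed and a hash of the analytic configuration (output
location excluded), and reruns are byte-identical. Stage logs record
counts in/retained/excluded at every filter. rsID is the join key
throughout; chromosome/position are metadata only.

Missing genotypes: default policy "strict" leaves the subject unscored and
flagged; the optional "available-variant" policy scores over non-missing
entries rescaled by total/available weight and flags the record.

## Numerical choices and problem sizes

* `MixedLM` fits use REML with lbfgs then powell fallback;
  non-convergence yields a flagged, coefficient-free result rather than an
  exception. On noise-free data (all within-subject residuals below
  1e-10) the BLUP path returns per-subject OLS slopes directly, the exact
  zero-noise limit of the shrinkage estimator, avoiding a degenerate
  variance-component fit.
* Cohen's d requires n ≥ 2 per group and positive pooled SD; violations
  raise.
* The stochastic validation suite uses 100 replicates at n = 300 for
  parameter recovery (3-SE check against the analytic d and ≥95% correct
  risk-group assignment), 500 replicates at n = 150 for type-I error of
  the interaction test (95% binomial band around 0.05), and 50 replicates
  at 400 subjects per stratum for stratification fidelity (≥90% joint
  success). These sizes give the operating-characteristic checks stable
  pass behaviour at fixed seeds while keeping the whole suite to a few
  minutes on one CPU.

## Known limitations

The packaged weights are point estimates from one modest reference sample
(all non-APOE CIs cross zero); the package reproduces the construction, not
a claim of per-variant significance. The equal-weight z-composites are a
declared stand-in for the cited normative composites. Real-data SUVR
harmonisation (e.g. Centiloid) and genotype imputation are out of scope;
VCF ingestion is deliberately minimal (biallelic SNVs, GT field, rsID
match).
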