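# Methods

## The model

The package analyses case-control data under the additive genetic model: the
log-odds of disease is linear in the count of risk alleles. For a single
variant with dosage g ∈ {0,1,2},

    logit P(D = 1 | g, x) = β₀ + β_g·g + βᵀx,

with covariates x = (age, male sex, BMI) unless noted. Odds ratios estimated
by prospective logistic regression are valid under retrospective
(case-control) sampling, which is what the fitting relies on throughout.

The genetic risk score is the unweighted sum of risk-allele dosages over a
panel: GRS1 over all 36 panel SNPs, GRS2 over the 14 flagged as significant
in the source study. Effect sizes are *not* used as weights; the score is an
allele count. With m of S panel genotypes missing for a participant, the
attained count is rescaled to the full panel, GRS_w = GRS·S/(S − m). The
printed formula this implements ("number of risk alleles / risk alleles −
missing genotypes") is ambiguous as written; S/(S − m) is the standard
missing-genotype correction and the only dimensionally coherent reading, and
it is what makes non-integer tertile cutpoints (e.g. 37.21) attainable.
Participants with ≥4 missing genotypes are excluded outright (threshold
configurable); with no missingness the weighted and raw scores coincide, and
analyses always use the weighted score.

Quantile categories (tertiles, quintiles) are cut at the empirical quantiles
of the pooled cases+controls analytic sample, ties to the lower category.
The pooled basis is a choice — the source does not say pooled or
control-only — made because it is the conservative default; it is exposed as
the vector passed to `assign_quantiles`.

## Joint effects and interaction

Lifestyle is discretised three ways, deliberately coexisting: WHO BMI
classes (≤25, >25–<30, ≥30; exactly 25 falls low, exactly 30 high), WHR
tertiles from the pooled sample, and a composite count 0–3 of
[BMI > 25] + [WHR > 0.85] + [no exercise]. Note the composite's WHR
component uses the fixed 0.85 cut, not the tertile boundaries.

The joint-effect grid is one logistic model per lifestyle panel with an
indicator for every (GRS tertile × lifestyle category) cell except the
double-low reference, so every OR shares a single baseline. Cells with no
cases or no controls are reported with their counts and an undefined OR;
their participants are dropped from that fit rather than silently absorbed
into the reference. Adjustment sets follow the source's table footnotes —
age+sex for the BMI and composite panels, age+sex+BMI for the WHR and
exercise panels — and are overridable, because the footnote marks in the
source are ambiguous.

The interaction test is a 1-df likelihood ratio: main-effects model (ordinal
GRS tertile code 0–2, ordinal/binary lifestyle code, adjustments) versus the
same model plus the single product of the two codes. A single product term —
not a (k−1)×(m−1) indicator block — is used because the tested hypothesis is
a trend-by-trend multiplicative departure.

## Statistical conventions

- Logistic fits: Newton/IRLS via statsmodels to relative tolerance 1e-8,
  max 100 iterations. Non-convergence raises; |β| > 15 on any non-intercept
  term is treated as (quasi-)separation and raises with the term named.
- Intervals are Wald, exp(β ± 1.96·se); p-values two-sided Wald z. For
  categorical GRS models both a 1-df ordinal trend p and a (k−1)-df
  heterogeneity LRT p are reported, since either reading of a "trend over
  categories" may be wanted.
- Hardy–Weinberg QC: plain 1-df chi-square against p², 2pq, q² at the sample
  allele frequency, flagged at P < 10⁻⁴, computed on controls. The
  chi-square (not an exact test) is used deliberately — it is the
  field-standard QC — but it over-rejects for rare alleles with zero
  heterozygotes at small n; the test suite verifies agreement with a
  Levene–Haldane exact oracle wherever expected genotype counts are ≥5 and
  the p-value is not within a decade of the threshold.
- LD QC: same-locus pairs are screened with the composite genotype
  correlation r² on pairwise-complete dosages (the estimator available for
  unphased data), flagged at r² ≥ 0.80. Monomorphic vectors raise a distinct
  error rather than returning 0, so "undefined" is never read as "in
  equilibrium".
- Power: the exposure is treated as subject-level binary with prevalence p₀
  in controls and the odds-transformed p₁ in cases; power of the uncorrected
  two-proportion chi-square uses the pooled-variance normal approximation,
  power = Φ(|p₁−p₀|/se₀ − z_{α/2}) (+ the negligible opposite tail). The
  subject-level reading reproduces the 88% design figure; counting alleles
  (2N trials) would not. A simulation method (binomial draws + Pearson
  chi-square) is provided and agrees with the approximation to within
  simulation error.
- Sign test: exact binomial tail at p = ½, defaulting to one-sided
  P(X ≥ k) — the variant whose value at k=23, n=36 matches the source's
  printed 0.066 — with a two-sided doubling available.
- Direction consistency counts estimated OR strictly greater than 1 for the
  literature risk allele; OR exactly 1.00 is inconsistent. On the panel's
  published two-decimal ORs this gives 24/36 (one OR prints as 1.00); the
  source's count of 23 presumably reflects unrounded estimates.

## The synthetic cohort generator

The generator emulates exactly the structure the analysis assumes, with
defaults fixed at the study conditions:

- 2,679 cases and 3,322 controls (the study sizes);
- control genotypes in Hardy–Weinberg proportions at the panel frequencies
  (which are sample-wide frequencies treated as control frequencies — a
  second-order distortion at these effect sizes);
- case genotypes drawn retrospectively with P(g|case) ∝ HWE(g)·ORᵍ per SNP,
  the genotype law implied by the additive logistic model; for the additive
  model this stays binomial with p′ = p·OR/(1 − p + p·OR);
- SNPs independent across loci (no LD), the simplest structure satisfying
  the score's r² < 0.80 assumption;
- lifestyle category draws conditional on status from the study's observed
  margins (BMI classes 68.4/27.3/4.3% in controls vs 36.4/49.3/14.3% in
  cases, WHR tertiles 42.9/30.5/26.6 vs 18.9/32.8/48.3, exercise 36.4 vs
  38.7%), with continuous BMI/WHR drawn from truncated normals inside the
  drawn category (means anchored at the study's 23.7/26.4 kg/m² and
  0.83/0.87; SDs 3.0 and 0.05; WHR tertile bounds 0.81/0.85, the upper bound
  being the fixed high-WHR cut). Sex and age use the study's male fractions
  (21.46/26.76%) and medians (53.16/58.57 y; truncated normal, SD 8, range
  40–75). Conditioning on status reproduces the joint structure the
  stratified analyses consume without inventing unreported causal
  parameters; it also makes genotype and lifestyle conditionally independent
  given status, i.e. exactly multiplicative — the correct null for
  calibrating the interaction LRT.
- missingness: uniform at a configurable rate, plus a configurable number of
  "heavy-missing" participants given ≥4 missing genotypes each, so the
  exclusion rule has an exactly known casualty count. The canonical test
  cohort (seed 20121121) draws 6,075 participants and rigs 74, leaving 6,001
  after exclusion.
- randomness: one root seed; genotypes, phenotypes, missingness and the
  interaction re-sampler each use an independently spawned substream, so
  adding a stage never perturbs earlier draws; equal seeds give bitwise
  equal cohorts.

For interaction power studies, setting `grs_env_interaction_beta` re-samples
case status from a prospective logistic model with main effects log(1.08)
per score point and log(1.10) for no-exercise plus the product term; this
intentionally overrides the per-SNP retrospective enrichment.

What the generator does *not* emulate: LD between loci, population
stratification, genotyping error, covariate measurement error, and any
genotype–lifestyle dependence within status. Passing tests therefore
establish estimator correctness under the analysis's own assumptions, not
robustness to their violation in real cohorts.

## Test and calibration scales

Calibration checks run at sizes chosen to balance resolution against
runtime: parameter recovery at n = 20,000; interaction type-I error over 500
null cohorts of n ≈ 6,000 (accepted in (0.03, 0.07)); Wald 95% CI coverage
over 500 null cohorts of n = 2,000 (accepted in (0.93, 0.97)); power
simulation cross-checks at 10,000 replicates with 3-SE bands per grid cell.

## Known limitations

- The logistic fitter inherits statsmodels' behaviour for near-separated
  data; Firth or exact logistic regression is out of scope, as is any
  multiple-testing correction (matching the source analysis, which reported
  uncorrected p-values).
- Strand ambiguity in VCF input is refused, never guessed: allele pairs must
  match the panel literally (possibly swapped), and A/T / C/G flips raise.
- Multi-allelic variants, imputation, phasing and meta-analysis are out of
  scope; the panel is biallelic throughout.
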