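# Methods

## Mediation model and suppression classification

The pipeline treats each SNP as the exposure in a three-variable mediation
model with adiponectin as mediator and HDL-C as outcome, both analyzed on
the natural-log scale (log-normality is the standard working assumption for
these lipid/adipokine measurements; the log base is a convention and all
coefficients are interpreted on natural-log scales). Three OLS regressions
are fit on one common list-wise-deleted sample per SNP:

1. `log M ~ G + age + sex + bmi + smoking` → α
2. `log Y ~ log M + G + covariates` → β (mediator) and γ′ (direct)
3. `log Y ~ G + covariates` → total effect τ

Because the regressions are nested and share the sample, τ = αβ + γ′ holds
algebraically; the implementation asserts this to 1e-10 in the no-missing
case. β and γ′ are taken from the same regression (2), the standard
three-regression layout. The total effect is reported both as the
regression-(3) coefficient and as the sum αβ + γ′ (identical up to
floating point); published tables that round components independently can
show a small discrepancy between the two forms, and no attempt is made to
force printed-rounding agreement.

The Sobel test uses the first-order delta-method variance
a²·se_b² + b²·se_a² without the se²se² cross term; the Aroian variant
(adding the cross term) is available behind a flag. The first-order form is
the default because it reproduces the conventional z statistic for the
worked example this package targets (z = −11.16 from α = −0.079 ± 0.006,
β = 0.21 ± 0.01; Aroian gives −11.15).

Classification (significance level configurable, default 0.05 — the
conventional two-sided threshold):

- **suppression** — criteria 1, 2, 4 hold, |γ′| > |τ| and sign(αβ) ≠
  sign(γ′). Criterion 3 is deliberately not required: opposing paths of
  similar magnitude abolish the total effect, which is the phenomenon of
  interest.
- **full mediation** — criteria 1–4 hold and γ′ is non-significant.
- **partial mediation** — criteria 1–4 hold, γ′ significant, same-sign αβ.
- **none** — anything else.

Suppression takes precedence when both patterns match, since an
opposing-sign decomposition is not a mediation in the classical sense.

## Association scan

Additive genotype coding (0/1/2 minor-allele count), classical
homoscedastic OLS standard errors and t-distribution p-values — the
defaults of the standard GWAS and general-statistics tools this pipeline
mirrors. Two adjustment sets are scanned: "base" (age, sex, BMI, smoking)
and "base+mediator" (adding log adiponectin). Sex is coded 0 = male,
1 = female; smoking 0/1. The genome-wide threshold defaults to 5×10⁻⁸ and
is reported as a flag alongside raw p-values; no further multiple-testing
correction is applied. SNPs monomorphic after list-wise deletion yield
flagged untestable records rather than errors. Rank-deficient designs are
rejected with the collinear columns named.

## Quality control

Filter order: samples first (call rate ≥ 97%), then SNPs on the retained
samples — MAF ≥ 0.05, missingness ≤ 3%, Hardy–Weinberg exact p ≥ 1e-6.
The missingness rule reads the conventional "SNP call rate < 3%" exclusion
as missingness > 3%, since the literal reading (exclude SNPs called in
under 3% of samples) would exclude almost nothing. HWE uses the
conditional exact test: the two-sided p is the sum of conditional
probabilities, given the allele counts, of all heterozygote counts no more
probable than the observed one (plain tail summation, no mid-p), computed
in log space so biobank-scale counts cannot overflow. Only autosomal
biallelic SNPs are accepted at load time.

## Haplotype / LD estimation

Two-locus haplotype frequencies are estimated by EM over the
double-heterozygote phase ambiguity, started from linkage-equilibrium
frequencies, converging when the largest frequency change drops below
1e-10 (cap 1000 iterations); the per-iteration log-likelihood path is
stored and is non-decreasing. D is the coupling disequilibrium of the two
minor alleles; D′ is reported as |D|/Dmax; r² = D²/(p(1−p)q(1−q)).
Monomorphic sites return a degenerate estimate (r² = 0) with a flag.
Haplotype association regresses the transformed outcome on posterior
(fractional) expected haplotype dosages — unbiased at moderate LD where
best-guess phasing is not — with the most frequent haplotype (the GG
analog) as reference; haplotypes with total expected count below 5 are
flagged unstable.

## Synthetic cohort generator

The generator emulates the statistical structure of the motivating cohort
of 2,199 Taiwanese adults:

- **Covariates.** Sex ~ Bernoulli(0.552 female); per-sex age and BMI
  normal (men 48.6 ± 11.1 y, 25.1 ± 3.4 kg/m²; women 48.2 ± 10.7 y,
  23.4 ± 3.5 kg/m²); smoking Bernoulli (33.4% men, 5.5% women).
- **Focal SNP pair.** Two haplotypes per sample drawn from the
  four-haplotype distribution implied by MAFs (0.32, 0.22) and normalized
  D′ (default 0.9, a tight intragenic LD block) with minor alleles in
  coupling phase; random mating. Normalized D′ ∈ [0, 1] is always
  feasible; the raw-D helper rejects infeasible disequilibria outside the
  Frechet bounds.
- **Phenotypes.** Log adiponectin and log HDL-C follow the mediation path
  with α = −0.079, β = 0.21, γ′ = +0.015 per minor-allele copy (indirect
  effect −0.017 opposing the direct effect — the suppression structure).
  Covariate effects on the log scales are small, plausible defaults
  (e.g. BMI −0.03 on log adiponectin), all overridable. Predictors are
  centered per sex so per-sex means are controlled exactly.
- **Scale calibration.** Per-sex raw adiponectin means/SDs (2.88 ± 1.45
  men, 4.01 ± 1.97 women mg/L) are converted to lognormal location/scale
  by moment matching; the mediator's residual SD is the total log-SD minus
  the variance explained by genotype and covariates, so simulated raw
  means and SDs reproduce the configured values. The outcome's residual
  SD defaults to 0.09 on the log scale, chosen so that at n = 2199 the
  mediator-adjusted genotype association is strong (p ≈ 10⁻⁶–10⁻⁷) while
  the marginal association is null — the scan pattern the pipeline is
  built to detect. A consequence is that simulated raw HDL-C SD
  (≈ 8 mg/dL) is smaller than the real cohort's (≈ 13 mg/dL): the real
  measurement presumably carries extra between-assay and biological
  variance not attributable to this three-variable system, and matching
  the adjusted-signal strength was prioritized over matching the raw
  spread.
- **Null panel and missingness.** Null SNPs are binomial under HWE with
  MAFs uniform on (0.05, 0.5), independent of all phenotypes; genotype
  missingness is completely at random (default 0.5%).
- **Reproducibility.** A single integer seed feeds a `SeedSequence` whose
  spawned children drive covariates, haplotypes, mediator noise, outcome
  noise, null SNPs and missingness; identical seeds give byte-identical
  cohorts.

What the generator does **not** emulate: population structure and
relatedness, genotyping batch effects, informative missingness,
non-additive genetic effects, X-chromosome dosage, measurement error in
covariates, and the full LD landscape of a real genome (null SNPs are
mutually independent). Passing tests therefore demonstrate correctness of
the statistical machinery under the model's own assumptions, not
robustness to confounding or cryptic relatedness in real cohorts.

## Problem sizes and numerical choices

The test suite and acceptance script use 200 replicate cohorts at
n = 2199 for parameter-recovery and suppression-rate checks (Monte-Carlo
SE on the mean of α̂ ≈ 0.001, comfortably resolving the generative
values), 1000 null SNPs for calibration, and n = 10⁵ draws for LD
round-trip checks — sizes at which every check is stable across seeds.
OLS is delegated to statsmodels after an explicit pivoted-QR rank check;
the EM and exact-test kernels are validated against independent oracles
(1-D likelihood grid; exact-integer enumeration) in the suite.

## Known limitations

- Outcomes are continuous only; no logistic/binary mediation.
- Single mediator; no bootstrap CIs for the indirect effect (Sobel only).
- Two-locus haplotypes only; no multi-locus phasing.
- Classical SEs assume homoscedasticity; heteroscedasticity-robust
  variants are not offered.
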