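# Methods

## The score and the models

The weighted PRS is the plain weighted sum `Σ_j w_j g_ij` of risk-allele
dosages times per-allele log odds ratios; the unweighted score is the raw
risk-allele count. No normalization by the weight sum or panel size is
applied: the published control median of ~7.5 over 41 SNPs, with every
per-SNP weight below 0.47, is only consistent with the sum convention. A
normalization option exists but is off by default.

All association models are logistic regressions adjusted for age (years)
and sex (male indicator), fit by iteratively reweighted least squares with
step-halving so the deviance never increases; Wald covariance comes from
the observed information at the optimum, and all 95% intervals use
z = 1.959964. Separation is detected by diverging coefficients (|β| > 15)
and flagged, never silently corrected — Firth-type penalties are out of
scope. Age odds ratios are rescaled per decade for reporting.

Quantile stratification uses the inverse empirical CDF (quantile(p) =
smallest x with CDF(x) ≥ p, no interpolation) and left-closed right-open
bins: a score equal to a boundary belongs to the upper bin, and scores
outside the reference range fall into the first or last bin. The shipped
European-ancestry quintile boundaries (6.80, 7.32, 7.77, 8.28) are the
published external-control cutoffs; African-American analyses derive
cutoffs internally from their own controls. The 99th-percentile contrast
compares flagged individuals to the middle quintile in a logistic model
restricted to those two strata.

The heterogeneity trend test is a likelihood-ratio test between two
baseline-category multinomial logits fit by Newton's method: the full model
has category-specific intercepts, PRS slopes, and covariate effects; the
constrained model shares one PRS slope across case categories while leaving
covariate effects category-specific, so only slope equality is tested.
LRT = 2Δlog-likelihood on (#case categories − 1) df. (The alternative —
constraining covariates too — changes the null hypothesis and is not the
default.)

Discrimination is the concordance probability (ROC AUC) in Mann–Whitney
form with half credit for ties, with a Hanley–McNeil standard error
truncated to [0, 1]. Per-SNP models are log-additive (dosage as a single
linear term), reported at the nominal 0.05 level with no multiple-testing
correction, since the panel is fixed a priori. Crude 2×2 odds ratios use
the cross-product with a Woolf interval; the Haldane–Anscombe 0.5
correction is applied only on request. Exposure screens use per-exposure
complete cases (denominators therefore vary), a two-sided χ² or Welch t
crude test, then the adjusted logistic model.

## Quality control

Filter order is fixed: (1) flagged samples (sex discordance, genotyped
relative — accepted as precomputed flags; array-level inference of genetic
sex and kinship is out of scope) and samples with call rate < 0.90; (2)
monomorphic variants; (3) variants with call rate < 0.95; (4) variants with
exact-test Hardy–Weinberg P < 1e-5 on the retained samples — controls only
when phenotype labels are available, since case enrichment can distort
genotype frequencies. Thresholds are strict inequalities. Sample filters
run first so sample-level missingness cannot distort variant statistics;
the filter is idempotent.

The Hardy–Weinberg test is the exact conditional test (probability-ordering
two-sided p, computed by full enumeration over heterozygote counts in log
space); the asymptotic χ² test is available as an option. The two agree in
the rejection tail but can differ by several percent in the mid-range at
n ≤ a few thousand — the exact test is the default precisely because the
filter operates in the far tail.

Allele harmonization enumerates all four orientations of a VCF (REF, ALT)
pair against the panel (risk, other) pair — allele order × strand — and
accepts a unique match. Palindromic (A/T, C/G) variants match twice with
opposite dosage mappings and are excluded by default; an override trusts
the file's strand. Synthetic panels avoid palindromic pairs by
construction.

## Ancestry

Supervised admixture: reference allele frequencies are fixed and each
individual's mixing proportions q over K populations (default EUR, AFR,
EAS) are estimated by EM on the binomial likelihood
`g_j ~ Bin(2, Σ_k q_k f_kj)`, frequencies clamped to [1e-6, 1−1e-6],
missing sites skipped. The objective is concave in q, so the uniform start
affects only the iteration count; the log-likelihood is non-decreasing
every iteration and convergence is declared when it improves by < 1e-6.
Classification follows the study rule: AFR ≥ 0.50 → AA (inclusive bound),
else EUR > 0.80 → EA (exclusive), else OTHER.

In the pipeline, admixture is estimated from a dedicated
ancestry-informative-marker (AIM) panel rather than the 41 trait SNPs: the
original analysis had genome-wide data, and a few dozen weakly
differentiated SNPs cannot support a 50%/80% classification rule. The
simulator draws AIMs under the Balding–Nichols model (ancestral frequency
p ~ U(0.1, 0.9), per-population frequencies Beta-distributed around p with
Fst = 0.15, default 300 markers), which gives near-perfect label recovery
at realistic differentiation.

## The synthetic cohort generator

The generator emulates the study design, not just its marginals:
case-control sampling with exact group sizes (defaults 2631 controls, 396
LC-MBL, 164 HC-MBL, 696 CLL — the European-ancestry cohort), achieved by
drawing covariate/genotype pools and rejection-sampling categories to
target counts, with a 100× oversampling cap and a diagnostic error beyond
it. Outcomes follow a baseline-category multinomial logit whose linear
predictors are centered (PRS at its panel expectation, age at 60, sex at
1/2) so intercepts read as log-odds for an average individual.

Default parameters are the published study conditions wherever printed:
per-unit PRS slopes ln 1.75 / ln 2.14 / ln 2.53 for LC-MBL / HC-MBL / CLL
(the graded clone-size trend), age effect 0.06 per year (≈ OR 1.8 per
decade), sex effect ln 1.73, ages truncated-normal (mean 64, SD 10, range
30–100), male fraction 0.45. Panel weights are uniform on
(ln 1.05, ln 1.46) and EUR risk-allele frequencies uniform on (0.15, 0.70),
chosen so the control score has mean ≈ 7.5 and SD ≈ 1 — the published
scale; AFR frequencies are drawn lower (0.08, 0.62), reproducing the
published ~7-point median frequency gap and, downstream, the reduced score
variance that attenuates discrimination in AA analyses. Because a 41-SNP
random draw still leaves the panel-level expected score with SD ≈ 0.8
across seeds, `make_panel` can anchor a panel by rescaling all weights by
one constant so the expected EUR score is exactly 7.46; the pipeline and
fixtures use this anchor so the shipped external cutoffs stay meaningful
for any seed.

What the generator does **not** emulate: linkage disequilibrium (variants
are independent, per the additive score's own assumption), haplotypes,
genotyping-intensity artifacts, and relatedness beyond exact duplicates.
Consequently, passing tests demonstrate the correctness of the statistical
machinery under the stated generative model — they do not certify behavior
under real LD structure, and the cross-ancestry attenuation reproduced here
is the allele-frequency component only, not the LD/tagging component. For
the same reason, with identical per-allele effects and identical weights
the *per-unit* weighted-score odds ratio is frequency-invariant in this
model; the attenuation that lower frequencies do produce — smaller score
variance, hence lower c-statistic, and larger per-SNP standard errors,
hence fewer nominally significant variants — is what the directional
property test asserts.

Artifacts are injected post hoc: per-variant and per-sample missingness at
stated Bernoulli rates; Hardy–Weinberg distortion via an inbreeding-like
coefficient F with P(het) = 2f(1−f)(1−F) (sign-controllable, infeasible
combinations rejected); duplicates appended with a stated per-site
discordance; monomorphic overwrites to the modal dosage.

All randomness flows from one integer seed through named SHA-256-derived
substreams, so adding a stage never perturbs existing streams and every
output (which carries no timestamps) is byte-identical across reruns.

## Numerical choices and degenerate inputs

Logistic/multinomial fits converge on Δlog-likelihood < 1e-10 with step
size < 1e-8; linear predictors are clipped at ±30 inside link evaluations;
singular information matrices yield NaN covariance and non-estimable rows
rather than exceptions. An all-zero or all-one outcome is flagged
degenerate immediately. Constant score vectors cannot define quantile
cutoffs (error); NaN scores cannot be binned (error); an all-missing
dosage vector yields no score, with the reason recorded. Kruskal–Wallis on
identical values returns H = 0, p = 1. Missing genotypes default to
mean imputation with twice the control allele frequency (keeping everyone
scorable); `complete_only` excludes the individual instead, and the two
agree exactly without missingness.

## Problem sizes

The acceptance recomputation uses 10 replicates of 50,000 individuals for
the MBL and EA-CLL contrasts and 10 × 20,000 for LC-MBL, HC-MBL and AA-CLL;
the Wald-coverage property uses 500 replicates of n = 800; oracle
equivalences run at n ≤ 2,000 (c-statistic) and genotype totals ≤ 500
(Hardy–Weinberg enumeration). These sizes make Monte-Carlo error small
relative to the comparison tolerances while keeping the default runs quick
on a single CPU.
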