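# Methods

This note documents the statistical model, the generator, the numerical
choices and the known limitations of `gxepi`.  It states nothing the test
suite or `scripts/acceptance.py` does not itself compute.

## Design and model

The data structure is a matched case-control study: each case (a patient
with the adverse outcome) is matched to *m* controls from the same hospital,
of the same sex, within ± 5 years of age.  The analysis model is a logistic
regression for case status with independent Gaussian random intercepts on
three nested grouping levels — matched stratum (level 2), hospital
(level 3) and recruitment period (level 4), with subjects at level 1:

    logit P(y_i = 1) = x_i'β + u_stratum(i) + u_hospital(i) + u_period(i)
    u_ℓ ~ N(0, σ_ℓ²)  independently within each level

The fixed effects of interest are the three indicators of the four-group
exposure × carriage coding (exposed/wild, exposed/carrier,
unexposed/carrier, each versus the doubly-unexposed reference), plus
adjustment covariates.  Hospitals are nested inside period cells (the
hospital grouping label is the period–hospital pair), so the nesting
stratum ⊂ hospital ⊂ period is well defined even when the same physical
hospital recruits in both periods.

We deliberately fit random stratum intercepts rather than conditional
logistic regression: the random-intercept formulation is the model family
the reported estimates of such studies come from, and it extends naturally
to the hospital and period levels.  Conditional logistic is out of scope.

### Estimation

Maximum likelihood with a Laplace approximation to the marginal likelihood:

1. **Stage 1 (profiled).** For trial SDs, the fixed effects and random-effect
   modes jointly maximise the penalized log-likelihood by Newton iterations
   (sparse Cholesky-type solves; the random-effect cross-products are sparse,
   so desk-scale problems with ~1000 strata fit in milliseconds).  The SDs
   are optimized by bounded L-BFGS-B starting at 0.1 with the boundary σ = 0
   allowed.
2. **Stage 2 (joint).** The fixed effects move into the outer objective with
   only the random effects profiled.  Stage 1 ignores the dependence of the
   Laplace curvature term on β; stage 2 restores it and matches the default
   objective of `lme4::glmer` (nAGQ = 1).  A test compares the two
   implementations on a clustered fixture and agrees to ~1e-3 in
   coefficients, variance component and log-likelihood.

Fixed-effect covariance is the inverse Schur complement of the
random-effect block of the joint curvature at the optimum (variance-
parameter uncertainty is not propagated; SEs are therefore slightly smaller
than `glmer`'s profile-aware ones, by ~3 % on the comparison fixture).
BIC uses k = (number of fixed effects) + (number of variance components),
with n the number of analysed subjects.  Levels whose SD estimate falls
below 1e-5 are treated as exactly zero (boundary estimate, noted in the
model output); with only two recruitment periods the period-level variance
is weakly identified and boundary estimates are expected and reported
without reinterpretation.  In 1:m matched data the stratum-level variance is
barely identified by design (every stratum holds one case), so near-zero
stratum SDs are the norm, as they would be with any Laplace ML fitter.

Plain logistic ML (Newton, convergence when max |score| < 1e-8 or the
relative log-likelihood change < 1e-10) is exposed as the fixed-effects
limit; separation is flagged via `converged=False` rather than raised.
Rank-deficient designs raise an error naming the collinear terms.

### Interaction measures

RERI = OR₁₁ − OR₁₀ − OR₀₁ + 1 and S = (OR₁₁ − 1)/((OR₁₀ − 1) + (OR₀₁ − 1)).
The delta-method RERI variance uses ∇ = (−e^β₁, e^β₂, −e^β₃) on the 3 × 3
coefficient covariance; the S interval is built on log S and
back-transformed.  S is undefined when its denominator is within 1e-12 of
zero; its CI is additionally withheld (with a note) when OR₁₁ ≤ 1 or the
denominator is negative, where the log transform does not exist.  Estimates
with a component OR below 1 are reported with an interpretability note, not
suppressed.  A parametric bootstrap (β* ~ N(β̂, Σ̂), percentile intervals,
seeded) is provided both as an alternative interval and as the cross-check
used in the tests; the published intervals' construction is not documented,
so point estimates — not CIs — are the reproduction targets.

### Confounder selection

Forward change-in-estimate search: a candidate enters only if it shifts at
least one of the three group ORs by ≥ 10 % (relative; "the OR of the main
variable" is ambiguous with three indicators, so the maximum over the three
is used — the conservative superset) *and* strictly decreases BIC.  The
qualifying candidate with the largest shift wins each round; ties break by
declared candidate order; every evaluation lands in an audit trail.  By
default the paper-style forced adjustment set (arthrosis, H. pylori,
gastrointestinal history, proton-pump inhibitors, antiaggregants,
anticoagulants, interview count and reliability) is used without selection;
when selection is enabled it runs once globally by default (`selection_scope
= "per_model"` repeats it per SNP × stratum).

### Genotype QC

The exact Hardy–Weinberg test conditions on the observed allele counts: the
heterozygote count then has a known discrete distribution, and the p-value
sums the probabilities of all counts no more probable than the observed one
(probability ordering, numerically via log-gamma; the test-suite oracle
recomputes it in exact rational arithmetic).  The 1-df chi-square test
against p², 2pq, q² expectations is reported alongside; the exact p is
primary.  HWE is tested in controls only, and is reported as not applicable
when controls show fewer than three genotype classes — the convention of
the prevalence table this mirrors, which prints "Not applicable" for
two-class loci, not only monovariant ones.  The default rejection threshold
is α = 0.001 (configurable; the source wording is ambiguous about whether
this is a threshold or an observed-significance convention).  Call rate is
(non-missing)/(all participants) with an inclusive ≥ 0.98 pass.  QC failures
flag SNPs; the pipeline skips flagged SNPs unless explicitly overridden.

### Pipeline conventions

* Dominant genetic model (carrier = ≥ 1 variant allele, either alternate at
  dual-variant loci); the "wild" allele is the left allele of the
  rsID:X>Y notation.  Other genetic models are out of scope.
* Drug strata are independent dichotomies: aspirin use does not reclassify
  a subject in the non-aspirin stratum, and vice versa; `any_nsaid` is the
  union.  Exposure windows are inclusive integer day counts
  (0 ≤ days ≤ window, default 7).
* Missing genotype at a SNP excludes the subject from that SNP's analyses;
  missing covariates are explicit and dropped listwise per analysis with the
  drop count reported.  No imputation.
* Interaction estimates are marked "not applicable" when the
  exposed-carrier cell holds fewer than `min_cell_count` (default 3) cases
  or controls; counts are still reported.  Monovariant SNPs are skipped
  with an explicit reason.  Every panel SNP appears in the results or the
  skip log.
* No multiple-testing adjustment: the candidate panel is chosen a priori
  and all performed tests are reported; the run record counts them so users
  can correct externally.

## The synthetic-data generator

The generator inverts the analysis model so that the whole pipeline can be
exercised with known truth.  A source population is organised into latent
clusters of ~8 subjects sharing hospital, recruitment period, sex, a 5-year
age band and a cluster random intercept; genotypes are drawn in
Hardy–Weinberg proportions; binary covariates with configured prevalences
shift drug exposure through a shared logistic term (making confounding real)
and shift outcome risk; case status follows the logistic model with the
target group odds ratios.  Enrolment emulates consecutive case recruitment:
every incident case is eligible, cases are taken in random order, and each
forms its own matched stratum with m controls drawn without replacement
from the non-case members of its own cluster — so matched sets share the
matching factors and the cluster intercept, exactly what the analysis model
assumes.  (Sampling at most one case per cluster would under-represent
case-dense clusters and bias the high-risk groups downward; the
consecutive-enrolment scheme avoids that.)

Defaults emulate the motivating study's composition: 326 cases, 1:2
matching, 4 hospitals, 2 periods, 74 % male, ages 30–85, a focal SNP with
variant-allele frequency 0.64 (≈ 87 % carriers) and a null SNP at 0.22,
non-aspirin exposure 13 % and aspirin 3 % in the source population, H.
pylori (prevalence 0.77, outcome OR 2.5) and anticoagulant use (0.05, OR
3.1) as real confounders plus arthrosis as a null covariate, random-
intercept SDs 0.3, and a 7-day exposure window.  The baseline odds anchor
(0.25) is chosen so the source population yields enough cases for matching;
it is recorded in the truth record, which also stores every parameter, the
implied RERI/S truth, realized random effects and sampled group counts.

What the generator does **not** emulate: interview measurement error,
recall bias, serology misclassification, linkage disequilibrium between
panel SNPs, variable stratum sizes (controls per case is fixed; the real
design averaged ≈ 1:2.3 with variation), or secular exposure trends.
Passing tests therefore demonstrate the estimator's behaviour under the
assumed model, not robustness to those real-data features.

Two estimator-side caveats the simulations make visible: (a) group ORs
estimated by the unconditional random-intercept fit on matched data are
mildly attenuated relative to the conditional generative ORs
(non-collapsibility plus matched sampling), which shows up as a small
downward shift of RERI at the simulated effect sizes; (b) with a rare
wild-type allele the exposed/wild cell is small and single-replicate
estimates scatter widely — the tests therefore check medians and CI
coverage over seeds, not single draws.

## Problem sizes and determinism

Bundled fixtures are ≤ 200 subjects; simulation-based tests use 1000 cases
× 2 controls (the scale of the motivating design) with up to 50 seeded
replicates, and the exact-test oracle comparison runs 500 random tables of
n ≤ 200.  All randomness flows from explicit seeds (numpy `default_rng`);
model fitting is deterministic given data and starting values, and a
re-run of the pipeline with the same config and seed writes byte-identical
CSVs.
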