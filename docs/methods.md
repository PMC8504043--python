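# Methods

This note records the statistical model, the scoring rules, the synthetic
cohort generator and the numerical choices behind `rxqual`, including the
places where the design was genuinely open and what was decided.

## Assessment and scoring

Every prescription is rated against 20 criteria (met / not met / not
applicable). Criteria #1–#5 concern patient-level data (allergies, age,
weight, renal function, drug history), #6–#15 the formal completeness of the
order (validity, computer origin, legibility, substance abbreviations, drug
name, dose strength, dosage form, single dose with unit, dosage interval,
whole-number dose), and #16–#20 safe administration (clear risky-route
wording, body site, identifiable risks, reason for as-needed use, overall
completeness).

The packaged ruleset maps structured input fields to outcomes; every
predicate is replaceable, and the ruleset version string travels into every
result. Points where the underlying adjudication scheme had to be decided
here:

* **Applicability conventions.** Tri-state input fields (`None` = not
  applicable) drive the denominators: drug history does not apply to
  patients without pre-admission medication; the abbreviation criterion
  (#9) applies only where the displayed name contains an active-substance
  designation; dose strength (#11), single dose/unit (#13) and interval
  (#14) can be inapplicable for some formulations; the whole-number
  criterion (#15) applies only when a single-dose value exists; #16 applies
  to every order with a risky route, regular or as-needed; #17 only where a
  body site is required; #19 only to as-needed orders.
* **Risky routes** are a closed vocabulary (epidural, subcutaneous,
  gastrointestinal, via probe, ...) plus a prefix rule: any route token
  starting with `intra` (intravenous, intrathecal, ...) is risky. Tokens
  are normalised (lowercase, hyphens stripped) before lookup; unknown
  tokens are rejected at parse time.
* **Criterion #18** consumes a risk-flag count from an upstream medication
  review; the package does not perform interaction or dose checking.
* **Criterion #20** is an explicit input flag by default; a derived mode
  (conjunction of #10–#14, #16, #17 where applicable) is available and
  labelled as such.
* **Missing required fields raise errors** naming the prescription and
  criterion. Defaulting to "not met" would silently bias every score
  downward.

Scores: `prescription-Fscore = met/applicable` per order;
`criteria-Fscore = met/applicable` per criterion and cohort. Percentages
are rounded half away from zero to one decimal. Prescription counts per
patient and other dispersions use the sample SD (n−1).

The cohort-matching filter keeps post-implementation patients whose five
count variables (total and four category counts) all lie within one sample
SD of the pre-cohort means; the interval is closed at both ends ("within
one SD" read inclusively).

## Univariate comparisons

Score distributions are compared with the Mann–Whitney U test in its normal
approximation with tie correction (group sizes here are in the hundreds;
the exact method is not implemented), with effect size r = |z|/√n.
Criterion fulfilment is compared with Pearson's chi-squared on the 2×2
met/not-met table, without continuity correction by default (a switch is
exposed); the uncorrected variant reproduces the reference analysis of the
abbreviation criterion (p = 0.0115 → 0.012) more closely than the corrected
one (0.0136). Tables with a zero margin return p = 1 with a degenerate
flag. No multiplicity adjustment is applied across the 20 criterion tests.

## The beta GLMM

Transformed scores `y' = (y·(N−1)+0.5)/N` (N = all observations in the
analysis set) are modelled as

    y_ij | b_i ~ Beta(μ_ij φ, (1−μ_ij) φ),  logit(μ_ij) = x_ijᵀβ + b_i,
    b_i ~ N(0, σ_b²)

in the mean–precision parameterisation with a single constant φ (no
dispersion covariates). Fixed effects: intercept, time point, prescription
category (reference standard peroral), comedication count, and ward in
weighted effect coding — ward k ≠ ref scores 1 in its column, the reference
ward scores −w_k/w_ref, with w the ward's share of prescriptions, so each
ward column has prescription-weighted mean zero and coefficients are
deviations from the weighted hospital average. The reference ward's
coefficient is recovered as −Σ w_k/w_ref · β_k with a delta-method SE
(weights treated as fixed constants of the observed design); refitting with
a rotated reference is available as a cross-check and leaves predictions
unchanged.

**Estimation.** The marginal likelihood integrates each patient's beta
density product against the normal random-effect density. The integral is
approximated by adaptive Gauss–Hermite quadrature: a safeguarded Newton
search finds each patient's posterior mode of b, the integrand is rescaled
by the curvature there, and the Gauss–Hermite rule is applied on the
recentred axis (1 node = Laplace approximation; default 15 nodes,
configurable). Log-sum-exp keeps the per-patient aggregation stable.
Optimisation is L-BFGS-B over (β, log σ_b, log φ) from a deterministic
start — β from least squares on the logit outcome, σ_b = 0.1, φ = 10 — so
refits are bitwise reproducible. The analytic gradient differentiates the
quadrature sum with the node locations held fixed; the neglected mode-shift
term decays with the quadrature error and is negligible from ~11 nodes
(verified against central differences: max component error ~5e−4 at 11
nodes, ~2e−5 at 15). Model fits therefore use at least 11 nodes. The
covariance of the estimates is the inverse numerical Hessian (central
differences of the analytic gradient); Wald z = 1.96 intervals and p-values
match the reporting convention of the source analysis. σ_b = 0 exactly
reproduces fixed-effects beta regression (checked against statsmodels'
`BetaModel` to 1e−4 in coefficients), and the quadrature is checked against
dense brute-force integration on small fixtures to 1e−4.

**Predictions.** "Covariate-adjusted" predicted scores are population-level
(`b_i = 0`, plogis(xᵀβ)); empirical-Bayes conditional predictions are
available behind a flag since either reading of the source is defensible.
Net interventional effects are post-minus-pre differences of mean predicted
scores per category, in percentage points.

**E-value.** For OR ≥ 1, `E = OR + √(OR·(OR−1))`; estimates below 1 are
inverted first. Applied to the adjusted intervention OR of 10.11 this gives
19.7. The formula is applied to the odds ratio directly, as in the source
analysis; with a common outcome this overstates the risk-ratio-scale
E-value, which is the analyst's interpretive burden, not a computation
choice.

## Change patterns

Per criterion, each ward contributes a (pre, post) criteria-Fscore
trajectory. Patterns: A = directions differ; B = same direction, different
starts and ends; C = same direction and ends, different starts; D = same
starts, ends, direction. "Same" starts/ends means pairwise spread ≤ 2
percentage points; a trajectory is flat when |Δ| ≤ 1 point; flat mixed with
one direction counts as that direction, flat mixed with both directions as
differing. The reference study assigned patterns visually without a numeric
rule, so these tolerances are package defaults — small, documented,
configurable — and the classification is validated by its properties
(permutation invariance; raising the tolerance can only move criteria
toward D), not by matching the published icon assignments. Wards where a
criterion is never applicable at one time point are excluded from that
criterion's classification.

## Synthetic cohorts

The hospital data are not deposited, so the generator emulates their
structure at the study's own settings: 160 patients per arm (20 per ward,
40 on the double-sized ward 7), per-patient prescription counts from a
gamma distribution matched to mean ± SD (11.6 ± 5.6 pre, 10.0 ± 3.3 post),
rounded and truncated at ≥ 1 (positive, overdispersed counts; the source
reports only mean ± SD), category mixtures per arm (56.8/14.3/24.4/4.5% pre,
62.2/12.6/22.7/2.5% post), and the comedication count defined as the
patient's prescriptions minus one.

*Score level* draws transformed scores directly from the GLMM at the
published effect sizes (intervention OR 10.11, category ORs 0.76/0.59/0.87,
comedication OR 0.99, ward ORs from the published table, σ_b = 0.762).
φ = 30 is the one free parameter the source never reports; it was fixed
once so that conditional score dispersion is of the same order as the
published cohort SDs, and recovery simulations estimate it consistently.

*Record level* generates structured patient/prescription rows. Each
criterion outcome is Bernoulli on the logit scale with a patient-shared
latent shift (SD 0.762, the published random-intercept SD, taken as the
clustering calibration); the per-criterion offsets are debiased by
Gauss–Hermite quadrature so each configured marginal rate is matched in
expectation despite the latent variability. Applicability tri-states are
drawn at the published denominator shares (body-site requirement ~0.5% of
orders, echoing its tiny denominators); value-presence and the
single-dose/unit criterion are drawn jointly so both marginals hold; the
electronic-origin criterion follows the arm deterministically (paper
source pre, electronic post). Only the *marginal* applicability rates are
reproduced — the empirical joint distribution of tri-states is unknown.

*Study bundles* apply the one-SD matching filter to freshly drawn post
candidates until each ward reaches its quota, with a capped number of
rounds and diagnostics on failure.

What the generator does **not** emulate: drug identities and doses with
pharmacological meaning, criterion-to-criterion dependence beyond the
shared patient shift, prescriber- or workflow-level clustering below the
ward, temporal learning curves, and the joint tri-state distribution.
Passing tests on these cohorts therefore demonstrate correctness of the
computations and calibration of the marginals, not fidelity to any real
hospital's joint data distribution.

## Validation strategy and problem sizes

* Worked-example ratios and the E-value are exact checks against published
  counts.
* The quadrature is validated against 10,001-point dense integration on
  ≤ 5-patient fixtures over a grid of (σ_b, φ) values (tolerance 1e−4).
* The σ_b = 0 reduction is validated against statsmodels' independent beta
  regression (1e−4).
* Parameter recovery runs 50 replicates of 320 patients × ~10 orders at the
  published truth (OR 10.11, σ_b 0.762): relative bias of the log-OR below
  5%, 95% Wald coverage within [90%, 99%]. Fits use 11 quadrature nodes and
  a 1e−5 gradient tolerance, which the node-convergence checks show is well
  past the accuracy needed at this scale.
* Generator calibration pushes a full default cohort through the criteria
  engine and requires every criterion rate to sit within the 99% clustered
  binomial bound, the binomial variance inflated by the design effect
  1 + (m−1)·ICC implied a priori by the configured latent shift (ICC = 1
  for patient-level criteria, which are constant within a patient). The
  naive i.i.d. binomial bound would be miscalibrated for exactly the
  clustering the generator is designed to produce.
* Structural invariants (category partition, NA + applicable = 20, open
  interval and fixed point of the transformation, weighted-effect-coding
  zero sums, tolerance monotonicity of change patterns, end-to-end seed
  determinism) are asserted on generated cohorts, several via
  property-based testing.

## Known limitations

* Wald inference only; no profile-likelihood or bootstrap intervals.
* Single constant precision φ; no dispersion submodel; one random
  intercept, no crossed or nested effects.
* The default ruleset reverse-engineers applicability from criterion names
  and published denominators; a site's own adjudication scheme should be
  supplied as a custom ruleset where it differs.
* The exact-zero/one criterion rates are reproduced deterministically, so
  their sampling variability is not modelled.
* CSV inputs must be structured; there is no free-text or EHR-export
  parsing.
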