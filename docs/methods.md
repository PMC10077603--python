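# Methods

## Model

For each spirometry outcome (FEV1 in litres, FVC in litres, the
dimensionless FEV1/FVC ratio) and each sex, the reference distribution is
an LMS model with the skewness index fixed at L = 1:

    M(age, height) = exp(m_b0 + m_b1·ln(height) + m_b2·ln(age) + Mspline(age))
    S(age)         = exp(s_b0 + s_b1·ln(age) + Sspline(age))

Height is in cm, age in years. `M` is the predicted median, `S` the
coefficient of variation, and the spline terms are age-indexed additive
corrections stored as lookup tables (monotone cubic interpolation between
tabulated knots; constant extrapolation with a logged warning outside the
tabulated range, matching how published LMS lookup tables are used).

With L = 1 the model asserts normally distributed residuals: the Z-score
is the linear form `z = (y − M)/(M·S)` and the lower limit of normal is
`LLN = M·(1 + z_c·S)` with `z_c = Φ⁻¹(0.05) = −1.6449` by default
(reported as −1.64 at two decimals). A Box–Cox form
`((y/M)^L − 1)/(L·S)` is provided for other values of L but is not tuned.
The CV convention is `S = SD/M`, which is what makes "subtract the mean,
divide by the SD" consistent with the LLN formula above.

Piecewise-polynomial reference equations (polynomial segments in age and
height over abutting age intervals, value- and slope-continuous at the
joins to 1e−9) are supported as comparison models; they carry their own
additive SD segments and use `z = (y − mean)/SD`, `LLN = mean + z_c·SD`.
They are never extrapolated outside their covered age range.

## Fitting (the "rederived LMS" estimator)

Per outcome and sex, on a screened cohort of at least 30 subjects:

1. **Median stage.** Weighted penalized least squares of `ln y` on
   `[1, ln height, ln age]` plus a cubic B-spline in age (P-spline:
   second-order difference penalty on the basis coefficients). Interior
   knots (4 by default) sit at equally spaced age quantiles. The spline
   basis is projected, in-sample, onto the orthogonal complement of
   `[1, ln age]`, and coefficient directions that map to (near) zero in
   data space are removed by an eigendecomposition; this keeps the scalar
   coefficients identified and the penalized system well conditioned at
   any penalty weight. The penalty weight targets a fixed effective
   dimension (4 for the mean spline by default; a GCV grid search is
   available and is frozen after the first iteration because its discrete
   selection has no continuous fixed point under evolving weights).
   With `n_knots = 0` the stage is exactly unweighted ordinary least
   squares of the log-linear model — the brute-force-checkable baseline.

2. **Scatter stage.** The squared stage-1 log-residuals enter a penalized
   regression of `ln(r² + δ²σ²)` on `[1, ln age]` plus an age spline
   (effective dimension 2 by default). The small regularizer δ² = 0.01
   bounds the otherwise unbounded sensitivity of `ln r²` to near-zero
   residuals; the intercept is corrected by the exactly matching constant
   `−E[ln(χ²₁ + δ²)] = +1.0293` (the classic +1.2704 χ²₁ correction is the
   δ → 0 limit), so the fitted log-variance is unbiased under normality.
   The log-scale variance is converted to a CV via `S = sqrt(exp(σ²) − 1)`.

3. **Alternation.** The scatter model feeds inverse-variance weights back
   into the median stage. The working log-variance moves by a damped step
   (initially 0.5, halved when progress stalls), which suppresses the
   period-2 limit cycles the raw alternation can fall into on small
   cohorts. Convergence is declared when the fitted log-mean and damped
   log-variance curves change by less than 1e−6 (default) at the data
   points; convergence is judged on fitted curves rather than raw
   coefficients because individual scatter coefficients remain noisy at
   machine level even when the curves are stable. Up to 200 iterations;
   non-convergence raises an error carrying the iteration trace.

4. **Back-transform and recentring.** The fitted log-mean is exponentiated
   (the log-normal median). The intercept is then shifted by the
   closed-form constant `ln(mean y / mean M̂)` so the cohort-mean
   *linear-scale* residual (observed − predicted) is exactly zero. This
   matches the L = 1 normal-error reading of the model, under which
   residuals average zero in litres; a pure median back-transform would
   leave a systematic `≈ M·σ²/2` (about 0.015 L at S = 0.10) positive mean
   residual. The recentring is deterministic given the regression fit, so
   the zero-knot estimator remains reproducible by two lines of linear
   algebra (ordinary least squares plus the same shift).

Spline terms of the returned model are tabulated on a 0.5-year age grid
over the cohort's age range; the model's S-curve is stored as a log-linear
part plus a residual lookup so the fitted values are reproduced exactly at
the grid nodes.

## Screening

Before fitting, cohorts are screened against a reference registry
(defaults to the generator's truth models): airway obstruction is
FEV1/FVC below the ratio LLN, small FVC is FVC below the FVC LLN, and a
subject flagged by either is excluded. With calibrated references this
mechanically removes ≈5% healthy tails per criterion (nearly independent,
so ≈9.5% union) in addition to true pathology; a clinical review, which
the screen emulates, excludes fewer because it weighs the whole report.
Exclusion counts are monotone in the critical Z.

## Sampling variability

The cohort is partitioned into 10 disjoint subsets of near-equal size
(sizes differ by at most one), stratified by sex and age tertile so every
refit spans the age range, deterministically under a seed. Ten models are
fitted, each excluding one subset; predicted mean and LLN are evaluated on
an age grid at the sex-specific mean cohort height; the per-age min–max
envelope across the ten refits measures curve stability. The envelope is
widest at the edges of the age range (few subjects constrain the spline
there) and its width shrinks roughly as 1/√n.

## Model comparison

Residuals (observed − predicted, outcome units) are computed per subject
per model. Per model: one-sample t-test of zero mean and a
Kolmogorov–Smirnov normality test (against a normal with the sample's
estimated mean and SD; with estimated parameters this is the Lilliefors
variant, used descriptively). Across models: one-way repeated-measures
ANOVA on the within-subject residuals (computed from the subject × model
decomposition) with post-hoc paired t-tests, plus two-sample KS tests per
model pair. Repeated measures matches the paired post-hoc tests; no
multiple-testing correction is applied (raw p-values are reported; apply
Bonferroni externally if desired). Identical models are reported as
"no difference" (p = 1) rather than NaN. Z-score distributions are
summarized as moments, percentiles, below-LLN percentages by sex
(`100·#{z < z_c}/n`), and Gaussian-kernel densities (Silverman bandwidth)
tabulated on a grid for external plotting. The height–age association is
ordinary least squares of height on age per sex, reported as a positive
decline magnitude with 95% CI, r², F and p.

## Synthetic cohort generator

The generator emulates a population-based adult cohort from Northern
Sweden: two sexes of equal size (142 each by default, ≈284 total), ages
uniform on 20–90 years, cross-sectional height decline of 0.19 cm/year
(females) and 0.14 cm/year (males) around sex-specific trend lines
(intercepts chosen so the 40–60-year band means are 165.8/179.8 cm;
scatter SD 5.9/6.3 cm), body weight as a sex-specific normal, and a
smoking label (never/current/former/unknown) with frequencies mirroring a
questionnaire introduced mid-study; no model uses the smoking field.

Outcomes are drawn as `y = M·(1 + S·z)` with standard-normal `z` — i.e.
normal residuals with SD `M·S`, the distribution the L = 1 model asserts —
so the linear Z-score of a healthy subject under the generating model is
standard normal by construction and exactly 5% fall below the LLN. (A
log-normal generator was considered and rejected: with the linear Z-score
convention it puts ≈3.6% rather than 5% below the LLN at S = 0.10, which
would contradict the model's own calibration.) FEV1 and FVC share a
correlated z-pair (ρ = 0.84) so that violations of `0 < fev1 ≤ fvc` are
vanishingly rare (they are rejected and redrawn, leaving the marginals
calibrated) and the implied CV of the ratio is realistic; the ratio truth
model's S is set to exactly this implied CV, `sqrt(S₁² + S₂² − 2ρS₁S₂)`,
fitted once as a log-linear function of age and frozen, so the truth
registry describes the distribution the generator actually produces.

The truth M-curves are log-linear (spline terms zero) with height
exponents 2.10 (FVC) and 1.95 (FEV1) and intercept/age coefficients
solved once by least squares through three age-band anchors (ages 30, 50,
75 with trend heights and band mean volumes of a heart-healthy adult
cohort) and committed as frozen constants; the ratio truth model is the
exact coefficient difference of the FEV1 and FVC models. The log-linear
form cannot reproduce the flat-then-falling band pattern exactly, so band
mean volumes are approximate (the 40–60-year means are matched best);
band mean heights are matched exactly by construction.

Pathology is injected by multiplying FEV1 by 0.75 in a 6% subset
(obstructive pattern), and additionally FVC by 0.80 in 1/8 of those
(small-FVC pattern). What the generator does **not** emulate: blow-level
curves or measurement repeats, longitudinal ageing, smoking effects on
volumes, skewed (L ≠ 1) outcome distributions, and secular height trends.
Passing tests therefore demonstrate correctness of the estimation and
comparison machinery under the stated model, not robustness to the
messiness of real spirometry data.

## Numerical choices and degenerate inputs

- Critical Z default −1.6449 (Φ⁻¹(0.05)); configurable everywhere.
- Empty spline tables are the constant zero; single-knot tables are
  constant; duplicate or non-increasing knot ages are rejected.
- S is floored at 1e−12 so fitted models of (near) noiseless data remain
  valid (`S > 0`); a noiseless cohort yields an essentially zero-width
  subset envelope.
- Constant height (or any rank-deficient design) raises a rank-deficiency
  error; fewer than 30 subjects per sex refuses to fit.
- Identical models in a comparison report p = 1 ("no difference");
  a height trend on constant heights reports slope 0, F = 0.
- Problem sizes used by the shipped checks: calibration at 100,000
  subjects; parameter recovery at n = 5000 per sex over 20 replicates;
  subset variability at cohort sizes 270 and 540 over 20 and 10
  replicates — sizes at which Monte-Carlo error is small relative to the
  tolerances tested.

## Known limitations

- L is fixed (configurable but never estimated); no Box–Cox power search.
- The scatter stage estimates σ(age) from squared residuals rather than by
  full maximum likelihood; it is consistent and unbiased under normality
  but slightly less efficient than a GAMLSS-type ML fit.
- Adults only (age 18–95 by validation; default 20–90); no pediatric
  extension, no ethnicity adjustments, no upper limit of normal.
- The screened-cohort below-LLN percentages are conditional on screening
  with the same (or a correlated) reference and should not be read as
  population prevalences.
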