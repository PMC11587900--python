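# Methods

## Oxidative balance score

The OBS sums 0/1/2 points over 20 exposures: 16 dietary components
(14 antioxidants — fiber, carotene, riboflavin, niacin, vitamin B6, total
folate, dietary vitamin B12, vitamins C and E, calcium, magnesium, zinc,
copper, selenium — and 2 pro-oxidants, total fat and iron) and 4
lifestyle components (physical activity as MET score, antioxidant; serum
cotinine, alcohol and BMI, pro-oxidant).  The registry
(`src/obsmed/components.yaml`) is the source of truth and is validated
against the 16/4 and 5/15 count invariants; only the pro-oxidant set is
canonical, so the antioxidant list can be swapped per study.

Scoring conventions, all configurable but chosen once:

* **Tertiles** are the 1/3 and 2/3 empirical quantiles (inverted-CDF
  convention) computed *within gender* on the analytic sample.  Unweighted
  by default (`weighted_tertiles: false` switches to survey-weighted
  quantiles).
* **Tie rule**: a value exactly at a cutoff falls in the lower tertile
  (≤ rule), which makes scoring deterministic under heavy ties.
* **Alcohol** is categorical: exactly 0 g/day scores 2; below 15 (women) /
  30 (men) g/day scores 1; at or above the threshold scores 0.  The
  boundary is resolved to "heavy" because the threshold is defined by ≥.
* **BMI** is scored by gender-specific tertiles like every non-alcohol
  component, not by clinical classes.
* Participants missing any component receive no score and are flagged
  excluded.
* **Dichotomization**: low OBS iff total < cutoff.  The default cutoff is
  the first tertile of the score in the analytic sample (an externally
  supplied fractional cutoff such as 15.72 is honored exactly; note the
  dichotomization uses a strict <, unlike the tertile tie rule, so a
  total equal to the cutoff is "high").

## Survey-weighted estimation

Logistic models are fitted by weighted pseudo-maximum-likelihood
(statsmodels GLM with variance weights; weights are normalized to mean 1,
which changes nothing — all estimators here are invariant to rescaling
the weights).  The covariance is the design-based sandwich
`B⁻¹ G B⁻¹`: `B` is the weighted information matrix and `G` accumulates
`n_h/(n_h−1)` times the scatter of PSU score totals about their stratum
mean ("with-replacement" Taylor linearization, the standard choice for
NHANES-like designs; jackknife and replicate weights are out of scope).
Weights are treated as sampling, not frequency, weights — this affects
only variances.  Strata with a single PSU raise an error by default; a
documented option recenters them at the grand mean.  P-values use the
normal reference; a design-t reference on (#PSUs − #strata) degrees of
freedom is available via the fit's `design_df`.

With equal weights and one PSU per observation in one stratum everything
reduces exactly to the classical iid statistics (logistic MLE, arithmetic
mean, Pearson chi-square); the test suite asserts these reductions at
1e-6/1e-8.

The Rao–Scott test divides the Pearson statistic (computed from weighted
cell proportions at the actual sample size) by the mean generalized
design effect `tr(V₀⁺ V̂)/(K−1)`, where `V̂` is the linearized covariance
of the cell-proportion vector and `V₀` its multinomial counterpart with
denominator n−1; the correction is exactly 1 in the iid case.

Missing data are handled complete-case within each model fit unless the
multiple-imputation pathway is engaged.

## Restricted cubic splines and the mediator cutoff

The RCS basis is the standard restricted truncated-power form: k knots
give k−1 columns (x plus k−2 cubic terms), normalized by
`(t_k − t_1)²`, linear beyond the boundary knots for every coefficient
vector.  Default 4 knots at the 5th/35th/65th/95th percentiles (3 and 5
knots supported).  `p_overall` is the joint Wald test of all spline
terms, `p_nonlinear` of the nonlinear terms only — Wald rather than
likelihood-ratio because design-based fits maximize a pseudo-likelihood.

The inflection point is the first abscissa where the numerical slope of
the fitted log-odds curve changes sign on a 512-point grid between the
boundary knots; slope magnitudes below 1e-8 are treated as plateaus, and
multiple crossings are logged with the first returned.  The mediator
cutoff policy `nearest_quantile_median` snaps to the sample median when
it lies within 10% of the IQR from the inflection (reproducing the
"inflection ≈ median" logic without hard-coding a number), else keeps the
inflection.  In the pipeline, the inflection drives the cutoff only when
`p_nonlinear` is significant (default α = 0.05): with no evidence of
nonlinearity a detected slope reversal is sampling noise, and the median
is used instead.  Covariate adjustment and survey weighting are both on
by default for the spline fit.

## Mediation

All three path models are survey-weighted logistic regressions on the
same complete-case rows: `c` from outcome ~ exposure + covariates, `a`
from mediator ~ exposure + covariates, and `b`, `c′` from
outcome ~ exposure + mediator + covariates.  The indirect effect `a·b`
gets a **distribution-of-product** CI: empirical 2.5/97.5% quantiles of
`Z₁·Z₂`, `Z₁ ~ N(a, se_a²)`, `Z₂ ~ N(b, se_b²)` independent, by seeded
Monte Carlo (default 10⁶ draws; below 10⁴ a warning is raised).  The
independence of the two normals is the standard product-of-coefficients
assumption (the covariance across the two fits is not estimated).  A
Sobel interval is always reported alongside; the two agree (within 2%)
when both paths are many SEs from zero, and the Monte-Carlo quantiles are
validated against a 10⁷-draw oracle in the acceptance suite.

The mediated proportion is `a·b / c` — indirect over total on the log-OR
scale — validated against the published worked example
(0.071 / ln 1.61 = 14.9%).  Because log-odds ratios are non-collapsible
for binary outcomes, `c` need not equal `c′ + a·b`; the decomposition gap
is always reported, never hidden, and is small for rare outcomes.  A
sign-discordant `a·b` vs `c` (suppression) is flagged as inconsistent.
Subgroup analyses refit all models within each level, dropping the
stratifier from the covariate list; exposure and mediator cutoffs stay
global, matching a single published cutoff across subgroup rows.

## Multiple imputation

Education, WBC and serum vitamin B12 are imputed by chained univariate
regressions (10 cycles): linear regression with stochastic normal
residual draws for continuous columns, a weakly regularized multinomial
logit with categorical draws for education, on standardized demographic
and clinical predictors.  Parameters are not redrawn from their posterior,
so the procedure is "improper" MI — adequate at the 3–5% missingness the
generator emulates, and the MCAR-recovery test bounds its behavior
empirically.  Fits across the m completed tables are pooled by Rubin's
rules (mean coefficient; within-mean plus (1+1/m)·between covariance;
the standard degrees-of-freedom formula).  With zero missingness the MI
pathway reproduces the complete-case report exactly.

## Synthetic cohort generator

The generator emulates an NHANES-like hypertensive cohort: a balanced
stratified two-stage design (default 14 strata × 2 PSUs) with weights
drawn uniformly and independently of everything else (so weighted and
unweighted estimands coincide in truth, enabling recovery tests);
gender-shifted log-normal dietary intakes; a zero-inflated log-normal for
alcohol; a smoker/non-smoker cotinine mixture; and plausible demographic
and clinical marginals (dyslipidemia prevalence 0.80, matching the >80%
reported in the motivating cohort).

The causal structure is: the latent low-OBS indicator `L` is the bottom
tertile of the true OBS computed from the generated components (by the
same scoring code the analysis uses, so analysis-side rescoring agrees
with the latent truth); log MMA is normal (sd 0.45, median ≈150 nmol/L)
with a location shift for `L` solved numerically so that dichotomizing at
the distribution's median yields exactly the log-OR `alpha_m` (path a);
CVD is Bernoulli with logit = `gamma_direct·L + beta_m·M` + covariate
effects (age +0.40/decade, male +0.26, diabetes +0.59, dyslipidemia
+0.34 on the log-odds scale), intercept calibrated so the expected
prevalence equals `baseline_prevalence` (default 0.1963).  Defaults
inject path ORs 1.32 (a), 1.34 (b) and 1.50 (c′) at n = 4137 — the
magnitudes and scale of the motivating study.  Latent indicators are kept
in the output for oracle checks.

What the generator does **not** emulate: informative sampling (weights
correlated with outcome), questionnaire/recall measurement error,
multi-day intake averaging, energy adjustment, MET-score construction
from activity items (a MET variable is emitted directly), or any true
slope reversal in the MMA→CVD dose-response (the injected effect is a
monotone threshold).  Passing tests therefore demonstrate correctness of
the estimators under a well-specified survey design, not robustness to
those real-data complications.  Missingness is MCAR only, which is what
makes the MI sensitivity check interpretable.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen for tight-but-affordable Monte
Carlo error: 200 replicates of n = 20 000 for path recovery (coverage
≥90% required per path), 2000 replicates for distribution-of-product
coverage (93–97% band), 500 replicates of n = 4000 for the nonlinearity
type-I error (the Wald test is conservative at small n and near-nominal
by n = 4000), and 100 replicates of n = 1200 for MCAR recovery.  The
default pipeline run uses the study-scale n = 4137, so its mediation
estimates carry the same order of sampling noise as the motivating
analysis; the acceptance script also reports a 20 000-person recovery
replicate where the injected ORs are estimated with ~±5% error.

Other numerics: IRLS to tolerance 1e-10 with separation detection
(errors, never silent output); rank deficiency reported with the aliased
term names via pivoted QR; covariances symmetrized; the
distribution-of-product CI and all generators are seed-deterministic;
reports serialize ORs to 2 decimals and percentages to 1 decimal in CSVs
while the JSON keeps full precision.

## Known limitations

* Variance estimation is linearization-only (no BRR/Fay or jackknife).
* The mediation decomposition is on the odds-ratio scale and inherits
  its non-collapsibility; counterfactual (natural-effects) mediation and
  exposure–mediator interaction decompositions are out of scope.
* The inflection detector reports the first slope reversal only; formal
  change-point inference (segmented regression) is not attempted.
* Tertile cutoffs and the OBS cutoff are recomputed per analytic sample;
  externally fixed cutoffs must be passed explicitly for cross-cohort
  comparability.
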