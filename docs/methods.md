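# Methods

This package evaluates a means-restriction suicide-prevention program — the
removal of barbecue charcoal from open shelves to locked storage in one large
city — with a quasi-experimental design: the intervention city is compared
with two control cities before and after the program start (2012-05-01),
using method-specific death counts (charcoal-burning vs all other suicide
methods) and city populations. The pipeline has four statistical stages plus
a synthetic-data generator that makes every stage testable without registry
access.

## Data model

The unit of analysis is one *observation record*: site × method × time
interval, with count `y_i`, population `Pop_i` (held constant within each
calendar year), interval length `T_i` in days, and calendar covariate
weights. Daily records carry one-hot weekday/month indicators; weekly
records (2013, where registries release only weekly aggregates) carry the
average of the daily indicators over the days covered — 1/7 per weekday for
a full week, month weights proportional to the days falling in each month.
Records never straddle the intervention date; intervals are split there.
Deaths are classified by ICD-10 code: X67 and Y17 count as charcoal-burning
(intentional self-poisoning by other gases, plus the undetermined-intent
counterpart), the rest of X60–X84 and Y10–Y34 as other-method suicide.

Rates are annualized per 100,000 person-years with a 365.25-day year
everywhere; person-time sums `Pop_i × T_i`, so per-calendar-year populations
are handled exactly.

## Count regression

For record *i* the mean model is

    E[y_i] = Pop_i T_i exp{ b0 + B(t_i)b_tr + site + weekday + month
                            + post_i b_post + site_i×post_i b_extra }

a Poisson GLM with log link and offset `log(Pop_i T_i)`. The secular trend
`B(t)` is a clamped cubic B-spline (order 4) evaluated at the interval
midpoint, with evenly spaced interior knots; the first basis column is
dropped because the full clamped basis sums to one and an explicit intercept
is kept. The number of interior knots (candidates 0–10) is chosen by AIC,
ties resolved toward fewer knots. The reference cell is the reference
(control) city on a Monday in January before the intervention. `post` is the
common intervention-period level change shared with the reference city;
`post_x_<site>` is each other city's extra change — the intervention-city
*contrast* is the causal quantity of interest, and `post + post_x_<site>`
its *total* post-period change. Effects are reported as percent rate
reductions `100(1−exp(β))` with Wald intervals transformed from the log
scale. Fits are run separately per method category (charcoal / other / all).

After the Poisson fit, an auxiliary-regression dispersion test (one-sided,
alternative Var = (1+c)μ) checks equidispersion; if rejected at 5% the model
is refitted as NB2 (Var = μ + αμ²) with the dispersion estimated jointly by
maximum likelihood. Goodness of fit uses non-randomized PIT residuals: each
observation's probability mass is spread uniformly over
`[F_i(y_i−1), F_i(y_i)]`, the aggregate histogram should be uniform, and a
chi-squared statistic with bins−1 df summarizes departure. Two
finite-sample properties worth knowing: the dispersion test is conservative
when many parameters are estimated relative to the information (leverage
pulls squared residuals down) and its one-sided size approaches 5% slowly
(the auxiliary variable is asymptotically a scaled χ²₁, so the Edgeworth
error decays like n^(−1/2)); and with very sparse counts (daily means well
below 1) the discrete PIT spreads each observation's mass widely, making the
chi-squared check conservative — diagnostic calibration tests therefore run
in a moderate-count regime (means ~10) where the asymptotics hold.

## Nonparametric intensity

Counts are also viewed as a counting process with population-level rate
λ(t) = P(t)α(t); α(t), the per-capita intensity per 100,000 person-years, is
estimated by local-polynomial Poisson likelihood: at each grid time the
log-intensity is approximated by a polynomial in (t_i−t)/h, maximized under
Epanechnikov kernel weights, with sandwich (kernel-weighted information)
variances and normal intervals on the log scale. Pre- and post-intervention
segments are smoothed independently so the estimate may jump at the
intervention date. The *change-point rule* declares a downward change point
when the pre-boundary estimate exceeds the post segment's pointwise 95%
upper bound at the intervention date (one-sided).

Tuning defaults and their rationale:

* **Bandwidth 365 days.** One seasonal cycle; at the study's event rates
  (~0.66 charcoal deaths/day in the intervention city) shorter windows leave
  too few events for stable boundary estimates. An analytic power
  calculation (local-likelihood variance at the boundary) shows a 180-day
  local-linear window would detect the observed-size step (−0.31 on the log
  scale) in well under half of replicates.
* **Degree 1 (local linear) for curves**, the standard choice for boundary
  bias when drawing the full trajectory.
* **Degree 0 (local constant) for the boundary contrast** behind the
  change-point rule: at the boundary the local-linear equivalent kernel
  inflates variance roughly fourfold, costing most of the rule's power,
  while the local-constant boundary bias (≈ slope × 0.375h ≈ 0.02 on the
  log scale under the study-sized trend) is negligible against a 0.31 step.
  With these settings the rule detects the study-sized step in ~90% of
  replicates while the post CI excludes the true pre-boundary level in ~2.5%
  under a homogeneous null.
* The plug-in rule compares an *estimated* pre level with the post CI, so
  its null false-positive rate is not the CI's 2.5% but
  Φ̄(1.96·se_post/√(se_pre²+se_post²)) — about 8% when the two standard
  errors are comparable, and larger under a steep secular decline (the
  degree-0 boundary biases then push the two estimates apart). The tests
  check the rule against this oracle, and the 2.5% statement against the
  true pre level.

## Counterfactual lives saved

Let δ̂ be the intervention city's fitted post-period log change — by default
the *total* `post + post_x_<city>` (`city_total`), since the counterfactual
of interest is "no intervention period at all" for that city; removing only
the contrast (`city_specific`) is available as an option. Each
post-intervention record of the city gets the counterfactual mean
μ_cf = μ̂ exp(−δ̂); B = 10,000 replicates draw counts from the fitted family
at μ_cf, total them, and subtract the observed total. The median of the B
differences is the lives-saved estimate and the 2.5th/97.5th percentiles
(type-7 linear-interpolation quantiles, pinned for reproducibility) its 95%
interval. Because the interaction column is in the design, the maximum
likelihood score equations make the fitted intervention-cell total equal the
observed total exactly, so the estimate is approximately
`observed × (exp(−δ̂) − 1)`.

Coefficients are held at their point estimates: the simulation propagates
count-level (Poisson/NB) noise only. This matches an interval of width
≈ 2×1.96×√(Σμ_cf) ≈ 73 deaths at the study's scale; propagating the
uncertainty of δ̂ itself (SE ≈ 0.11) would roughly double the spread and is
deliberately not the default.

## Synthetic-data generator

The generator draws daily Poisson counts per site × method with log-mean
structure exactly matching the regression model: baseline annual rate per
100,000 person-years (interpreted at average seasonality — weekday and month
multipliers are normalized to geometric mean one), a cubic-B-spline secular
log-trend, and a step multiplier from the intervention date. Days from a
cutover date on are aggregated to weekly records (counts summed, weights
averaged), emulating the 2013 reporting change. `truth()` returns the
implied regression coefficients for parameter-recovery tests.

The calibrated default scenario (`study_scenario`) encodes the published
study conditions: three cities with populations 3.9M/2.7M/2.7M; the
2009-01-01–2013-12-31 calendar (1216 pre-intervention days, 610 post) with
weekly aggregation from 2013; baseline charcoal rates 6.2/3.5/5.3 and
other-method rates 12.3/10.8/14.9 per 100,000; charcoal intervention
log-effects +0.05 (common), −0.36 (intervention-city extra), −0.23
(adjacent-control extra); no effect on other methods. The secular trend is
linear on the log scale with pre-period mean zero and post-period mean −0.16
for charcoal (−0.02 for other methods) — the level that makes the published
intervention effects and the published pre/post counts mutually consistent
in all three cities. Seasonality defaults are modest and typical of suicide
time series (Monday peak ~+6%, spring peak/winter trough within ±10%).

What the generator does *not* emulate: day-of-month effects, holidays,
autocorrelation or clustering beyond Poisson noise, reporting delays,
age/sex structure, spatial spillover between adjacent cities, and
method-substitution dynamics. Passing tests therefore demonstrate that the
pipeline recovers the assumed data-generating structure at the study's
scale — not that real registry data satisfy that structure; the PIT and
dispersion diagnostics exist precisely to check the latter on real inputs.

## Numerical choices and degenerate inputs

* Local-likelihood maximization: damped Newton iterations (step clipped at 5
  on the log scale), converged at 1e-10; windows with no events return a
  zero estimate flagged degenerate with an infinite upper bound; bandwidths
  longer than a segment are truncated with a warning.
* GLM fitting uses iteratively reweighted least squares (tolerance 1e-10);
  the NB2 dispersion is profiled jointly via BFGS started at the Poisson
  solution; a dispersion estimate at the Poisson boundary (α < 1e-8, or a
  singular information matrix) returns the Poisson-equivalent fit with a
  warning.
* Structurally empty design columns (months never observed, intervention
  terms on pre-only subsets) are dropped and recorded; any remaining rank
  deficiency is an error naming the collinear columns.
* A perfect fit makes the dispersion statistic −∞ (not overdispersed) rather
  than dividing by zero.
* All randomness flows through `numpy.random.default_rng` seeds; a fixed
  seed reproduces generator output, pipeline bundles and simulation
  percentiles bit-for-bit.

## Problem sizes used in the test suite

Simulation-based checks use the study scale (three cities, two methods,
1,826 days, ~4.5k records per method fit) for parameter recovery (100
replicates), change-point power (200 replicates), and dispersion-test power;
diagnostic size/calibration checks run where their asymptotics apply
(intercept-only fits at n = 16,000, mean 10, 500 replicates for dispersion
size; 200 replicates at study scale for PIT); counterfactual consistency
uses B = 10,000. The full suite runs in about a minute on one core.

## Known limitations

* The control cities' published rates cannot be reproduced exactly from the
  rounded populations given (the study used exact per-year registry
  populations); descriptive checks therefore target the intervention city's
  counts and the published rate ratios.
* The all-methods fit treats the sum of two differently-affected Poisson
  streams as log-linear — a mild misspecification inherited from the study
  design.
* Weekly records enter at their midpoint with averaged dummies rather than
  being expanded to days; with a smooth trend the approximation error is
  negligible at h ≥ one year but grows for short bandwidths.
* No autocorrelation modelling, quasi-Poisson option, random effects,
  automatic bandwidth selection, or simultaneous confidence bands.
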