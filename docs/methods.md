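# Methods

## Model structure and assumptions

The cohort model has eight health states: hypertension (event-free), three
acute event states (stroke, CHD — carried as myocardial infarction in
reports — and heart failure), their three chronic sequels, and death. One
cycle is one year; a trapezoid half-cycle correction is applied to every
per-cycle accrual. The cohort enters in hypertension at the trial's mean age
(58.8 years) and is propagated by row-vector × matrix products until it
reaches the age cap of 100 years, after which any remaining occupancy is
moved to death so that years of life lost can be accounted at the cap. The
last modelled transition therefore kills survivors at the cap; for this
cohort fewer than 2% of entrants are still alive there, so the truncation
error is small and identical across strategies.

Structural choices made where the design was genuinely open:

* **Acute states last exactly one cycle.** Survivors of the acute year move
  to the matching post-event state; there is no return to the event-free
  state (no such arrow exists in the published state list).
* **Recurrent events** from post-event states re-enter the acute state of
  the new event. Their hazards are the first-event hazards scaled by a
  per-post-state multiplier carried in the parameter bundle (defaults 2.0
  after stroke, 1.5 after MI/HF — literature-order stand-ins).
* **Competing risks** within a cycle are resolved by rate-proportional
  allocation: probabilities are converted to rates r_i = −ln(1 − p_i), the
  one-cycle exit probability is 1 − exp(−Σr), and each cause receives its
  rate share. This is order-independent and conserves probability exactly,
  unlike sequential application of per-cause probabilities.
* **Sex** is handled as two independent cohort runs at the profile's mean
  covariates, pooled downstream at the trial sex mix (64.3% female).
  Heterogeneity beyond sex is out of scope; risk is evaluated at cohort-mean
  covariates with binary risk factors entering as prevalences.

## Risk equations

Each acute event carries a Framingham-style equation: a named coefficient
vector, an intercept (`baseline_term`), a published horizon H (10 years
here) and a functional form — logistic for stroke and CHD, a Weibull
survival form (shape 1.2) for heart failure. Coefficients are data, never
code: the published variants differ across sources and the original
study's exact choices are not public, so the engine is variant-agnostic and
the shipped coefficient set is a stand-in with published-style magnitudes
(log-odds ≈ 0.05/year of age, ≈ 0.011–0.017/mm Hg SBP, ≈ 0.5 for diabetes
or smoking).

The H-year risk is converted to a constant annual hazard
r = −ln(1 − p_H)/H; calibration factors κ multiply these hazards (and the
background-mortality and case-fatality hazards), which is the multiplicative
baseline-hazard scaling the calibration procedure expects. The treatment
effect is a shift of the SBP covariate (−4.99 mm Hg for the intervention,
floored at 1 mm Hg), applied before evaluation, so it propagates to every
event type through its SBP coefficient.

## Mortality, DALYs, costs

Background mortality is an age- and sex-specific life table (qx, ex).
Post-event and acute states multiply the background hazard by relative
risks ≥ 1; acute states add a first-cycle case fatality. Deaths during
cycle t are assigned mid-cycle time (t + ½) and mid-cycle age. YLL values
each death at the life table's residual expectancy ex(age), discounted as a
mid-year annuity from the time of death, with the death time itself
discounted to baseline. YLD is half-cycle-corrected prevalence × GBD-style
disability weight × cycle length, discounted at the cycle midpoint. Costs
combine annual state costs (routine hypertension care US$201/patient-year
in every living pre-terminal state, higher in post-event states), one-off
event costs charged on inflow to an acute state, and — for the intervention
only — US$10 per alive patient-year. The US$10 is treated as annual rather
than one-off because the published lifetime incremental cost (US$105)
exceeds any one-off reading; this is the main interpretive choice flagged as
open. Years alive are reported undiscounted (matching the magnitudes of the
published years-alive column); DALYs and costs use the 3% rate. The
DALY pipeline is used throughout; published mentions of "utility"/"QALY"
alongside exclusively DALY-denominated results are treated as terminology
for the same quantity.

## Calibration

Targets are cumulative all-cause mortality fractions at follow-up times
(default 2 and 5 years, trial-follow-up-like). The objective is the sum of
squared differences between model-predicted death occupancy (linearly
interpolated between cycle boundaries, pooled over sexes at the cohort mix)
and the targets, evaluated on the standard-of-care strategy —
trial-consistent mortality is a control-arm property. Minimisation runs
Nelder–Mead in log κ (positivity by construction; objective tolerance 1e−8,
500-iteration cap) seeded from the best point of a 7-point log-spaced grid
on [0.25, 4] per factor; non-convergence returns the best-found factors
flagged rather than raising. Which hazards get a free factor is an
argument; the default frees one factor on background mortality and one
shared across event case fatalities. With targets on all-cause mortality
alone those two are only weakly jointly identified, so the parameter-
recovery experiments free the background factor only.

## Probabilistic sensitivity analysis

Families follow convention per parameter class — beta for probabilities,
case fatalities and disability weights; gamma for costs; lognormal for
relative risks; normal for risk-equation coefficients and the SBP effect
(mean −4.99, SD 2.37 mm Hg from the trial's 95% CI) — all overridable in
the bundle, addressed by dotted parameter paths. Iteration i draws from
`numpy.random.default_rng([seed, i])`, a counter scheme that makes runs
bit-reproducible and order-independent. Draws that violate a bundle
invariant trigger a full joint redraw (cap 100); failed model evaluations
are skipped and logged, never resampled, and more than 1% failures aborts.
Intervals are equal-tailed 2.5th/97.5th empirical percentiles with the
inclusive linear-interpolation definition (`numpy.percentile`,
`method="linear"`). The CEAC is the fraction of draws with positive net
monetary benefit at each threshold.

## Synthetic inputs: what they emulate and what they do not

The generator produces the full input bundle the analysis needs. Published
constants are fixed and never randomized: the cohort profile, the SBP
effect, the US$10 and US$201 costs, 3% discounting, the US$183/500/1000
thresholds and the 10 000-iteration PSA setting. Three quantities are solved
numerically at generation time so the synthetic model sits at published
magnitudes: the Gompertz–Makeham life-table level per sex (slope 0.09,
Makeham constant 0.001/year) targets residual life expectancy at age 58.8 of
24 years (men) and 26 (women), which lands standard-of-care undiscounted
years alive in the published 19–23 band once cardiovascular mortality acts;
and each risk equation's intercept targets the published 10-year cumulative
incidence magnitudes (MI ≈ 0.19, stroke ≈ 0.048 men / 0.028 women,
HF ≈ 0.01). Remaining stand-ins (disability weights, event costs, relative
risks, case fatalities, recurrence multipliers) are drawn uniformly within
±10% of literature-order central values, deterministically in the recipe
seed.

What passing tests on this fixture do show: the arithmetic of the trace,
accrual, calibration and PSA machinery, and the qualitative published
pattern (intervention in the north-east quadrant, uniformly lower event
incidence, ICER above US$183 on the base inputs). What they do not show:
agreement with the original study's absolute costs, DALYs, ICERs or CEAC
probabilities, which depend on its unpublished input tables. The
incremental-table reconstruction (feeding the published per-strategy means
through the incremental analysis) is the only exact quantitative check
available, and it reproduces the printed incremental columns; the published
male ICER (234.34) is itself ~0.2% away from its own printed inputs
(101/0.43 = 234.9), and the printed pooled years-alive gain (0.19) exceeds
both sex-specific gains (0.17/0.18), so those cells are checked at the
precision their internal consistency supports.

## Numerical choices and problem sizes

Tolerances: transition-matrix rows sum to 1 within 1e−12, trace rows within
1e−10; serialization is canonical JSON (sorted keys), byte-reproducible;
life-table lookups interpolate linearly in age; CSV life tables are parsed
with round-trip float precision. Degenerate inputs: qx = 1 rows make every
living state transition to death; zero-risk bundles reduce the model to
pure background survival; a zero discount rate and zero weights reduce
DALYs to undiscounted YLL exactly.

Validation and test problem sizes were chosen to make each check decisive
while keeping the default runs desk-scale: the individual-level
microsimulation cross-check uses 200 000 patients (Monte-Carlo SE below
1.2 × 10⁻³ per occupancy cell), the noisy calibration-recovery study uses
50 seeds at noise SD 0.005, and the PSA contract checks use 2000
iterations; analysis scripts default to 1000 PSA iterations and the
acceptance script to 500, against the nominal 10 000 of the study settings
(CEAC Monte-Carlo error at 500 iterations is ≈ ±2 percentage points).

## Known limitations

Chronic kidney disease progression is not modelled (CKD enters only as a
risk-equation covariate), non-medical and indirect costs are excluded, and
the Framingham-style equations are not re-fitted to South Asian cohorts —
all inherited scope decisions of the analysis being reproduced. Post-event
risks do not depend on time since the event beyond the acute year, and the
cohort-mean covariate evaluation understates risk convexity relative to a
heterogeneous microsimulation.
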