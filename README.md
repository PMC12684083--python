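# cobra-cea

A lifetime Markov cost-effectiveness model of the COBRA-BPS community
hypertension-management programme versus standard of care (SoC) in Pakistan,
rebuilt as a tested, reusable Python pipeline for health economists and
modellers.

COBRA-BPS is a multi-component programme (community health-worker home
visits, blood-pressure monitoring and referral, provider training, triage
and care coordination) shown in a cluster-randomised trial to lower systolic
blood pressure by a mean of 4.99 mm Hg in rural Pakistan, at a programme
cost of US$10 per participant on top of US$201 per patient-year of routine
hypertension care. The question the model answers: projected over the
remaining lifetime of a hypertensive cohort, do the avoided strokes,
myocardial infarctions and heart-failure events justify the extra cost at
willingness-to-pay thresholds of US$183 (Pakistan's marginal productivity of
public health spending), US$500 and US$1000 per DALY averted?

## Model

An eight-state cohort state-transition model with one-year cycles and
half-cycle correction:

    HYPERTENSION → {STROKE, CHD, HF} → {POST_STROKE, POST_CHD, POST_HF} → DEATH

* The cohort enters at the trial profile (mean age 58.8 ± 11.5 years, 64.3%
  female, 25.8% diabetes, 41.9% CKD) in the hypertension state.
* First-event risks come from Framingham-style equations evaluated at the
  cohort's mean covariates per sex; the published H-year risk p is bridged
  to the annual cycle as 1 − (1 − p)^(1/H). The intervention enters solely
  through its SBP reduction (−4.99 mm Hg).
* Competing exits within a cycle are resolved through rates:
  p_i = (r_i / Σr)(1 − e^(−Σr)), so row probabilities conserve mass exactly.
* Acute event states last one cycle (case fatality plus relative-risk-scaled
  background mortality), then progress to chronic post-event states with
  elevated mortality and recurrent-event risk.
* DALYs = YLL + YLD: each death loses the life-table residual expectancy
  e(a) valued as a mid-year annuity; YLD is disability-weighted prevalence.
  Costs and DALYs are discounted at 3% per annum; years alive are reported
  undiscounted.
* Calibration multiplies selected baseline hazards by factors κ minimising
  the least-squares distance to observed cumulative all-cause mortality
  (Nelder–Mead over log κ, seeded by a coarse grid); coefficients are never
  re-estimated.
* The probabilistic sensitivity analysis jointly redraws all uncertain
  parameters (beta for probabilities and weights, gamma/lognormal for costs
  and relative risks, normal for coefficients and the SBP effect), re-runs
  both strategies per draw, and reports equal-tailed 95% intervals, the
  cost-effectiveness plane and the acceptability curve
  CEAC(λ) = P(λ·ΔE − ΔC > 0).

The original study's full input tables are not public; `synthetic_data`
generates a complete stand-in bundle whose published constants are fixed and
whose remaining values are solved or drawn to sit at published magnitudes
(see `docs/methods.md`).

## Worked example

```bash
python analysis/01_generate_fixture.py          # writes results/fixture/bundle.json
python analysis/02_base_case.py                 # deterministic lifetime model
python analysis/05_published_incrementals.py    # reconstruct the printed incremental table
```

`02_base_case.py` prints (synthetic-bundle run):

```
pooled incremental cost: US$126
pooled DALYs averted:    0.077
pooled years alive gain: 0.170
pooled ICER:             US$1629/DALY averted
NMB at US$183/DALY: -112 (not cost-effective)
```

i.e. on the synthetic inputs the programme gains health at extra cost
(north-east quadrant) and is not cost-effective at US$183/DALY — the
published qualitative verdict — while the absolute ICER depends on the
stand-in inputs. `05_published_incrementals.py` feeds the *published*
per-strategy means through the same incremental analysis and reproduces the
printed columns:

```
male:   dC 101.0 (printed 101.0), dE 0.430, ICER 234.88 (printed 234.34)
female: dC 108.0 (printed 108.0), dE 0.410, ICER 263.41 (printed 263.41)
pooled: dC 105.5 (printed 105.0), dE 0.417, ICER 252.92 (printed 252.4)
```

A `cobra-cea` command-line interface wraps the same steps
(`generate-fixtures`, `run-base-case`, `run-psa`, `calibrate`, `report`).

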