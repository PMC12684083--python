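"""Synthetic parameter bundles and calibration targets.

The original evaluation's full input set (risk-equation coefficients, life
table, disability weights, costs, relative risks, PSA hyperparameters) is
not public; only the headline quantities appear in the main text.  This
module generates a complete, validated stand-in bundle:

* Main-text constants are fixed, never randomized: cohort 58.8 ± 11.5 years,
  64.3% female, 25.8% diabetes, 41.9% CKD; SBP effect −4.99 mm Hg; programme
  cost US$10/participant-year; routine hypertension care US$201/patient-year;
  3% discounting; thresholds US$183/500/1000; 10 000 PSA iterations.
* The life table follows a Gompertz–Makeham hazard per sex, with the level
  solved so residual life expectancy at the cohort's baseline age matches a
  target (defaults chosen so standard-of-care years alive lands in the
  published 19–23 band).
* Risk-equation intercepts are solved so the 10-year event risks at baseline
  covariates sit at the magnitudes of the published 10-year cumulative
  incidences (MI ≈ 0.19, stroke ≈ 0.048/0.028 by sex, HF ≈ 0.01).

All other values (disability weights, event costs, relative risks, case
fatalities) are drawn uniformly from plausible ranges around literature-order
central values — they are synthetic stand-ins, not the original inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .calibration import CalibrationTarget, predicted_mortality, _with_kappa
from .parameters import (
    ACUTE_STATES,
    POST_STATES,
    AnalysisSettings,
    CohortProfile,
    CostSet,
    DisabilityWeightSet,
    HealthState,
    LifeTable,
    LifeTableRow,
    MortalityRRSet,
    ParameterBundle,
    PSADistribution,
    PSASettings,
    RiskEquationSpec,
    StrategySpec,
)
from .risk_engine import covariates_for, evaluate_risk_equation

__all__ = ["FixtureRecipe", "generate_bundle", "generate_calibration_targets",
           "default_bundle", "SOC", "COBRA"]

SOC = "SoC"
COBRA = "COBRA"

# published 10-year cumulative incidence magnitudes used to anchor intercepts
RISK_ANCHORS_10Y = {
    HealthState.STROKE: {"male": 0.048, "female": 0.028},
    HealthState.CHD: {"male": 0.187, "female": 0.190},
    HealthState.HF: {"male": 0.010, "female": 0.006},
}


@dataclass
class FixtureRecipe:
    """Everything needed to generate one synthetic bundle, deterministically.

    Ranges are (lo, hi) bounds for uniform draws; central values sit at the
    midpoints.  ``kappa_true`` and ``target_noise_sd`` drive the calibration
    parameter-recovery experiments.
    """

    seed: int = 0
    # Gompertz-Makeham: h(age) = makeham + level * exp(slope * (age - 30));
    # the level is solved per sex for the life-expectancy target below.
    gompertz_slope: float = 0.09
    makeham_constant: float = 0.001
    target_ex_at_baseline: dict[str, float] = field(
        default_factory=lambda: {"male": 24.0, "female": 26.0}
    )
    age_min: int = 30
    age_max: int = 110
    # uniform half-widths (relative) applied around central values
    cost_jitter: float = 0.10
    weight_jitter: float = 0.10
    rr_jitter: float = 0.10
    coefficient_jitter: float = 0.0
    # calibration-experiment knobs
    kappa_true: dict[str, float] = field(default_factory=dict)
    target_noise_sd: float = 0.005
    target_times: tuple[float, ...] = (2.0, 5.0)


# central values for the synthetic stand-in inputs -------------------------
_WEIGHTS = {
    HealthState.HYPERTENSION: 0.0,
    HealthState.STROKE: 0.32,
    HealthState.POST_STROKE: 0.19,
    HealthState.CHD: 0.42,
    HealthState.POST_CHD: 0.08,
    HealthState.HF: 0.28,
    HealthState.POST_HF: 0.19,
}
_ANNUAL_COSTS = {
    HealthState.POST_STROKE: 280.0,
    HealthState.POST_CHD: 230.0,
    HealthState.POST_HF: 310.0,
}
_EVENT_COSTS = {
    HealthState.STROKE: 1450.0,
    HealthState.CHD: 1180.0,
    HealthState.HF: 890.0,
}
_RR = {
    HealthState.STROKE: 2.2,
    HealthState.POST_STROKE: 2.2,
    HealthState.CHD: 1.8,
    HealthState.POST_CHD: 1.8,
    HealthState.HF: 2.6,
    HealthState.POST_HF: 2.6,
}
_CASE_FATALITY = {
    HealthState.STROKE: 0.30,
    HealthState.CHD: 0.23,
    HealthState.HF: 0.25,
}
_RECURRENCE = {
    HealthState.POST_STROKE: 2.0,
    HealthState.POST_CHD: 1.5,
    HealthState.POST_HF: 1.5,
}
# Framingham-style log-odds (log-rate for HF) weights
_COEFFICIENTS = {
    HealthState.STROKE: {
        "age": 0.055, "male": 0.55, "sbp": 0.017, "diabetes": 0.60,
        "smoker": 0.50, "ckd": 0.40, "total_chol": 0.002, "hdl": -0.008,
    },
    HealthState.CHD: {
        "age": 0.048, "male": -0.02, "sbp": 0.011, "diabetes": 0.50,
        "smoker": 0.55, "ckd": 0.30, "total_chol": 0.006, "hdl": -0.012,
    },
    HealthState.HF: {
        "age": 0.060, "male": 0.45, "sbp": 0.012, "diabetes": 0.50,
        "smoker": 0.20, "ckd": 0.50, "total_chol": 0.001, "hdl": -0.005,
    },
}
_HF_WEIBULL_SHAPE = 1.2

_SBP_EFFECT_MEAN = -4.99
# trial 95% CI −9.63 to −0.35 mm Hg -> normal sd
_SBP_EFFECT_SD = (9.63 - 0.35) / (2 * 1.96)


def _jitter(rng: np.random.Generator, central: float, rel: float) -> float:
    if rel <= 0:
        return central
    return float(central * rng.uniform(1 - rel, 1 + rel))


def _gompertz_qx(age: np.ndarray, level: float, slope: float, makeham: float) -> np.ndarray:
    hazard = makeham + level * np.exp(slope * (age - 30.0))
    return -np.expm1(-hazard)


def _life_expectancy(qx: np.ndarray) -> np.ndarray:
    """ex per age from qx by standard arithmetic (half-year of death credit).

    With l the survival curve from the first age, the person-years lived in
    year j per person alive at age i are (l_j / l_i)(1 - qx_j / 2), so
    ex_i = sum_{j >= i} l_j (1 - qx_j / 2) / l_i.
    """
    l = np.concatenate([[1.0], np.cumprod(1.0 - qx[:-1])])
    w = l * (1.0 - 0.5 * qx)
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.cumsum(w[::-1])[::-1] / l
    # ages nobody reaches (l = 0): certain death within the year, half-year credit
    return np.where(l > 0, ex, 0.5)


def _build_life_table(recipe: FixtureRecipe, baseline_age: float) -> LifeTable:
    ages = np.arange(recipe.age_min, recipe.age_max + 1, dtype=float)
    rows: list[LifeTableRow] = []
    for sex in ("male", "female"):
        target = recipe.target_ex_at_baseline[sex]

        def ex_error(log_level: float) -> float:
            qx = _gompertz_qx(ages, math.exp(log_level), recipe.gompertz_slope,
                              recipe.makeham_constant)
            qx[-1] = 1.0
            ex = _life_expectancy(qx)
            return float(np.interp(baseline_age, ages, ex)) - target

        log_level = optimize.brentq(ex_error, math.log(1e-7), math.log(5e-3), xtol=1e-10)
        qx = _gompertz_qx(ages, math.exp(log_level), recipe.gompertz_slope,
                          recipe.makeham_constant)
        qx[-1] = 1.0
        ex = _life_expectancy(qx)
        rows.extend(
            LifeTableRow(age=int(a), sex=sex, qx=float(q), ex=float(e))
            for a, q, e in zip(ages, qx, ex)
        )
    return LifeTable(rows=rows)


def _solve_intercept(
    spec_wo_intercept: RiskEquationSpec, cohort: CohortProfile, target_mean_risk: float,
    w_female: float,
) -> float:
    """Intercept such that the sex-mix-weighted 10-year risk at baseline
    covariates equals the anchor."""

    def risk_at(b0: float) -> float:
        spec = spec_wo_intercept.model_copy(update={"baseline_term": b0})
        total = 0.0
        for sex, w in (("male", 1 - w_female), ("female", w_female)):
            cov = _baseline_cov(cohort, sex)
            total += w * evaluate_risk_equation(spec, cov)
        return total - target_mean_risk

    return optimize.brentq(risk_at, -40.0, 10.0, xtol=1e-12)


def _baseline_cov(cohort: CohortProfile, sex: str):
    from .risk_engine import CovariateVector

    return CovariateVector(
        age=cohort.mean_age,
        male=1.0 if sex == "male" else 0.0,
        sbp=cohort.mean_sbp,
        diabetes=cohort.prop_diabetes,
        smoker=cohort.prop_smoker,
        ckd=cohort.prop_ckd,
        total_chol=cohort.mean_total_chol,
        hdl=cohort.mean_hdl,
    )


def _beta_params(mean: float, sd: float) -> dict[str, float]:
    k = mean * (1 - mean) / sd**2 - 1
    return {"alpha": mean * k, "beta": (1 - mean) * k}


def _gamma_params(mean: float, sd: float) -> dict[str, float]:
    shape = (mean / sd) ** 2
    return {"shape": shape, "scale": mean / shape}


def generate_bundle(recipe: FixtureRecipe | None = None) -> ParameterBundle:
    """Generate a complete validated bundle, deterministic in the recipe seed."""
    recipe = recipe or FixtureRecipe()
    rng = np.random.default_rng(recipe.seed)

    cohort = CohortProfile(
        mean_age=58.8, sd_age=11.5, prop_female=0.643, prop_diabetes=0.258,
        prop_ckd=0.419, prop_smoker=0.13, mean_sbp=146.4,
        mean_total_chol=200.0, mean_hdl=45.0,
    )
    life_table = _build_life_table(recipe, cohort.mean_age)

    weights = {
        s: (0.0 if s is HealthState.HYPERTENSION
            else min(_jitter(rng, w, recipe.weight_jitter), 1.0))
        for s, w in _WEIGHTS.items()
    }
    annual_costs = {s: 0.0 for s in HealthState}
    annual_costs[HealthState.HYPERTENSION] = 201.0
    for s in ACUTE_STATES:  # routine care continues through the acute year
        annual_costs[s] = 201.0
    for s, c in _ANNUAL_COSTS.items():
        annual_costs[s] = _jitter(rng, c, recipe.cost_jitter)
    event_costs = {s: _jitter(rng, c, recipe.cost_jitter) for s, c in _EVENT_COSTS.items()}

    rr = {s: max(_jitter(rng, v, recipe.rr_jitter), 1.0) for s, v in _RR.items()}
    case_fatality = {
        s: min(_jitter(rng, v, recipe.rr_jitter), 1.0) for s, v in _CASE_FATALITY.items()
    }

    risk_equations = []
    for event in ACUTE_STATES:
        coeffs = {
            name: _jitter(rng, beta, recipe.coefficient_jitter)
            for name, beta in _COEFFICIENTS[event].items()
        }
        form = "weibull_survival" if event is HealthState.HF else "logistic"
        spec = RiskEquationSpec(
            event=event, coefficients=coeffs, baseline_term=0.0,
            horizon_years=10, functional_form=form,
            weibull_shape=_HF_WEIBULL_SHAPE if event is HealthState.HF else 1.0,
        )
        anchors = RISK_ANCHORS_10Y[event]
        mean_risk = (1 - cohort.prop_female) * anchors["male"] + cohort.prop_female * anchors["female"]
        b0 = _solve_intercept(spec, cohort, mean_risk, cohort.prop_female)
        risk_equations.append(spec.model_copy(update={"baseline_term": b0}))

    strategies = [
        StrategySpec(name=SOC, sbp_delta=0.0, adds_intervention_cost=False),
        StrategySpec(name=COBRA, sbp_delta=_SBP_EFFECT_MEAN, adds_intervention_cost=True),
    ]

    distributions: dict[str, PSADistribution] = {
        "strategies.COBRA.sbp_delta": PSADistribution(
            family="normal", params={"mu": _SBP_EFFECT_MEAN, "sigma": _SBP_EFFECT_SD}
        ),
        "costs.intervention_cost_per_cycle": PSADistribution(
            family="gamma", params=_gamma_params(10.0, 2.0)
        ),
        "costs.annual_state_cost.HYPERTENSION": PSADistribution(
            family="gamma", params=_gamma_params(201.0, 20.0)
        ),
    }
    for s in POST_STATES:
        distributions[f"costs.annual_state_cost.{s.value}"] = PSADistribution(
            family="gamma", params=_gamma_params(annual_costs[s], 0.2 * annual_costs[s])
        )
        distributions[f"mortality.rr.{s.value}"] = PSADistribution(
            family="lognormal", params={"mu": math.log(rr[s]), "sigma": 0.1}
        )
        distributions[f"disability_weights.weights.{s.value}"] = PSADistribution(
            family="beta", params=_beta_params(weights[s], 0.1 * weights[s])
        )
    for s in ACUTE_STATES:
        distributions[f"costs.event_cost.{s.value}"] = PSADistribution(
            family="gamma", params=_gamma_params(event_costs[s], 0.2 * event_costs[s])
        )
        distributions[f"mortality.case_fatality.{s.value}"] = PSADistribution(
            family="beta", params=_beta_params(case_fatality[s], 0.1 * case_fatality[s])
        )
        distributions[f"disability_weights.weights.{s.value}"] = PSADistribution(
            family="beta", params=_beta_params(weights[s], 0.1 * weights[s])
        )
        # uncertainty in the risk equations themselves: intercept and SBP slope
        spec = next(e for e in risk_equations if e.event is s)
        distributions[f"risk_equations.{s.value}.baseline_term"] = PSADistribution(
            family="normal", params={"mu": spec.baseline_term, "sigma": 0.08}
        )
        distributions[f"risk_equations.{s.value}.coefficients.sbp"] = PSADistribution(
            family="normal",
            params={"mu": spec.coefficients["sbp"], "sigma": 0.15 * spec.coefficients["sbp"]},
        )

    return ParameterBundle(
        cohort=cohort,
        risk_equations=risk_equations,
        life_table=life_table,
        disability_weights=DisabilityWeightSet(weights=weights),
        costs=CostSet(
            annual_state_cost=annual_costs,
            event_cost=event_costs,
            intervention_cost_per_cycle=10.0,
            currency_year=2023,
        ),
        mortality=MortalityRRSet(rr=rr, case_fatality=case_fatality),
        strategies=strategies,
        settings=AnalysisSettings(
            cycle_length=1.0, age_cap=100.0, discount_rate=0.03,
            thresholds=[183.0, 500.0, 1000.0], half_cycle_correction=True,
        ),
        psa=PSASettings(n_iterations=10_000, seed=recipe.seed, distributions=distributions),
        recurrence_multiplier=dict(_RECURRENCE),
    )


def default_bundle() -> ParameterBundle:
    """The default fixture bundle (recipe seed 0)."""
    return generate_bundle(FixtureRecipe())


def generate_calibration_targets(
    bundle: ParameterBundle,
    kappa_true: dict[str, float],
    times: tuple[float, ...] = (2.0, 5.0),
    sigma: float = 0.0,
    seed: int = 0,
    sex: str = "pooled",
) -> list[CalibrationTarget]:
    """Model-generated mortality targets under known hazard scalings.

    Runs the comparator strategy with ``kappa_true`` applied, reads cumulative
    all-cause mortality at each time, adds independent N(0, sigma) noise and
    clamps to [0, 1].  With sigma = 0 the targets are exactly the model's own
    mortality, so calibration should recover ``kappa_true``.
    """
    rng = np.random.default_rng(seed)
    scaled = _with_kappa(bundle, kappa_true)
    soc = bundle.strategy(SOC)
    out = []
    for t in sorted(times):
        m = predicted_mortality(scaled, soc, t, sex)
        if sigma > 0:
            m = float(np.clip(m + rng.normal(0.0, sigma), 0.0, 1.0))
        out.append(CalibrationTarget(time_years=t, cum_mortality=m, sex=sex))
    return out
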