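"""Per-cycle probabilities of first cardiovascular events.

Each acute event (stroke, CHD/MI, heart failure) has a Framingham-style risk
equation giving the probability of the event over a published horizon H
(typically 10 years) as a function of the cohort's covariates.  The engine

1. applies the strategy's systolic-blood-pressure effect to the covariates,
2. evaluates each equation's functional form (logistic or Weibull survival),
3. rescales the implied hazard by the calibration factor kappa for that event,
4. bridges the H-year risk to the 1-year model cycle, and
5. jointly normalizes competing events through rates so the total one-cycle
   transition probability can never exceed 1.

Coefficients are data, never code: the published equation variants differ,
so the engine is variant-agnostic and the fixture ships one published-style
coefficient set per event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .parameters import (
    ACUTE_STATES,
    HealthState,
    ParameterBundle,
    RiskEquationSpec,
    Sex,
    StrategySpec,
)

__all__ = [
    "CovariateVector",
    "covariates_for",
    "apply_sbp_effect",
    "multiyear_risk_to_annual_prob",
    "evaluate_risk_equation",
    "annual_event_probabilities",
    "normalize_competing",
]

SBP_FLOOR_MMHG = 1.0


@dataclass(frozen=True)
class CovariateVector:
    """Covariate values at which a risk equation is evaluated.

    The cohort model evaluates risk at the profile's mean covariates, with
    binary risk factors entering as cohort fractions, stratified by sex.
    """

    age: float
    male: float
    sbp: float
    diabetes: float
    smoker: float
    ckd: float
    total_chol: float
    hdl: float

    def __post_init__(self) -> None:
        if self.sbp <= 0:
            raise ValueError(f"sbp must be positive, got {self.sbp}")
        if not 0 <= self.male <= 1:
            raise ValueError("male indicator must lie in [0,1]")

    def value(self, name: str) -> float:
        if name == "female":
            return 1.0 - self.male
        try:
            return getattr(self, name)
        except AttributeError:
            raise KeyError(f"risk equation requires unknown covariate {name!r}")


def covariates_for(bundle: ParameterBundle, sex: Sex, age: float | None = None) -> CovariateVector:
    """Mean-covariate vector for one sex at a given age (default: baseline)."""
    c = bundle.cohort
    return CovariateVector(
        age=c.mean_age if age is None else age,
        male=0.0 if sex == "female" else 1.0,
        sbp=c.mean_sbp,
        diabetes=c.prop_diabetes,
        smoker=c.prop_smoker,
        ckd=c.prop_ckd,
        total_chol=c.mean_total_chol,
        hdl=c.mean_hdl,
    )


def apply_sbp_effect(cov: CovariateVector, strategy: StrategySpec) -> CovariateVector:
    """Shift systolic blood pressure by the strategy's effect (mm Hg).

    The intervention's mean SBP reduction (default −4.99 mm Hg) enters the
    risk equations through this shift.  SBP is floored at 1 mm Hg so a large
    sampled effect can never produce a non-physical covariate.
    """
    if strategy.sbp_delta == 0:
        return cov
    return replace(cov, sbp=max(cov.sbp + strategy.sbp_delta, SBP_FLOOR_MMHG))


def multiyear_risk_to_annual_prob(p: float, horizon_years: int) -> float:
    """Convert a probability over H years to the equivalent annual probability
    under constant hazard: 1 − (1 − p)^(1/H)."""
    if not 0 <= p <= 1:
        raise ValueError(f"risk must lie in [0,1], got {p}")
    if horizon_years < 1:
        raise ValueError("horizon must be at least one year")
    if p == 1.0:
        return 1.0
    return 1.0 - (1.0 - p) ** (1.0 / horizon_years)


def _linear_predictor(spec: RiskEquationSpec, cov: CovariateVector) -> float:
    return sum(beta * cov.value(name) for name, beta in spec.coefficients.items())


def evaluate_risk_equation(spec: RiskEquationSpec, cov: CovariateVector) -> float:
    """H-year event risk from one equation at the given covariates.

    logistic:          p_H = expit(baseline_term + x'beta)
    weibull_survival:  p_H = 1 − exp(−exp(baseline_term + x'beta) · H^shape)
    """
    lp = spec.baseline_term + _linear_predictor(spec, cov)
    if spec.functional_form == "logistic":
        if lp >= 0:
            return 1.0 / (1.0 + math.exp(-lp))
        e = math.exp(lp)  # overflow-safe branch for very negative predictors
        return e / (1.0 + e)
    scale = math.exp(min(lp, 700.0))
    return -math.expm1(-scale * spec.horizon_years ** spec.weibull_shape)


def annual_event_rate(
    spec: RiskEquationSpec, cov: CovariateVector, kappa: float = 1.0
) -> float:
    """Calibrated annual event hazard: the H-year risk converted to a constant
    annual rate, multiplied by the calibration factor for this event."""
    if kappa <= 0:
        raise ValueError(f"calibration factor must be positive, got {kappa}")
    p_h = evaluate_risk_equation(spec, cov)
    if p_h >= 1.0:
        return math.inf
    return kappa * (-math.log1p(-p_h) / spec.horizon_years)


def normalize_competing(rates: dict[HealthState, float]) -> dict[HealthState, float]:
    """Allocate competing risks proportionally to their rates.

    With total rate R = sum r_i, the one-cycle exit probability is
    1 − exp(−R); each event receives the share r_i / R of it.  Exit
    probabilities plus the stay probability exp(−R) therefore sum to exactly
    one, independent of any event ordering.
    """
    total = sum(rates.values())
    if total == 0:
        return {k: 0.0 for k in rates}
    if math.isinf(total):
        finite = {k: (0.0 if math.isfinite(r) else 1.0) for k, r in rates.items()}
        n_inf = sum(finite.values())
        return {k: v / n_inf for k, v in finite.items()}
    exit_prob = -math.expm1(-total)
    return {k: exit_prob * r / total for k, r in rates.items()}


def annual_event_probabilities(
    cov: CovariateVector,
    specs: list[RiskEquationSpec],
    kappa: dict[str, float] | None = None,
) -> dict[HealthState, float]:
    """Competing-risk-normalized annual first-event probabilities.

    ``kappa`` maps event-state names (e.g. ``"STROKE"``) to multiplicative
    hazard scalings; absent entries default to 1 (uncalibrated).
    """
    kappa = kappa or {}
    events = [spec.event for spec in specs]
    if sorted(e.value for e in events) != sorted(s.value for s in ACUTE_STATES):
        raise ValueError("need exactly one risk equation per acute event")
    rates = {
        spec.event: annual_event_rate(spec, cov, kappa.get(spec.event.value, 1.0))
        for spec in specs
    }
    return normalize_competing(rates)
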