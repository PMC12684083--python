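"""Shared fixtures: the default synthetic bundle and small toy models."""

from __future__ import annotations

import numpy as np
import pytest

from cobra_cea.markov_engine import N_STATES, Trace, TransitionMatrix, _IDX
from cobra_cea.parameters import (
    AnalysisSettings,
    CohortProfile,
    CostSet,
    DisabilityWeightSet,
    HealthState,
    LifeTable,
    LifeTableRow,
    MortalityRRSet,
    ParameterBundle,
    PSASettings,
    RiskEquationSpec,
    StrategySpec,
)
from cobra_cea.pipeline import evaluate_bundle
from cobra_cea.synthetic_data import _life_expectancy, default_bundle


@pytest.fixture(scope="session")
def bundle() -> ParameterBundle:
    return default_bundle()


@pytest.fixture(scope="session")
def base_case(bundle):
    """Both strategies, both sexes, pooled, incrementals — computed once."""
    return evaluate_bundle(bundle)


def constant_qx_life_table(q: float, age_min: int = 30, age_max: int = 110) -> LifeTable:
    ages = np.arange(age_min, age_max + 1)
    qx = np.full(len(ages), q)
    qx[-1] = 1.0
    ex = _life_expectancy(qx)
    rows = [
        LifeTableRow(age=int(a), sex=sex, qx=float(qv), ex=float(e))
        for sex in ("male", "female")
        for a, qv, e in zip(ages, qx, ex)
    ]
    return LifeTable(rows=rows)


def make_toy_bundle(
    q: float = 0.1,
    event_log_rate: float = -1000.0,
    age_cap: float = 100.0,
    discount_rate: float = 0.0,
    annual_hypertension_cost: float = 0.0,
    disability_weights: dict | None = None,
) -> ParameterBundle:
    """Minimal bundle: constant background mortality q, (by default) zero
    event risk, zero costs and weights — the analytically tractable limit."""
    weights = {s: 0.0 for s in HealthState if s is not HealthState.DEATH}
    if disability_weights:
        weights.update(disability_weights)
    annual = {s: 0.0 for s in HealthState}
    annual[HealthState.HYPERTENSION] = annual_hypertension_cost
    specs = [
        RiskEquationSpec(
            event=e, coefficients={}, baseline_term=event_log_rate,
            horizon_years=10, functional_form="weibull_survival",
        )
        for e in (HealthState.STROKE, HealthState.CHD, HealthState.HF)
    ]
    return ParameterBundle(
        cohort=CohortProfile(
            mean_age=58.8, sd_age=11.5, prop_female=0.643, prop_diabetes=0.258,
            prop_ckd=0.419, prop_smoker=0.13, mean_sbp=146.4,
            mean_total_chol=200.0, mean_hdl=45.0,
        ),
        risk_equations=specs,
        life_table=constant_qx_life_table(q),
        disability_weights=DisabilityWeightSet(weights=weights),
        costs=CostSet(
            annual_state_cost=annual,
            event_cost={},
            intervention_cost_per_cycle=10.0,
        ),
        mortality=MortalityRRSet(
            rr={},
            case_fatality={s: 0.0 for s in (HealthState.STROKE, HealthState.CHD, HealthState.HF)},
        ),
        strategies=[
            StrategySpec(name="SoC"),
            StrategySpec(name="COBRA", sbp_delta=-4.99, adds_intervention_cost=True),
        ],
        settings=AnalysisSettings(discount_rate=discount_rate, age_cap=age_cap),
        psa=PSASettings(n_iterations=10, seed=0, distributions={}),
    )


def manual_trace(alive: list[float], sex: str = "male", age0: float = 60.0) -> Trace:
    """Trace fully in HYPERTENSION with the given alive fractions per cycle
    boundary, identity dynamics (no events)."""
    n = len(alive)
    occ = np.zeros((n, N_STATES))
    occ[:, _IDX[HealthState.HYPERTENSION]] = alive
    occ[:, _IDX[HealthState.DEATH]] = 1.0 - np.asarray(alive)
    ident = np.eye(N_STATES)
    matrices = [TransitionMatrix(probs=ident, cycle=t, sex=sex) for t in range(n - 1)]
    ages = age0 + np.arange(n, dtype=float)
    return Trace(occupancy=occ, ages=ages, sex=sex, strategy="SoC", matrices=matrices)
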