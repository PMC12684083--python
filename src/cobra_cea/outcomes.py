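"""Discounted life years, DALYs (YLL + YLD) and costs from a trace.

Accrual conventions
-------------------
* Half-cycle correction: state membership during cycle t is the trapezoid
  mean of the occupancies at boundaries t and t+1.
* Per-cycle accruals (life years, YLD, state costs) are discounted at the
  cycle midpoint t + 1/2; one-off event costs likewise, since events occur
  during the cycle.
* Years of life lost: each death during cycle t loses the life table's
  residual expectancy ex at the mid-cycle age; the lost-year stream is valued
  as a mid-year annuity discounted from the time of death, and the time of
  death is itself discounted to cycle 0.
* "Years alive" is reported undiscounted; costs and DALYs at the settings
  rate (3% per annum by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .markov_engine import Trace, cumulative_incidence, _IDX
from .parameters import (
    ACUTE_STATES,
    LIVING_STATES,
    STATE_ORDER,
    AnalysisSettings,
    CostSet,
    DisabilityWeightSet,
    HealthState,
    LifeTable,
    ParameterBundle,
    Sex,
    StrategySpec,
)

__all__ = [
    "Death",
    "StrategyResult",
    "discount_factor",
    "half_cycle_membership",
    "annuity_factor",
    "compute_yll",
    "compute_yld",
    "accrue_costs",
    "life_years",
    "trace_deaths",
    "summarize",
]

INCIDENCE_HORIZONS = (5, 10, 30)


def discount_factor(t: float, rate: float) -> float:
    """Present value at time 0 of one unit at year t: (1 + rate)^(-t)."""
    if t < 0:
        raise ValueError("time must be nonnegative")
    if rate < 0:
        raise ValueError("discount rate must be nonnegative")
    return (1.0 + rate) ** (-t)


def half_cycle_membership(trace: Trace) -> np.ndarray:
    """Effective state membership per cycle: trapezoid mean of the occupancy
    at the two cycle boundaries.  Shape (n_cycles, n_states)."""
    occ = trace.occupancy
    return 0.5 * (occ[:-1] + occ[1:])


def annuity_factor(years: float, rate: float) -> float:
    """Present value of a 1/year stream over ``years``, mid-year convention.

    Full years contribute (1+rate)^-(k+1/2); a fractional final year
    contributes pro rata at its own midpoint.
    """
    if years < 0:
        raise ValueError("years must be nonnegative")
    whole = int(math.floor(years))
    frac = years - whole
    total = sum(discount_factor(k + 0.5, rate) for k in range(whole))
    if frac > 0:
        total += frac * discount_factor(whole + frac / 2.0, rate)
    return total


@dataclass(frozen=True)
class Death:
    """A cohort fraction dying at a given model time and age."""

    time: float  # years from cycle 0
    age: float   # age at death, used for the ex lookup
    fraction: float


def trace_deaths(trace: Trace) -> list[Death]:
    """Per-cycle deaths with mid-cycle time and age-at-death convention."""
    deaths = trace.deaths_per_cycle()
    out: list[Death] = []
    for t, d in enumerate(deaths):
        if d > 0:
            out.append(Death(time=t + 0.5, age=float(trace.ages[t]) + 0.5, fraction=float(d)))
    return out


def compute_yll(
    deaths: list[Death], life_table: LifeTable, settings: AnalysisSettings, sex: Sex
) -> float:
    """Discounted years of life lost to premature mortality.

    Each death loses ex(age) years (standard residual expectancy from the
    life table); the stream is a mid-year annuity from the time of death,
    discounted back to cycle 0.
    """
    r = settings.discount_rate
    total = 0.0
    for d in deaths:
        lo, hi = life_table.age_range(sex)
        age = min(max(d.age, lo), hi)  # cap-age deaths may sit past the last row
        ex = life_table.ex(age, sex)
        total += d.fraction * discount_factor(d.time, r) * annuity_factor(ex, r)
    return total


def compute_yld(
    trace: Trace, weights: DisabilityWeightSet, settings: AnalysisSettings
) -> float:
    """Discounted years lived with disability: half-cycle-corrected prevalence
    of each state times its disability weight, per cycle."""
    membership = half_cycle_membership(trace)
    r = settings.discount_rate
    dt = settings.cycle_length
    w = np.array([weights.weights.get(s, 0.0) for s in STATE_ORDER])
    per_cycle = membership @ w * dt
    disc = np.array([discount_factor((t + 0.5) * dt, r) for t in range(membership.shape[0])])
    return float(per_cycle @ disc)


def _new_event_fractions(trace: Trace) -> np.ndarray:
    """Flow into each acute state during each cycle (first plus recurrent
    events), shape (n_cycles, n_acute)."""
    occ = trace.occupancy
    out = np.zeros((trace.n_cycles, len(ACUTE_STATES)))
    for t, m in enumerate(trace.matrices):
        for j, acute in enumerate(ACUTE_STATES):
            col = _IDX[acute]
            inflow = sum(
                occ[t, _IDX[src]] * m.probs[_IDX[src], col]
                for src in LIVING_STATES
                if src is not acute
            )
            out[t, j] = inflow
    return out


def accrue_costs(
    trace: Trace, costs: CostSet, strategy: StrategySpec, settings: AnalysisSettings
) -> float:
    """Total discounted cost: annual state costs on half-cycle-corrected
    occupancy, one-off event costs on new-event inflow, and — for strategies
    that carry it — the programme cost per alive patient-year."""
    membership = half_cycle_membership(trace)
    r, dt = settings.discount_rate, settings.cycle_length
    annual = np.array([costs.annual_state_cost.get(s, 0.0) for s in STATE_ORDER])
    per_cycle = membership @ annual * dt
    if strategy.adds_intervention_cost:
        alive = membership[:, [_IDX[s] for s in LIVING_STATES]].sum(axis=1)
        per_cycle = per_cycle + alive * costs.intervention_cost_per_cycle * dt
    event_costs = np.array([costs.event_cost.get(s, 0.0) for s in ACUTE_STATES])
    per_cycle = per_cycle + _new_event_fractions(trace) @ event_costs
    disc = np.array([discount_factor((t + 0.5) * dt, r) for t in range(membership.shape[0])])
    return float(per_cycle @ disc)


def life_years(trace: Trace, settings: AnalysisSettings, discounted: bool) -> float:
    """(Optionally discounted) half-cycle-corrected years alive."""
    membership = half_cycle_membership(trace)
    alive = membership[:, [_IDX[s] for s in LIVING_STATES]].sum(axis=1)
    dt = settings.cycle_length
    if not discounted:
        return float(alive.sum() * dt)
    disc = np.array([discount_factor((t + 0.5) * dt, settings.discount_rate)
                     for t in range(membership.shape[0])])
    return float(alive @ disc * dt)


@dataclass
class StrategyResult:
    """Lifetime outcomes of one strategy for one sex (or pooled)."""

    strategy: str
    sex: str
    cost: float
    dalys: float
    yll: float
    yld: float
    life_years_discounted: float
    years_alive: float
    cumulative_incidence: dict[str, dict[int, float]] = field(default_factory=dict)

    def scalar_fields(self) -> dict[str, float]:
        return {
            "cost": self.cost,
            "dalys": self.dalys,
            "yll": self.yll,
            "yld": self.yld,
            "life_years_discounted": self.life_years_discounted,
            "years_alive": self.years_alive,
        }


def summarize(trace: Trace, bundle: ParameterBundle, strategy: StrategySpec) -> StrategyResult:
    """Package a trace into lifetime discounted cost, DALYs (= YLL + YLD),
    years alive and cumulative incidences at 5/10/30 years."""
    settings = bundle.settings
    sex: Sex = trace.sex
    yll = compute_yll(trace_deaths(trace), bundle.life_table, settings, sex)
    yld = compute_yld(trace, bundle.disability_weights, settings)
    cost = accrue_costs(trace, bundle.costs, strategy, settings)
    incidence = {
        event.value: {
            h: cumulative_incidence(trace, event, min(h, trace.n_cycles))
            for h in INCIDENCE_HORIZONS
        }
        for event in ACUTE_STATES
    }
    return StrategyResult(
        strategy=strategy.name,
        sex=sex,
        cost=cost,
        dalys=yll + yld,
        yll=yll,
        yld=yld,
        life_years_discounted=life_years(trace, settings, discounted=True),
        years_alive=life_years(trace, settings, discounted=False),
        cumulative_incidence=incidence,
    )
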