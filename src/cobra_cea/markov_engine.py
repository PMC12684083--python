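"""Cohort state-transition dynamics: per-cycle matrices and the trace.

The cohort enters in HYPERTENSION at the profile's mean age and is propagated
one-year cycle by cycle until it reaches the age cap (lifetime horizon), at
which point any remaining occupancy is forced to DEATH so that years of life
lost can be accounted at the cap.  Within a cycle, competing exits from a
living state (first or recurrent events, background death, case fatality) are
resolved by rate-proportional allocation, never by a fixed event hierarchy.

Structural assumptions
----------------------
* Acute event states (STROKE/CHD/HF) last exactly one cycle; survivors move
  to the matching POST_* state.
* POST_* states carry elevated background mortality (relative risks) and
  recurrent-event risk (a rate multiplier on the first-event hazards);
  recurrent events re-enter the acute state of the new event.  There is no
  arrow back to the event-free HYPERTENSION state.
* DEATH is absorbing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    ACUTE_STATES,
    ACUTE_TO_POST,
    POST_STATES,
    STATE_ORDER,
    HealthState,
    ParameterBundle,
    Sex,
    StrategySpec,
)
from .risk_engine import (
    annual_event_rate,
    apply_sbp_effect,
    covariates_for,
    normalize_competing,
)

__all__ = ["TransitionMatrix", "Trace", "build_transition_matrix", "run_trace",
           "cumulative_incidence", "n_cycles"]

N_STATES = len(STATE_ORDER)
_IDX = {s: i for i, s in enumerate(STATE_ORDER)}
_DEATH = _IDX[HealthState.DEATH]

# hazard names used by calibration factors
KAPPA_BACKGROUND = "background_mortality"
KAPPA_CASE_FATALITY = "event_case_fatality"

ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class TransitionMatrix:
    """One cycle's 8x8 transition probabilities for one sex."""

    probs: np.ndarray
    cycle: int
    sex: Sex

    def __post_init__(self) -> None:
        p = self.probs
        if p.shape != (N_STATES, N_STATES):
            raise ValueError(f"transition matrix must be {N_STATES}x{N_STATES}")
        if np.any(p < -ROW_SUM_TOL) or np.any(p > 1 + ROW_SUM_TOL):
            raise ValueError("transition probabilities outside [0,1]")
        rowsums = p.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-10):
            raise ValueError(f"rows must sum to 1, got {rowsums}")
        death_row = np.zeros(N_STATES)
        death_row[_DEATH] = 1.0
        if not np.allclose(p[_DEATH], death_row, atol=ROW_SUM_TOL):
            raise ValueError("DEATH must be absorbing")

    def __getitem__(self, key: tuple[HealthState, HealthState]) -> float:
        src, dst = key
        return float(self.probs[_IDX[src], _IDX[dst]])


@dataclass
class Trace:
    """Cycle-by-state cohort occupancy for one strategy and sex.

    ``occupancy`` has ``n_cycles + 1`` rows (cycle boundaries 0..T); each row
    sums to one.  ``ages`` gives the cohort age at each boundary.
    ``matrices`` retains the per-cycle transition matrices so downstream
    accounting (event counts, incidence) can re-read the flows.
    """

    occupancy: np.ndarray
    ages: np.ndarray
    sex: Sex
    strategy: str
    matrices: list[TransitionMatrix] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        occ = self.occupancy
        if np.any(occ < -1e-12):
            raise ValueError("occupancy must be nonnegative")
        if np.any(np.abs(occ.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("each trace row must sum to 1")
        death = occ[:, _DEATH]
        if np.any(np.diff(death) < -1e-12):
            raise ValueError("DEATH occupancy must be nondecreasing")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def state_column(self, state: HealthState) -> np.ndarray:
        return self.occupancy[:, _IDX[state]]

    def alive(self) -> np.ndarray:
        return 1.0 - self.state_column(HealthState.DEATH)

    def deaths_per_cycle(self) -> np.ndarray:
        """Fraction of the cohort dying during each cycle t -> t+1."""
        return np.diff(self.state_column(HealthState.DEATH))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=[s.value for s in STATE_ORDER])
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df


def n_cycles(bundle: ParameterBundle) -> int:
    """Cycles from baseline age to the age cap (at least one)."""
    span = bundle.settings.age_cap - bundle.cohort.mean_age
    return max(int(math.ceil(span / bundle.settings.cycle_length)), 1)


def _background_death_rate(bundle: ParameterBundle, age: float, sex: Sex) -> float:
    qx = bundle.life_table.qx(age, sex)
    kappa = bundle.kappa_for(KAPPA_BACKGROUND)
    if qx >= 1.0:
        return math.inf
    return kappa * -math.log1p(-qx)


def build_transition_matrix(
    cycle: int,
    sex: Sex,
    bundle: ParameterBundle,
    strategy: StrategySpec,
) -> TransitionMatrix:
    """Transition matrix for one cycle, sex and strategy.

    Raises if the cohort's age at this cycle falls outside the life table;
    cap the horizon at the table's last age in that case.
    """
    age = bundle.cohort.mean_age + cycle * bundle.settings.cycle_length
    lo, hi = bundle.life_table.age_range(sex)
    if not lo <= age <= hi:
        raise ValueError(
            f"cohort age {age:.1f} at cycle {cycle} outside life table "
            f"[{lo}, {hi}]; cap the horizon at the table's last age"
        )
    cov = apply_sbp_effect(covariates_for(bundle, sex, age=age), strategy)
    event_rates = {
        spec.event: annual_event_rate(
            spec, cov, bundle.kappa_for(spec.event.value)
        )
        for spec in bundle.risk_equations
    }
    death_rate = _background_death_rate(bundle, age, sex)
    kappa_cf = bundle.kappa_for(KAPPA_CASE_FATALITY)

    p = np.zeros((N_STATES, N_STATES))

    # HYPERTENSION: first events + background death + stay
    exits = dict(event_rates)
    exits[HealthState.DEATH] = death_rate
    alloc = normalize_competing(exits)
    row = _IDX[HealthState.HYPERTENSION]
    for state, prob in alloc.items():
        p[row, _IDX[state]] = prob
    p[row, row] = 1.0 - sum(alloc.values())

    # Acute states: case fatality + RR-adjusted background death, remainder
    # progresses to the matching POST_* state after the one-cycle acute year.
    for acute in ACUTE_STATES:
        row = _IDX[acute]
        cf = min(kappa_cf * bundle.mortality.case_fatality[acute], 1.0)
        rr = bundle.mortality.rr.get(acute, 1.0)
        rr_death = -math.expm1(-rr * death_rate) if math.isfinite(death_rate) else 1.0
        p_death = 1.0 - (1.0 - cf) * (1.0 - rr_death)
        p[row, _DEATH] = p_death
        p[row, _IDX[ACUTE_TO_POST[acute]]] = 1.0 - p_death

    # POST_* states: recurrent events (scaled first-event hazards) +
    # RR-adjusted background death + stay.
    for post in POST_STATES:
        row = _IDX[post]
        mult = bundle.recurrence_multiplier.get(post, 1.0)
        rr = bundle.mortality.rr.get(post, 1.0)
        exits = {ev: mult * r for ev, r in event_rates.items()}
        exits[HealthState.DEATH] = rr * death_rate
        alloc = normalize_competing(exits)
        for state, prob in alloc.items():
            p[row, _IDX[state]] = prob
        p[row, row] = 1.0 - sum(alloc.values())

    p[_DEATH, _DEATH] = 1.0
    return TransitionMatrix(probs=p, cycle=cycle, sex=sex)


def run_trace(bundle: ParameterBundle, strategy: StrategySpec, sex: Sex) -> Trace:
    """Propagate the cohort from HYPERTENSION at baseline age to the age cap.

    Row t+1 = row t x matrix(t); after the final cycle any remaining living
    occupancy is forced to DEATH (lifetime horizon closure).
    """
    T = n_cycles(bundle)
    occ = np.zeros((T + 1, N_STATES))
    occ[0, _IDX[HealthState.HYPERTENSION]] = 1.0
    matrices: list[TransitionMatrix] = []
    for t in range(T - 1):
        m = build_transition_matrix(t, sex, bundle, strategy)
        matrices.append(m)
        occ[t + 1] = occ[t] @ m.probs
    # final cycle: everyone still alive dies at the age cap
    final = np.zeros((N_STATES, N_STATES))
    final[:, _DEATH] = 1.0
    matrices.append(TransitionMatrix(probs=final, cycle=T - 1, sex=sex))
    occ[T] = occ[T - 1] @ final
    ages = bundle.cohort.mean_age + np.arange(T + 1) * bundle.settings.cycle_length
    return Trace(occupancy=occ, ages=ages, sex=sex, strategy=strategy.name, matrices=matrices)


def cumulative_incidence(trace: Trace, event: HealthState, years: float) -> float:
    """Cumulative incidence of first events of one type within ``years``.

    Counts flow out of the event-free HYPERTENSION state into the acute
    event state, so recurrent events are excluded.
    """
    if event not in ACUTE_STATES:
        raise ValueError(f"{event} is not an acute event state")
    if years > trace.n_cycles:
        raise ValueError(f"horizon {years} exceeds trace length {trace.n_cycles}")
    hyp = _IDX[HealthState.HYPERTENSION]
    total = 0.0
    for t in range(int(years)):
        m = trace.matrices[t]
        total += trace.occupancy[t, hyp] * m.probs[hyp, _IDX[event]]
    return total
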