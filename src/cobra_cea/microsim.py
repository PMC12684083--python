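"""Individual-level microsimulation used to validate the cohort trace.

Samples N patients through the same per-cycle transition matrices and counts
state occupancy.  Because every patient in a state shares that state's
transition row, the empirical occupancy is an unbiased Monte-Carlo estimate
of the cohort trace; agreement within a few Monte-Carlo standard errors per
cell validates the matrix-propagation arithmetic independently of it.
"""

from __future__ import annotations

import numpy as np

from .markov_engine import N_STATES, Trace, _IDX, build_transition_matrix, n_cycles
from .parameters import HealthState, ParameterBundle, Sex, StrategySpec

__all__ = ["microsimulate", "mc_standard_error"]


def microsimulate(
    bundle: ParameterBundle,
    strategy: StrategySpec,
    sex: Sex,
    n_patients: int,
    seed: int = 0,
) -> np.ndarray:
    """Empirical occupancy fractions, shape (n_cycles + 1, n_states).

    All patients start in HYPERTENSION; each cycle, patients in state s move
    according to a categorical draw from that cycle's transition row.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    rng = np.random.default_rng(seed)
    T = n_cycles(bundle)
    state = np.full(n_patients, _IDX[HealthState.HYPERTENSION], dtype=np.int64)
    occ = np.zeros((T + 1, N_STATES))
    occ[0] = np.bincount(state, minlength=N_STATES) / n_patients
    for t in range(T - 1):
        m = build_transition_matrix(t, sex, bundle, strategy)
        cum = np.cumsum(m.probs, axis=1)
        u = rng.random(n_patients)
        # inverse-CDF draw per patient from its own state's row
        rows = cum[state]
        state = (u[:, None] > rows).sum(axis=1)
        occ[t + 1] = np.bincount(state, minlength=N_STATES) / n_patients
    # lifetime-horizon closure: survivors die at the age cap
    state = np.full(n_patients, _IDX[HealthState.DEATH], dtype=np.int64)
    occ[T] = np.bincount(state, minlength=N_STATES) / n_patients
    return occ


def mc_standard_error(expected: np.ndarray, n_patients: int) -> np.ndarray:
    """Binomial Monte-Carlo standard error per occupancy cell."""
    p = np.clip(expected, 0.0, 1.0)
    return np.sqrt(p * (1.0 - p) / n_patients)
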