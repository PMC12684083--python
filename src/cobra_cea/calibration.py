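"""Mortality calibration: scale baseline hazards to observed targets.

The model's absolute mortality is aligned to trial-observed cumulative
all-cause mortality by multiplying selected baseline hazards by factors
kappa and minimising the least-squares distance between model-predicted and
observed cumulative mortality at the target time points.  Covariate
coefficients and relative effects are never re-estimated.

By default two factors are free: one on background mortality and one shared
across the acute events' case fatality.  With targets on all-cause mortality
alone these two are only weakly jointly identified; parameter-recovery
studies should free a single factor.  Calibration is run on the comparator
(standard-of-care) strategy, since trial-consistent mortality is a
control-arm property.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .markov_engine import KAPPA_BACKGROUND, KAPPA_CASE_FATALITY, run_trace
from .parameters import HealthState, ParameterBundle, Sex, StrategySpec

__all__ = ["CalibrationTarget", "CalibrationResult", "mortality_objective", "calibrate",
           "DEFAULT_FREE_KAPPAS"]

DEFAULT_FREE_KAPPAS = (KAPPA_BACKGROUND, KAPPA_CASE_FATALITY)

GRID_LO, GRID_HI, GRID_POINTS = 0.25, 4.0, 7
OBJECTIVE_TOL = 1e-8
MAX_ITER = 500


@dataclass(frozen=True)
class CalibrationTarget:
    """Observed cumulative all-cause mortality at one follow-up time."""

    time_years: float
    cum_mortality: float
    sex: Sex | str = "pooled"

    def __post_init__(self) -> None:
        if not 0 <= self.cum_mortality <= 1:
            raise ValueError("cumulative mortality must lie in [0,1]")
        if self.time_years < 0:
            raise ValueError("target time must be nonnegative")


@dataclass
class CalibrationResult:
    kappa: dict[str, float]
    objective: float
    converged: bool
    iterations: int
    history: list[float] = field(default_factory=list, repr=False)


def _with_kappa(bundle: ParameterBundle, kappa: dict[str, float]) -> ParameterBundle:
    out = bundle.model_copy(deep=True)
    out.kappa = {**bundle.kappa, **kappa}
    return out


def predicted_mortality(
    bundle: ParameterBundle, strategy: StrategySpec, time_years: float, sex: Sex | str
) -> float:
    """Model-predicted cumulative all-cause mortality at ``time_years``
    (DEATH occupancy, linearly interpolated between cycle boundaries;
    pooled over sexes at the cohort's sex mix when sex == 'pooled')."""
    if sex == "pooled":
        w = bundle.cohort.prop_female
        return (1 - w) * predicted_mortality(bundle, strategy, time_years, "male") + \
            w * predicted_mortality(bundle, strategy, time_years, "female")
    trace = run_trace(bundle, strategy, sex)
    death = trace.state_column(HealthState.DEATH)
    t = np.clip(time_years / bundle.settings.cycle_length, 0, trace.n_cycles)
    return float(np.interp(t, np.arange(len(death)), death))


def mortality_objective(
    kappa: dict[str, float],
    bundle: ParameterBundle,
    strategy: StrategySpec,
    targets: list[CalibrationTarget],
) -> float:
    """Sum of squared deviations between model-predicted and observed
    cumulative all-cause mortality under the given hazard scalings."""
    for name, k in kappa.items():
        if k <= 0:
            raise ValueError(f"kappa[{name}] must be positive, got {k}")
    if not targets:
        return 0.0
    scaled = _with_kappa(bundle, kappa)
    total = 0.0
    # group targets by sex so each trace is run once
    for sex in {t.sex for t in targets}:
        times = [t for t in targets if t.sex == sex]
        for target in times:
            pred = predicted_mortality(scaled, strategy, target.time_years, sex)
            total += (pred - target.cum_mortality) ** 2
    return total


def calibrate(
    bundle: ParameterBundle,
    strategy: StrategySpec,
    targets: list[CalibrationTarget],
    free: tuple[str, ...] = DEFAULT_FREE_KAPPAS,
) -> CalibrationResult:
    """Find hazard scalings minimising the mortality objective.

    A coarse log-spaced grid scan over [0.25, 4] per factor seeds a
    Nelder-Mead simplex search in log space (positivity by construction).
    Non-convergence within the iteration cap returns the best-found factors
    with ``converged=False`` rather than raising.
    """
    if not targets:
        raise ValueError("calibration requires at least one target")
    if not free:
        raise ValueError("calibration requires at least one free factor")
    history: list[float] = []

    def obj_log(log_k: np.ndarray) -> float:
        kappa = {name: float(np.exp(v)) for name, v in zip(free, log_k)}
        val = mortality_objective(kappa, bundle, strategy, targets)
        history.append(val)
        return val

    # coarse grid pre-scan (full factorial over the free factors)
    grid = np.log(np.geomspace(GRID_LO, GRID_HI, GRID_POINTS))
    best_x = np.zeros(len(free))  # kappa = 1 seed
    best_val = obj_log(best_x)
    mesh = np.meshgrid(*([grid] * len(free)), indexing="ij")
    for idx in np.ndindex(*mesh[0].shape):
        x = np.array([m[idx] for m in mesh])
        val = obj_log(x)
        if val < best_val:
            best_val, best_x = val, x

    res = optimize.minimize(
        obj_log,
        best_x,
        method="Nelder-Mead",
        options={"fatol": OBJECTIVE_TOL, "xatol": 1e-6, "maxiter": MAX_ITER},
    )
    x, val = (res.x, float(res.fun)) if res.fun <= best_val else (best_x, best_val)
    return CalibrationResult(
        kappa={name: float(np.exp(v)) for name, v in zip(free, x)},
        objective=val,
        converged=bool(res.success) and val <= best_val,
        iterations=int(res.nit),
        history=history,
    )


def apply_calibration(bundle: ParameterBundle, result: CalibrationResult) -> ParameterBundle:
    """Return a copy of the bundle with the calibrated factors written into
    its kappa block (a calibrated bundle is self-contained)."""
    return _with_kappa(bundle, result.kappa)
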