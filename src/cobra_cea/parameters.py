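"""Parameter bundle: the complete, validated input set of the decision model.

Everything the model consumes — cohort profile, risk-equation coefficient
sets, a life table, disability weights, costs, post-event mortality relative
risks, strategy definitions, analysis settings and PSA distribution
specifications — travels in a single :class:`ParameterBundle`, serialized as
one JSON document with a schema version.  A bundle is therefore a complete,
reproducible description of one analysis.

Unknown fields are rejected rather than ignored: a silently misspelled
parameter name is the classic failure mode of decision models, so every model
here uses ``extra="forbid"``.
"""

from __future__ import annotations

import enum
import json
import math
from pathlib import Path
from typing import ClassVar, Literal

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

SCHEMA_VERSION = 1

__all__ = [
    "HealthState",
    "ACUTE_STATES",
    "POST_STATES",
    "LIVING_STATES",
    "ACUTE_TO_POST",
    "Sex",
    "CohortProfile",
    "RiskEquationSpec",
    "LifeTableRow",
    "LifeTable",
    "DisabilityWeightSet",
    "CostSet",
    "MortalityRRSet",
    "StrategySpec",
    "AnalysisSettings",
    "PSADistribution",
    "PSASettings",
    "ParameterBundle",
    "BundleValidationError",
    "load_bundle",
    "save_bundle",
    "load_life_table_csv",
]


class BundleValidationError(ValueError):
    """A bundle violated a model invariant (beyond plain schema shape)."""


class HealthState(str, enum.Enum):
    """The eight health states of the cohort model.

    The cohort enters in HYPERTENSION and may suffer a first acute
    cardiovascular event (STROKE, CHD — carried as myocardial infarction in
    reports — or HF).  Acute states last one cycle, then survivors move to the
    matching chronic POST_* state, which carries elevated mortality and
    recurrent-event risk.  DEATH is absorbing.
    """

    HYPERTENSION = "HYPERTENSION"
    STROKE = "STROKE"
    POST_STROKE = "POST_STROKE"
    CHD = "CHD"
    POST_CHD = "POST_CHD"
    HF = "HF"
    POST_HF = "POST_HF"
    DEATH = "DEATH"

    @property
    def index(self) -> int:
        return STATE_ORDER.index(self)


STATE_ORDER: tuple[HealthState, ...] = (
    HealthState.HYPERTENSION,
    HealthState.STROKE,
    HealthState.POST_STROKE,
    HealthState.CHD,
    HealthState.POST_CHD,
    HealthState.HF,
    HealthState.POST_HF,
    HealthState.DEATH,
)
ACUTE_STATES: tuple[HealthState, ...] = (
    HealthState.STROKE,
    HealthState.CHD,
    HealthState.HF,
)
POST_STATES: tuple[HealthState, ...] = (
    HealthState.POST_STROKE,
    HealthState.POST_CHD,
    HealthState.POST_HF,
)
LIVING_STATES: tuple[HealthState, ...] = tuple(
    s for s in STATE_ORDER if s is not HealthState.DEATH
)
ACUTE_TO_POST: dict[HealthState, HealthState] = {
    HealthState.STROKE: HealthState.POST_STROKE,
    HealthState.CHD: HealthState.POST_CHD,
    HealthState.HF: HealthState.POST_HF,
}

Sex = Literal["male", "female"]
SEXES: tuple[Sex, ...] = ("male", "female")


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class CohortProfile(_Model):
    """Baseline characteristics of the modelled hypertensive cohort.

    Risk is evaluated at these (sex-stratified) mean covariates; baseline
    characteristics are held fixed across PSA iterations so the PSA reflects
    parameter uncertainty, not cohort variability.
    """

    mean_age: float = Field(ge=18, le=100, description="years")
    sd_age: float = Field(ge=0)
    prop_female: float = Field(ge=0, le=1)
    prop_diabetes: float = Field(ge=0, le=1)
    prop_ckd: float = Field(ge=0, le=1)
    prop_smoker: float = Field(ge=0, le=1)
    mean_sbp: float = Field(gt=0, description="mm Hg")
    mean_total_chol: float = Field(gt=0, description="mg/dL")
    mean_hdl: float = Field(gt=0, description="mg/dL")


class RiskEquationSpec(_Model):
    """One Framingham-style event-risk equation.

    ``coefficients`` maps covariate names (age, male, sbp, diabetes, smoker,
    ckd, total_chol, hdl) to weights on the linear predictor;
    ``baseline_term`` is the intercept (logistic) or log baseline scale
    (Weibull survival), the quantity that calibration rescales; the published
    risk spans ``horizon_years`` and is bridged to the annual cycle by the
    risk engine.
    """

    event: HealthState
    coefficients: dict[str, float]
    baseline_term: float
    horizon_years: int = Field(ge=1)
    functional_form: Literal["logistic", "weibull_survival"] = "logistic"
    weibull_shape: float = Field(default=1.0, gt=0)

    ALLOWED_COVARIATES: ClassVar[frozenset[str]] = frozenset(
        {"age", "male", "female", "sbp", "diabetes", "smoker", "ckd",
         "total_chol", "hdl"}
    )

    @model_validator(mode="after")
    def _check(self) -> "RiskEquationSpec":
        if self.event not in ACUTE_STATES:
            raise ValueError(f"event must be an acute state, got {self.event}")
        unknown = set(self.coefficients) - self.ALLOWED_COVARIATES
        if unknown:
            raise ValueError(f"unknown covariates in coefficients: {sorted(unknown)}")
        return self


class LifeTableRow(_Model):
    age: int = Field(ge=0)
    sex: Sex
    qx: float = Field(ge=0, le=1, description="annual death probability")
    ex: float = Field(gt=0, description="residual life expectancy, years")


class LifeTable(_Model):
    """Age- and sex-specific all-cause mortality (qx) and residual life
    expectancy (ex), one row per (age, sex)."""

    rows: list[LifeTableRow]

    @model_validator(mode="after")
    def _check(self) -> "LifeTable":
        for sex in SEXES:
            ages = [r.age for r in self.rows if r.sex == sex]
            if not ages:
                raise ValueError(f"life table has no rows for sex={sex}")
            if sorted(ages) != list(range(min(ages), max(ages) + 1)):
                raise ValueError(f"life table ages not contiguous for sex={sex}")
        self._check_ex_consistency()
        return self

    def _check_ex_consistency(self, tol: float = 0.5) -> None:
        # Standard life-table arithmetic: ex(a) = sum of survival probabilities
        # from a, with a half-year for the year of death.
        for sex in SEXES:
            rows = sorted((r for r in self.rows if r.sex == sex), key=lambda r: r.age)
            n = len(rows)
            for i, row in enumerate(rows):
                alive = 1.0
                years = 0.0
                for j in range(i, n):
                    dead = alive * rows[j].qx
                    years += alive - 0.5 * dead
                    alive -= dead
                # beyond-table survivors: credit ex at the open end is unknown;
                # the default fixture closes the table with qx=1
                if abs(years - row.ex) > tol + alive * 50:
                    raise ValueError(
                        f"ex inconsistent with qx at age {row.age} ({sex}): "
                        f"stated {row.ex:.2f}, recomputed {years:.2f}"
                    )

    # -- lookups -----------------------------------------------------------
    def _series(self, sex: Sex, attr: str) -> tuple[list[int], list[float]]:
        rows = sorted((r for r in self.rows if r.sex == sex), key=lambda r: r.age)
        return [r.age for r in rows], [getattr(r, attr) for r in rows]

    def age_range(self, sex: Sex) -> tuple[int, int]:
        ages, _ = self._series(sex, "qx")
        return ages[0], ages[-1]

    def _interp(self, sex: Sex, attr: str, age: float) -> float:
        ages, vals = self._series(sex, attr)
        if age < ages[0] or age > ages[-1]:
            raise BundleValidationError(
                f"age {age} outside life table range [{ages[0]}, {ages[-1]}] for {sex}"
            )
        lo = int(math.floor(age))
        if lo == ages[-1]:
            return vals[-1]
        frac = age - lo
        i = ages.index(lo)
        return vals[i] * (1 - frac) + vals[i + 1] * frac

    def qx(self, age: float, sex: Sex) -> float:
        return self._interp(sex, "qx", age)

    def ex(self, age: float, sex: Sex) -> float:
        return self._interp(sex, "ex", age)


class DisabilityWeightSet(_Model):
    """GBD-style disability weights per living state, 0 = full health."""

    weights: dict[HealthState, float]

    @model_validator(mode="after")
    def _check(self) -> "DisabilityWeightSet":
        if HealthState.DEATH in self.weights:
            raise ValueError("DEATH carries no disability weight")
        for state, w in self.weights.items():
            if not 0 <= w <= 1:
                raise ValueError(f"disability weight for {state.value} outside [0,1]: {w}")
        missing = set(LIVING_STATES) - set(self.weights)
        if missing:
            raise ValueError(f"missing disability weights: {sorted(s.value for s in missing)}")
        return self

    def __getitem__(self, state: HealthState) -> float:
        return self.weights[state]


class CostSet(_Model):
    """Annual per-state costs, one-off acute event costs and the programme
    cost, all in constant US$ of ``currency_year``."""

    annual_state_cost: dict[HealthState, float]
    event_cost: dict[HealthState, float]
    intervention_cost_per_cycle: float = Field(ge=0)
    currency_year: int = 2023

    @model_validator(mode="after")
    def _check(self) -> "CostSet":
        for name, mapping in (("annual_state_cost", self.annual_state_cost),
                              ("event_cost", self.event_cost)):
            for state, c in mapping.items():
                if c < 0:
                    raise ValueError(f"{name}[{state.value}] negative: {c}")
        if self.annual_state_cost.get(HealthState.DEATH, 0.0) != 0.0:
            raise ValueError("DEATH must carry zero annual cost")
        unknown = set(self.event_cost) - set(ACUTE_STATES)
        if unknown:
            raise ValueError(
                f"event costs only apply to acute states, got {sorted(s.value for s in unknown)}"
            )
        return self


class MortalityRRSet(_Model):
    """Excess mortality after cardiovascular events.

    ``rr`` multiplies background qx in chronic (and acute) event states;
    ``case_fatality`` is the extra first-cycle death probability of an acute
    event.
    """

    rr: dict[HealthState, float]
    case_fatality: dict[HealthState, float]

    @model_validator(mode="after")
    def _check(self) -> "MortalityRRSet":
        for state, v in self.rr.items():
            if v < 1:
                raise ValueError(f"relative risk for {state.value} must be >= 1, got {v}")
        for state, v in self.case_fatality.items():
            if state not in ACUTE_STATES:
                raise ValueError(f"case fatality only applies to acute states, got {state.value}")
            if not 0 <= v <= 1:
                raise ValueError(f"case fatality for {state.value} outside [0,1]: {v}")
        missing = set(ACUTE_STATES) - set(self.case_fatality)
        if missing:
            raise ValueError(f"missing case fatality for {sorted(s.value for s in missing)}")
        return self


class StrategySpec(_Model):
    """A treatment strategy: its blood-pressure effect and whether it adds the
    per-participant programme cost."""

    name: str
    sbp_delta: float = 0.0
    adds_intervention_cost: bool = False


class AnalysisSettings(_Model):
    cycle_length: float = Field(default=1.0, gt=0, description="years")
    age_cap: float = Field(default=100.0, description="run until cohort reaches this age")
    discount_rate: float = Field(default=0.03, ge=0)
    thresholds: list[float] = Field(default_factory=lambda: [183.0, 500.0, 1000.0])
    half_cycle_correction: bool = True

    @model_validator(mode="after")
    def _check(self) -> "AnalysisSettings":
        if any(t < 0 for t in self.thresholds):
            raise ValueError("thresholds must be nonnegative")
        return self


class PSADistribution(_Model):
    family: Literal["beta", "gamma", "normal", "lognormal", "dirichlet"]
    params: dict[str, float] | None = None
    # dirichlet concentration vector for list-valued paths
    alpha: list[float] | None = None

    @model_validator(mode="after")
    def _check(self) -> "PSADistribution":
        required = {
            "beta": {"alpha", "beta"},
            "gamma": {"shape", "scale"},
            "normal": {"mu", "sigma"},
            "lognormal": {"mu", "sigma"},
        }
        if self.family == "dirichlet":
            if not self.alpha or any(a <= 0 for a in self.alpha):
                raise ValueError("dirichlet needs a positive concentration vector")
        else:
            got = set(self.params or {})
            if got != required[self.family]:
                raise ValueError(
                    f"{self.family} needs params {sorted(required[self.family])}, got {sorted(got)}"
                )
        return self


class PSASettings(_Model):
    n_iterations: int = Field(default=10_000, ge=1)
    seed: int = 20216
    distributions: dict[str, PSADistribution] = Field(default_factory=dict)


class ParameterBundle(_Model):
    """The complete input set of one analysis (the model's single source of
    truth; serialized as one JSON document)."""

    schema_version: int = SCHEMA_VERSION
    cohort: CohortProfile
    risk_equations: list[RiskEquationSpec]
    life_table: LifeTable
    disability_weights: DisabilityWeightSet
    costs: CostSet
    mortality: MortalityRRSet
    strategies: list[StrategySpec]
    settings: AnalysisSettings = Field(default_factory=AnalysisSettings)
    psa: PSASettings = Field(default_factory=PSASettings)
    # calibration scaling factors on baseline hazards (default: uncalibrated)
    kappa: dict[str, float] = Field(default_factory=dict)
    # rate multiplier on recurrent events from each POST_* state
    recurrence_multiplier: dict[HealthState, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "ParameterBundle":
        events = [spec.event for spec in self.risk_equations]
        if sorted(e.value for e in events) != sorted(s.value for s in ACUTE_STATES):
            raise ValueError("need exactly one risk equation per acute event")
        if len({s.name for s in self.strategies}) != len(self.strategies):
            raise ValueError("strategy names must be unique")
        for name, k in self.kappa.items():
            if k <= 0:
                raise ValueError(f"calibration factor kappa[{name}] must be positive, got {k}")
        for state, m in self.recurrence_multiplier.items():
            if state not in POST_STATES:
                raise ValueError(f"recurrence multiplier only applies to POST_* states, got {state.value}")
            if m < 0:
                raise ValueError("recurrence multiplier must be nonnegative")
        for path in self.psa.distributions:
            try:
                resolve_path(self, path)
            except Exception as err:  # noqa: BLE001 - rewrap with the offending path
                raise ValueError(f"PSA distribution path does not resolve: {path!r} ({err})")
        return self

    # convenience accessors -------------------------------------------------
    def strategy(self, name: str) -> StrategySpec:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"no strategy named {name!r}")

    def risk_equation(self, event: HealthState) -> RiskEquationSpec:
        for spec in self.risk_equations:
            if spec.event == event:
                return spec
        raise KeyError(f"no risk equation for {event}")

    def kappa_for(self, name: str) -> float:
        return self.kappa.get(name, 1.0)


# ---------------------------------------------------------------------------
# Dotted-path access, used by the PSA to address individual parameters.
# Grammar: segments separated by '.', where a segment indexes either an
# attribute, a dict key (HealthState names allowed), or a named list element
# (strategies and risk equations are addressed by name/event).
# ---------------------------------------------------------------------------

def _step(obj, segment: str):
    if isinstance(obj, dict):
        if segment in obj:
            return segment
        try:
            key = HealthState(segment)
        except ValueError:
            raise KeyError(f"no key {segment!r}")
        if key in obj:
            return key
        raise KeyError(f"no key {segment!r}")
    if isinstance(obj, list):
        for i, item in enumerate(obj):
            tag = getattr(item, "name", None) or getattr(getattr(item, "event", None), "value", None)
            if tag == segment:
                return i
        raise KeyError(f"no list element tagged {segment!r}")
    if isinstance(obj, BaseModel) and segment in type(obj).model_fields:
        return segment
    raise KeyError(f"cannot resolve segment {segment!r} on {type(obj).__name__}")


def resolve_path(bundle: ParameterBundle, path: str):
    """Return the value at a dotted parameter path, e.g.
    ``costs.event_cost.STROKE`` or ``strategies.COBRA.sbp_delta``."""
    obj = bundle
    for segment in path.split("."):
        key = _step(obj, segment)
        obj = obj[key] if isinstance(obj, (dict, list)) else getattr(obj, key)
    return obj


def set_path(bundle: ParameterBundle, path: str, value) -> None:
    """Assign ``value`` at a dotted parameter path (in place)."""
    obj = bundle
    segments = path.split(".")
    for segment in segments[:-1]:
        key = _step(obj, segment)
        obj = obj[key] if isinstance(obj, (dict, list)) else getattr(obj, key)
    key = _step(obj, segments[-1])
    if isinstance(obj, (dict, list)):
        obj[key] = value
    else:
        setattr(obj, key, value)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_bundle(bundle: ParameterBundle, path: str | Path) -> None:
    """Write a bundle as canonical (sorted-key, indented) JSON.

    Serialization is deterministic: two saves of the same bundle are
    byte-identical.
    """
    payload = bundle.model_dump(mode="json")
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_bundle(path: str | Path) -> ParameterBundle:
    """Read and fully validate a bundle file.

    Raises :class:`BundleValidationError` with the offending path/rule on any
    schema or invariant violation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"bundle file not found: {path}")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise BundleValidationError(f"bundle file is not valid JSON: {err}") from err
    try:
        bundle = ParameterBundle.model_validate(payload)
    except ValidationError as err:
        raise BundleValidationError(str(err)) from err
    if bundle.schema_version != SCHEMA_VERSION:
        raise BundleValidationError(
            f"unsupported schema_version {bundle.schema_version}, expected {SCHEMA_VERSION}"
        )
    return bundle


def load_life_table_csv(path: str | Path) -> LifeTable:
    """Import a life table from CSV with columns age, sex, qx, ex."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"age", "sex", "qx", "ex"}
    missing = required - set(df.columns)
    if missing:
        raise BundleValidationError(f"life table CSV missing columns: {sorted(missing)}")
    rows = [
        LifeTableRow(age=int(r.age), sex=str(r.sex), qx=float(r.qx), ex=float(r.ex))
        for r in df.itertuples()
    ]
    try:
        return LifeTable(rows=rows)
    except ValidationError as err:
        raise BundleValidationError(str(err)) from err
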