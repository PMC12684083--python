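"""Incremental cost-effectiveness statistics.

Conventions: incremental cost ΔC = cost(alternative) − cost(reference);
DALYs averted ΔE = DALYs(reference) − DALYs(alternative), so a positive ΔE
is a health gain.  ICER = ΔC/ΔE when both are positive; dominance labels
replace the ratio when the signs differ.  Net monetary benefit at a
willingness-to-pay λ per DALY averted is λ·ΔE − ΔC, positive iff the
alternative is cost-effective at λ (equivalently ICER < λ when ΔE > 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .outcomes import StrategyResult

__all__ = ["IncrementalResult", "incremental", "net_monetary_benefit", "pool_sexes",
           "DOMINANT", "DOMINATED"]

DOMINANT = "dominant"      # cheaper and more effective
DOMINATED = "dominated"    # costlier and less effective


@dataclass
class IncrementalResult:
    """Alternative-vs-reference comparison at one pooling level."""

    reference: str
    alternative: str
    sex: str
    delta_cost: float
    dalys_averted: float
    delta_years_alive: float
    icer: float | None          # US$/DALY averted; None when undefined
    dominance: str | None       # DOMINANT / DOMINATED / None
    nmb: dict[float, float] = field(default_factory=dict)


def net_monetary_benefit(threshold, dalys_averted, delta_cost):
    """λ·ΔE − ΔC at willingness-to-pay ``threshold`` per DALY averted.

    Accepts scalars or numpy arrays (broadcast elementwise).
    """
    if np.any(np.asarray(threshold) < 0):
        raise ValueError("threshold must be nonnegative")
    return threshold * dalys_averted - delta_cost


def incremental(
    ref: StrategyResult,
    alt: StrategyResult,
    thresholds: list[float] | None = None,
) -> IncrementalResult:
    """Incremental comparison of ``alt`` against ``ref`` (same sex/pooling)."""
    if ref.sex != alt.sex:
        raise ValueError(f"cannot compare results at different pooling levels: {ref.sex} vs {alt.sex}")
    delta_cost = alt.cost - ref.cost
    averted = ref.dalys - alt.dalys
    delta_years = alt.years_alive - ref.years_alive
    icer: float | None = None
    dominance: str | None = None
    if averted > 0 and delta_cost > 0:
        icer = delta_cost / averted
    elif averted > 0 and delta_cost <= 0:
        dominance = DOMINANT
    elif averted < 0 and delta_cost >= 0:
        dominance = DOMINATED
    elif averted < 0 and delta_cost < 0:
        # saves money but loses health: the ratio is reported southwest-style
        icer = delta_cost / averted
    nmb = {
        lam: net_monetary_benefit(lam, averted, delta_cost)
        for lam in (thresholds or [])
    }
    return IncrementalResult(
        reference=ref.strategy,
        alternative=alt.strategy,
        sex=ref.sex,
        delta_cost=delta_cost,
        dalys_averted=averted,
        delta_years_alive=delta_years,
        icer=icer,
        dominance=dominance,
        nmb=nmb,
    )


def pool_sexes(male: StrategyResult, female: StrategyResult, w_female: float) -> StrategyResult:
    """Weighted mean of the sex-specific results (default weight: the trial's
    sex mix).  Every scalar outcome and every cumulative incidence pools as a
    w_female-weighted average, so pooling is affine: pooling then differencing
    equals differencing then pooling."""
    if not 0 <= w_female <= 1:
        raise ValueError("w_female must lie in [0,1]")
    if male.strategy != female.strategy:
        raise ValueError("pooling requires results of the same strategy")
    w_m = 1.0 - w_female

    def mix(a: float, b: float) -> float:
        return w_m * a + w_female * b

    incidence = {
        event: {
            h: mix(male.cumulative_incidence[event][h], female.cumulative_incidence[event][h])
            for h in male.cumulative_incidence[event]
        }
        for event in male.cumulative_incidence
    }
    return StrategyResult(
        strategy=male.strategy,
        sex="pooled",
        cost=mix(male.cost, female.cost),
        dalys=mix(male.dalys, female.dalys),
        yll=mix(male.yll, female.yll),
        yld=mix(male.yld, female.yld),
        life_years_discounted=mix(male.life_years_discounted, female.life_years_discounted),
        years_alive=mix(male.years_alive, female.years_alive),
        cumulative_incidence=incidence,
    )
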