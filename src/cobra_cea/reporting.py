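"""Tabular report layouts mirroring the published result tables.

All outputs are CSV with a fixed, documented column order; CHD states are
relabelled "Myocardial infarction" in reports, matching how the published
tables name the event the CHD state carries.
"""

from __future__ import annotations

import pandas as pd

from .outcomes import INCIDENCE_HORIZONS
from .parameters import ACUTE_STATES, HealthState
from .pipeline import BaseCaseResult

__all__ = ["incidence_table", "cea_table", "state_cost_table", "REPORT_LABELS"]

REPORT_LABELS = {
    HealthState.STROKE: "Stroke",
    HealthState.CHD: "Myocardial infarction",
    HealthState.HF: "Heart failure",
}


def incidence_table(result: BaseCaseResult) -> pd.DataFrame:
    """Cumulative incidence of first events by 5/10/30 years, per sex and
    strategy (long format: sex, horizon_years, event, strategy, incidence)."""
    rows = []
    for sex in ("male", "female"):
        for horizon in INCIDENCE_HORIZONS:
            for event in ACUTE_STATES:
                for name, per_level in result.strategies.items():
                    rows.append({
                        "sex": sex,
                        "horizon_years": horizon,
                        "event": REPORT_LABELS[event],
                        "strategy": name,
                        "incidence": per_level[sex].cumulative_incidence[event.value][horizon],
                    })
    return pd.DataFrame(rows)


def cea_table(result: BaseCaseResult) -> pd.DataFrame:
    """Cost-effectiveness table in the published column order: strategy rows
    per sex and pooled, with incremental columns on the alternative row only
    (reference rows carry NA, as printed)."""
    rows = []
    for level in ("male", "female", "pooled"):
        inc = result.incrementals[level]
        for name in (result.reference, result.alternative):
            r = result.strategies[name][level]
            is_alt = name == result.alternative
            rows.append({
                "sex": level,
                "strategy": name,
                "cost_usd": r.cost,
                "dalys": r.dalys,
                "incremental_cost_usd": inc.delta_cost if is_alt else None,
                "incremental_dalys": inc.dalys_averted if is_alt else None,
                "icer_usd_per_daly": (inc.icer if is_alt else None),
                "dominance": (inc.dominance if is_alt else None),
                "years_alive": r.years_alive,
            })
    return pd.DataFrame(rows)


def state_cost_table(result: BaseCaseResult) -> pd.DataFrame:
    """Undiscounted lifetime share of cost is not separable from the trace
    here; this table reports the discounted totals per strategy and sex."""
    rows = []
    for name, per_level in result.strategies.items():
        for level in ("male", "female"):
            r = per_level[level]
            rows.append({
                "sex": level,
                "strategy": name,
                "total_cost_usd": r.cost,
                "years_alive": r.years_alive,
                "dalys": r.dalys,
            })
    return pd.DataFrame(rows)
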