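"""Discounting, half-cycle correction, YLL/YLD, cost accrual, summary."""

from __future__ import annotations

import numpy as np
import pytest

from cobra_cea.markov_engine import run_trace
from cobra_cea.outcomes import (
    Death,
    accrue_costs,
    annuity_factor,
    compute_yld,
    compute_yll,
    discount_factor,
    half_cycle_membership,
    life_years,
    summarize,
    trace_deaths,
)
from cobra_cea.parameters import (
    AnalysisSettings,
    CostSet,
    DisabilityWeightSet,
    HealthState,
    StrategySpec,
)

from conftest import constant_qx_life_table, make_toy_bundle, manual_trace


class TestDiscounting:
    def test_present_value_is_one(self):
        assert discount_factor(0.0, 0.03) == 1.0

    def test_zero_rate_no_discounting(self):
        assert discount_factor(17.0, 0.0) == 1.0

    def test_one_year_at_three_percent(self):
        assert discount_factor(1.0, 0.03) == pytest.approx(1 / 1.03)
        assert discount_factor(1.0, 0.03) == pytest.approx(0.970874, abs=1e-6)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1.0, 0.03)
        with pytest.raises(ValueError):
            discount_factor(1.0, -0.01)


class TestHalfCycle:
    def test_constant_occupancy_unchanged(self):
        trace = manual_trace([1.0, 1.0, 1.0])
        m = half_cycle_membership(trace)
        assert np.allclose(m.sum(axis=1), 1.0)
        assert np.all(m[:, 0] == 1.0)

    def test_step_drop_gives_midpoint(self):
        trace = manual_trace([1.0, 0.0])
        m = half_cycle_membership(trace)
        alive = m[0, :7].sum()
        assert alive == pytest.approx(0.5)

    def test_trapezoid_life_years_geometric_toy(self):
        """q = 0.1 over 3 cycles: (1+.9)/2 + (.9+.81)/2 + (.81+.729)/2 = 2.5745."""
        trace = manual_trace([1.0, 0.9, 0.81, 0.729])
        settings = AnalysisSettings(discount_rate=0.0)
        assert life_years(trace, settings, discounted=False) == pytest.approx(2.5745)


class TestYLL:
    def test_no_deaths_zero(self):
        lt = constant_qx_life_table(0.05)
        assert compute_yll([], lt, AnalysisSettings(), "male") == 0.0

    def test_undiscounted_equals_residual_expectancy(self):
        lt = constant_qx_life_table(1 / 10.5)  # ex ~= 10 away from the table end
        settings = AnalysisSettings(discount_rate=0.0)
        ex = lt.ex(40.0, "male")
        assert ex == pytest.approx(10.0, abs=0.05)
        got = compute_yll([Death(time=0.0, age=40.0, fraction=1.0)], lt, settings, "male")
        assert got == pytest.approx(ex, abs=1e-9)

    def test_discounted_midyear_annuity(self):
        """ex = 10 at 3%: sum over t of 1.03^-(t+1/2) = 8.656."""
        expected = sum(1.03 ** -(t + 0.5) for t in range(10))
        assert annuity_factor(10.0, 0.03) == pytest.approx(expected, abs=1e-12)
        assert annuity_factor(10.0, 0.03) == pytest.approx(8.656, abs=2e-3)

    def test_death_time_discounted_to_baseline(self):
        lt = constant_qx_life_table(1 / 10.5)
        settings = AnalysisSettings(discount_rate=0.03)
        at0 = compute_yll([Death(time=0.0, age=40.0, fraction=1.0)], lt, settings, "male")
        at5 = compute_yll([Death(time=5.0, age=45.0, fraction=1.0)], lt, settings, "male")
        # same residual expectancy (flat table), later death discounted more
        assert at5 == pytest.approx(at0 * discount_factor(5.0, 0.03), rel=1e-3)

    def test_fractional_years_prorated(self):
        whole = annuity_factor(3.0, 0.03)
        frac = annuity_factor(3.4, 0.03)
        assert whole < frac < annuity_factor(4.0, 0.03)


class TestYLD:
    def test_zero_weights_zero(self, bundle):
        trace = run_trace(bundle, bundle.strategy("SoC"), "male")
        weights = DisabilityWeightSet(
            weights={s: 0.0 for s in HealthState if s is not HealthState.DEATH}
        )
        assert compute_yld(trace, weights, bundle.settings) == 0.0

    def test_one_cycle_in_weighted_state(self):
        trace = manual_trace([1.0, 1.0])
        weights = {s: 0.0 for s in HealthState if s is not HealthState.DEATH}
        weights[HealthState.HYPERTENSION] = 0.2
        got = compute_yld(
            trace, DisabilityWeightSet(weights=weights), AnalysisSettings(discount_rate=0.0)
        )
        assert got == pytest.approx(0.2)

    def test_intervention_lowers_yld_on_fixture(self, bundle):
        """Event-state weights exceed the hypertension weight (zero), so the
        strategy with fewer events accrues less disability."""
        soc = run_trace(bundle, bundle.strategy("SoC"), "female")
        cobra = run_trace(bundle, bundle.strategy("COBRA"), "female")
        w, s = bundle.disability_weights, bundle.settings
        assert compute_yld(cobra, w, s) < compute_yld(soc, w, s)


class TestCosts:
    def _cost_set(self, hyp_annual=0.0):
        annual = {s: 0.0 for s in HealthState}
        annual[HealthState.HYPERTENSION] = hyp_annual
        return CostSet(annual_state_cost=annual, event_cost={},
                       intervention_cost_per_cycle=10.0)

    def test_zero_costs_zero(self):
        trace = manual_trace([1.0, 0.9])
        got = accrue_costs(trace, self._cost_set(), StrategySpec(name="SoC"),
                           AnalysisSettings(discount_rate=0.0))
        assert got == 0.0

    def test_routine_hypertension_care_cost(self):
        """One undiscounted patient-year of routine care costs US$201."""
        trace = manual_trace([1.0, 1.0])
        got = accrue_costs(trace, self._cost_set(201.0), StrategySpec(name="SoC"),
                           AnalysisSettings(discount_rate=0.0))
        assert got == pytest.approx(201.0)

    def test_intervention_adds_ten_per_patient_year(self):
        trace = manual_trace([1.0, 1.0])
        strategy = StrategySpec(name="COBRA", adds_intervention_cost=True)
        got = accrue_costs(trace, self._cost_set(201.0), strategy,
                           AnalysisSettings(discount_rate=0.0))
        assert got == pytest.approx(211.0)

    def test_discounting_commutes_with_aggregation(self, bundle):
        """Total discounted cost equals a plain per-cycle loop written
        independently of the vectorized accrual."""
        trace = run_trace(bundle, bundle.strategy("SoC"), "male")
        soc = bundle.strategy("SoC")
        total = accrue_costs(trace, bundle.costs, soc, bundle.settings)
        r = bundle.settings.discount_rate
        by_hand = 0.0
        for t in range(trace.n_cycles):
            mem = 0.5 * (trace.occupancy[t] + trace.occupancy[t + 1])
            state_cost = sum(
                mem[s.index] * bundle.costs.annual_state_cost.get(s, 0.0)
                for s in HealthState
            )
            event_cost = 0.0
            m = trace.matrices[t].probs
            for acute in (HealthState.STROKE, HealthState.CHD, HealthState.HF):
                inflow = sum(
                    trace.occupancy[t, src.index] * m[src.index, acute.index]
                    for src in HealthState
                    if src not in (acute, HealthState.DEATH)
                )
                event_cost += inflow * bundle.costs.event_cost.get(acute, 0.0)
            by_hand += (state_cost + event_cost) * (1 + r) ** -(t + 0.5)
        assert total == pytest.approx(by_hand, rel=1e-12)


class TestSummary:
    def test_daly_decomposition_exact(self, base_case):
        for per_level in base_case.strategies.values():
            for res in per_level.values():
                assert res.dalys == pytest.approx(res.yll + res.yld, abs=1e-12)

    def test_rate_zero_weight_zero_reduces_to_pure_yll(self, bundle):
        b = bundle.model_copy(deep=True)
        b.settings.discount_rate = 0.0
        b.disability_weights = DisabilityWeightSet(
            weights={s: 0.0 for s in HealthState if s is not HealthState.DEATH}
        )
        trace = run_trace(b, b.strategy("SoC"), "male")
        res = summarize(trace, b, b.strategy("SoC"))
        assert res.yld == 0.0
        assert res.dalys == pytest.approx(res.yll)
        assert res.yll == pytest.approx(
            compute_yll(trace_deaths(trace), b.life_table, b.settings, "male")
        )

    def test_intervention_gains_on_fixture(self, base_case):
        """Fewer DALYs and more years alive under the programme."""
        for level in ("male", "female", "pooled"):
            soc = base_case.strategies["SoC"][level]
            cobra = base_case.strategies["COBRA"][level]
            assert cobra.dalys <= soc.dalys
            assert cobra.years_alive >= soc.years_alive

    def test_years_alive_bounded_by_horizon(self, base_case, bundle):
        horizon = bundle.settings.age_cap - bundle.cohort.mean_age + 1
        for per_level in base_case.strategies.values():
            for res in per_level.values():
                assert 0 < res.years_alive <= horizon

    def test_null_bundle_summary(self):
        toy = make_toy_bundle(q=0.0)
        trace = run_trace(toy, toy.strategy("SoC"), "male")
        res = summarize(trace, toy, toy.strategy("SoC"))
        assert res.cost == 0.0
        assert res.yld == 0.0
        # the only DALYs are the residual-expectancy YLL at the horizon cap
        assert res.yll > 0
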