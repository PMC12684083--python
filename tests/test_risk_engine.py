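"""Risk-equation evaluation, SBP effect, horizon bridging, competing risks."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cobra_cea.parameters import ACUTE_STATES, HealthState, StrategySpec
from cobra_cea.risk_engine import (
    annual_event_probabilities,
    annual_event_rate,
    apply_sbp_effect,
    covariates_for,
    evaluate_risk_equation,
    multiyear_risk_to_annual_prob,
    normalize_competing,
)


class TestSBPEffect:
    def test_zero_delta_is_identity(self, bundle):
        cov = covariates_for(bundle, "male")
        assert apply_sbp_effect(cov, StrategySpec(name="SoC", sbp_delta=0.0)) is cov

    def test_shift_applied(self, bundle):
        cov = covariates_for(bundle, "female")
        cov = cov.__class__(**{**cov.__dict__, "sbp": 140.0})
        shifted = apply_sbp_effect(cov, StrategySpec(name="COBRA", sbp_delta=-4.99))
        assert shifted.sbp == pytest.approx(135.01)
        # only sbp changes
        assert shifted.age == cov.age and shifted.diabetes == cov.diabetes

    def test_floor_at_one_mmhg(self, bundle):
        cov = covariates_for(bundle, "male")
        shifted = apply_sbp_effect(cov, StrategySpec(name="X", sbp_delta=-1000.0))
        assert shifted.sbp == 1.0

    def test_positive_sbp_coefficient_lowers_risk_across_grid(self, bundle):
        """A blood-pressure reduction can never raise event risk when the
        SBP coefficient is positive."""
        cobra = bundle.strategy("COBRA")
        for sbp in np.linspace(110, 200, 10):
            cov = covariates_for(bundle, "male")
            cov = cov.__class__(**{**cov.__dict__, "sbp": float(sbp)})
            shifted = apply_sbp_effect(cov, cobra)
            for spec in bundle.risk_equations:
                assert spec.coefficients["sbp"] > 0
                assert evaluate_risk_equation(spec, shifted) <= evaluate_risk_equation(spec, cov)


class TestHorizonBridge:
    @pytest.mark.parametrize("h", [1, 5, 10])
    def test_boundary_cases(self, h):
        assert multiyear_risk_to_annual_prob(0.0, h) == 0.0
        assert multiyear_risk_to_annual_prob(1.0, h) == 1.0

    def test_ten_year_framingham_example(self):
        assert multiyear_risk_to_annual_prob(0.19, 10) == pytest.approx(
            1 - 0.81 ** 0.1, abs=1e-12
        )
        assert multiyear_risk_to_annual_prob(0.19, 10) == pytest.approx(0.0208516, abs=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            multiyear_risk_to_annual_prob(1.2, 10)
        with pytest.raises(ValueError):
            multiyear_risk_to_annual_prob(0.5, 0)

    @given(p=st.floats(0.0, 0.999), h=st.integers(1, 50))
    @settings(max_examples=200, deadline=None)
    def test_annual_survival_composes_back(self, p, h):
        """H independent annual survivals recover the H-year risk."""
        annual = multiyear_risk_to_annual_prob(p, h)
        assert 1 - (1 - annual) ** h == pytest.approx(p, abs=1e-12)


class TestCompetingRisks:
    def test_probability_conserved(self):
        rates = {HealthState.STROKE: 0.1, HealthState.CHD: 0.4, HealthState.HF: 0.02}
        alloc = normalize_competing(rates)
        stay = math.exp(-sum(rates.values()))
        assert sum(alloc.values()) + stay == pytest.approx(1.0, abs=1e-12)

    def test_allocation_proportional_to_rates(self):
        rates = {HealthState.STROKE: 0.2, HealthState.CHD: 0.1, HealthState.HF: 0.0}
        alloc = normalize_competing(rates)
        assert alloc[HealthState.STROKE] == pytest.approx(2 * alloc[HealthState.CHD])
        assert alloc[HealthState.HF] == 0.0

    def test_zero_rates(self):
        alloc = normalize_competing({HealthState.STROKE: 0.0})
        assert alloc[HealthState.STROKE] == 0.0


class TestAnnualEventProbabilities:
    def test_null_model_gives_zero(self, bundle):
        specs = [
            s.model_copy(update={
                "coefficients": {}, "baseline_term": -1000.0,
                "functional_form": "weibull_survival",
            })
            for s in bundle.risk_equations
        ]
        cov = covariates_for(bundle, "male")
        probs = annual_event_probabilities(cov, specs)
        assert all(p == 0.0 for p in probs.values())

    def test_kappa_scales_hazard(self, bundle):
        cov = covariates_for(bundle, "male")
        spec = bundle.risk_equation(HealthState.STROKE)
        r1 = annual_event_rate(spec, cov, 1.0)
        r2 = annual_event_rate(spec, cov, 2.0)
        assert r2 == pytest.approx(2 * r1)
        p1 = annual_event_probabilities(cov, bundle.risk_equations)
        p2 = annual_event_probabilities(cov, bundle.risk_equations, {"STROKE": 2.0})
        assert p2[HealthState.STROKE] > p1[HealthState.STROKE]

    def test_intervention_never_riskier(self, bundle):
        """At fixture coefficients the blood-pressure effect lowers every
        event probability (the published tables' uniform ordering)."""
        for sex in ("male", "female"):
            cov = covariates_for(bundle, sex)
            soc = annual_event_probabilities(cov, bundle.risk_equations)
            shifted = apply_sbp_effect(cov, bundle.strategy("COBRA"))
            cobra = annual_event_probabilities(shifted, bundle.risk_equations)
            for event in ACUTE_STATES:
                assert cobra[event] <= soc[event]

    def test_total_event_probability_below_one(self, bundle):
        cov = covariates_for(bundle, "male", age=99.0)
        probs = annual_event_probabilities(cov, bundle.risk_equations)
        assert sum(probs.values()) <= 1.0

    @given(sbp=st.floats(90.0, 220.0), bump=st.floats(0.1, 30.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_sbp(self, bundle, sbp, bump):
        cov = covariates_for(bundle, "female")
        lo = cov.__class__(**{**cov.__dict__, "sbp": sbp})
        hi = cov.__class__(**{**cov.__dict__, "sbp": sbp + bump})
        for spec in bundle.risk_equations:
            assert evaluate_risk_equation(spec, hi) >= evaluate_risk_equation(spec, lo)

    def test_missing_covariate_named_in_error(self, bundle):
        cov = covariates_for(bundle, "male")
        with pytest.raises(KeyError, match="bmi"):
            cov.value("bmi")
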