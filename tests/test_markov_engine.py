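"""Transition matrices, trace propagation, cumulative incidence."""

from __future__ import annotations

import numpy as np
import pytest

from cobra_cea.markov_engine import (
    N_STATES,
    build_transition_matrix,
    cumulative_incidence,
    n_cycles,
    run_trace,
)
from cobra_cea.parameters import ACUTE_STATES, POST_STATES, STATE_ORDER, HealthState

from conftest import make_toy_bundle

IDX = {s: i for i, s in enumerate(STATE_ORDER)}


class TestTransitionMatrix:
    def test_rows_sum_to_one_all_cycles(self, bundle):
        soc = bundle.strategy("SoC")
        for cycle in (0, 10, 25, 40):
            m = build_transition_matrix(cycle, "female", bundle, soc)
            assert np.allclose(m.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_death_absorbing(self, bundle):
        m = build_transition_matrix(0, "male", bundle, bundle.strategy("SoC"))
        expected = np.zeros(N_STATES)
        expected[IDX[HealthState.DEATH]] = 1.0
        assert np.array_equal(m.probs[IDX[HealthState.DEATH]], expected)

    def test_disallowed_transitions_exactly_zero(self, bundle):
        m = build_transition_matrix(0, "male", bundle, bundle.strategy("SoC"))
        # no recovery to the event-free state, no post-to-post jumps
        for post in POST_STATES:
            assert m.probs[IDX[post], IDX[HealthState.HYPERTENSION]] == 0.0
            for other in POST_STATES:
                if other is not post:
                    assert m.probs[IDX[post], IDX[other]] == 0.0
        # acute states can only die or progress to their own post state
        assert m.probs[IDX[HealthState.STROKE], IDX[HealthState.POST_CHD]] == 0.0
        assert m.probs[IDX[HealthState.STROKE], IDX[HealthState.HYPERTENSION]] == 0.0

    def test_null_dynamics_structural_identity(self):
        """Zero event risk and zero mortality: every row is a stay except the
        acute rows, which progress to their post state after the acute year."""
        toy = make_toy_bundle(q=0.0)
        m = build_transition_matrix(0, "male", toy, toy.strategy("SoC"))
        expected = np.eye(N_STATES)
        for acute in ACUTE_STATES:
            expected[IDX[acute], IDX[acute]] = 0.0
            from cobra_cea.parameters import ACUTE_TO_POST
            expected[IDX[acute], IDX[ACUTE_TO_POST[acute]]] = 1.0
        assert np.allclose(m.probs, expected, atol=1e-12)

    def test_certain_death(self):
        toy = make_toy_bundle(q=1.0)
        m = build_transition_matrix(0, "male", toy, toy.strategy("SoC"))
        assert np.allclose(m.probs[:, IDX[HealthState.DEATH]], 1.0)

    def test_intervention_lowers_first_event_entries(self, bundle):
        soc = build_transition_matrix(0, "male", bundle, bundle.strategy("SoC"))
        cobra = build_transition_matrix(0, "male", bundle, bundle.strategy("COBRA"))
        hyp = IDX[HealthState.HYPERTENSION]
        for event in ACUTE_STATES:
            assert cobra.probs[hyp, IDX[event]] <= soc.probs[hyp, IDX[event]]

    def test_age_outside_table_instructs_cap(self, bundle):
        with pytest.raises(ValueError, match="cap the horizon"):
            build_transition_matrix(200, "male", bundle, bundle.strategy("SoC"))


class TestTrace:
    def test_rows_sum_to_one_and_death_monotone(self, bundle):
        for name in ("SoC", "COBRA"):
            for sex in ("male", "female"):
                trace = run_trace(bundle, bundle.strategy(name), sex)
                assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
                death = trace.state_column(HealthState.DEATH)
                assert np.all(np.diff(death) >= -1e-12)
                assert np.all(trace.occupancy >= -1e-12)

    def test_trace_length_and_ages(self, bundle):
        trace = run_trace(bundle, bundle.strategy("SoC"), "male")
        T = n_cycles(bundle)
        assert trace.occupancy.shape == (T + 1, N_STATES)
        assert trace.ages[0] == bundle.cohort.mean_age
        assert trace.ages[1] - trace.ages[0] == bundle.settings.cycle_length

    def test_geometric_survival_closed_form(self):
        """With constant q = 0.1 and no events, alive occupancy is 0.9^t."""
        toy = make_toy_bundle(q=0.1)
        trace = run_trace(toy, toy.strategy("SoC"), "male")
        alive = trace.alive()
        for t in range(trace.n_cycles - 1):  # final cycle is the horizon closure
            assert alive[t] == pytest.approx(0.9 ** t, abs=1e-10)

    def test_horizon_closure_forces_death(self, bundle):
        trace = run_trace(bundle, bundle.strategy("SoC"), "female")
        assert trace.occupancy[-1, IDX[HealthState.DEATH]] == pytest.approx(1.0)

    def test_matrix_product_closed_form(self, bundle):
        """Row t equals initial occupancy times the product of matrices."""
        trace = run_trace(bundle, bundle.strategy("COBRA"), "male")
        state = np.zeros(N_STATES)
        state[IDX[HealthState.HYPERTENSION]] = 1.0
        for t, m in enumerate(trace.matrices):
            assert np.allclose(state, trace.occupancy[t], atol=1e-12)
            state = state @ m.probs
        assert np.allclose(state, trace.occupancy[-1], atol=1e-12)

    def test_null_strategy_equals_reference(self, bundle):
        """sbp_delta = 0 makes the intervention trace identical to SoC."""
        b = bundle.model_copy(deep=True)
        b.strategy("COBRA").sbp_delta = 0.0
        t_soc = run_trace(b, b.strategy("SoC"), "male")
        t_cob = run_trace(b, b.strategy("COBRA"), "male")
        assert np.array_equal(t_soc.occupancy, t_cob.occupancy)


class TestCumulativeIncidence:
    def test_zero_risk_zero_incidence(self):
        toy = make_toy_bundle(q=0.05)
        trace = run_trace(toy, toy.strategy("SoC"), "male")
        for event in ACUTE_STATES:
            for years in (5, 10, 30):
                assert cumulative_incidence(trace, event, years) == 0.0

    def test_nondecreasing_in_horizon(self, bundle):
        trace = run_trace(bundle, bundle.strategy("SoC"), "female")
        for event in ACUTE_STATES:
            vals = [cumulative_incidence(trace, event, y) for y in (5, 10, 30)]
            assert vals == sorted(vals)

    def test_constant_hazard_closed_form(self):
        """Constant annual stroke probability 0.02, no other exits:
        5-year cumulative incidence is 1 - 0.98^5."""
        toy = make_toy_bundle(q=0.0)
        # stroke-only risk: annual rate -ln(0.98) so the annual probability is 0.02
        spec = toy.risk_equation(HealthState.STROKE)
        rate = -np.log(0.98)
        # weibull_survival with shape 1: 10-year risk 1-exp(-10*rate)
        toy.risk_equations[toy.risk_equations.index(spec)] = spec.model_copy(
            update={"baseline_term": float(np.log(rate))}
        )
        trace = run_trace(toy, toy.strategy("SoC"), "male")
        got = cumulative_incidence(trace, HealthState.STROKE, 5)
        assert got == pytest.approx(1 - 0.98 ** 5, abs=1e-10)
        assert got == pytest.approx(0.09608, abs=1e-5)

    def test_unknown_event_rejected(self, bundle):
        trace = run_trace(bundle, bundle.strategy("SoC"), "male")
        with pytest.raises(ValueError):
            cumulative_incidence(trace, HealthState.POST_STROKE, 5)
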