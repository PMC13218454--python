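"""Markov engine: matrix construction, projection, discounting, accumulation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acescreen import markov as mk
from acescreen.parameters import TransitionInputs, UtilityTable

IDX = {s: i for i, s in enumerate(mk.STATES)}


def uniform_init(state="idiopathic_ace"):
    init = np.zeros(len(mk.STATES))
    init[IDX[state]] = 1.0
    return init


small_probs = st.floats(0.0, 0.3, allow_nan=False)


class TestTransitionMatrix:
    def test_all_zero_inputs_give_identity(self):
        t = TransitionInputs(0, 0, 0, 0, 0)
        assert np.array_equal(mk.build_transition_matrix(t), np.eye(len(mk.STATES)))

    def test_certain_mortality_sends_alive_states_to_death(self):
        t = TransitionInputs(background_mortality=1.0, omg_to_generalized=0,
                             incident_omg=0, incident_hypothyroid=0,
                             symptom_triggered_detection=0)
        m = mk.build_transition_matrix(t)
        for state in mk.STATES[:-1]:
            assert m[IDX[state], IDX["death"]] == 1.0

    def test_omg_row_arithmetic(self):
        t = TransitionInputs(background_mortality=0.01, omg_to_generalized=0.05,
                             incident_omg=0, incident_hypothyroid=0,
                             symptom_triggered_detection=0)
        m = mk.build_transition_matrix(t)
        row = m[IDX["omg_early_dx"]]
        assert row[IDX["omg_early_dx"]] == pytest.approx(0.94)
        assert row[IDX["generalized_mg"]] == pytest.approx(0.05)
        assert row[IDX["death"]] == pytest.approx(0.01)

    def test_excess_outflow_names_the_row(self):
        t = TransitionInputs(background_mortality=0.2, omg_to_generalized=0.3,
                             incident_omg=0, incident_hypothyroid=0,
                             symptom_triggered_detection=0.6)
        with pytest.raises(ValueError, match="omg_delayed"):
            mk.build_transition_matrix(t)

    @settings(deadline=None, max_examples=100)
    @given(mort=small_probs, gen=small_probs, inc=small_probs, det=small_probs)
    def test_rows_always_stochastic(self, mort, gen, inc, det):
        t = TransitionInputs(mort, gen, inc, inc, det)
        m = mk.build_transition_matrix(t)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert (m >= 0).all()


class TestRunCohort:
    def test_identity_matrix_freezes_occupancy(self):
        spec = mk.MarkovSpec(np.eye(7), uniform_init())
        trace = mk.run_cohort(spec, horizon=5, cohort_size=110)
        assert np.allclose(trace.occupancy, trace.occupancy[0])

    def test_conservation_of_cohort_mass(self, base_params):
        m = mk.build_transition_matrix(base_params.transitions)
        spec = mk.MarkovSpec(m, uniform_init())
        trace = mk.run_cohort(spec, horizon=10, cohort_size=110)
        assert np.allclose(trace.occupancy.sum(axis=1), 110, atol=1e-9)

    def test_geometric_decay_toy(self):
        # alive -> death with probability 0.5 per cycle: 100, 50, 25
        t = TransitionInputs(background_mortality=0.5, omg_to_generalized=0,
                             incident_omg=0, incident_hypothyroid=0,
                             symptom_triggered_detection=0)
        spec = mk.MarkovSpec(mk.build_transition_matrix(t), uniform_init())
        trace = mk.run_cohort(spec, horizon=2, cohort_size=100)
        assert trace.occupancy[:, IDX["idiopathic_ace"]] == pytest.approx([100, 50, 25])

    def test_death_occupancy_nondecreasing(self, base_params):
        m = mk.build_transition_matrix(base_params.transitions)
        init = np.full(7, 1 / 7)
        trace = mk.run_cohort(mk.MarkovSpec(m, init), horizon=10)
        death = trace.occupancy[:, IDX["death"]]
        assert (np.diff(death) >= -1e-12).all()

    def test_matches_path_enumeration_oracle(self):
        """Occupancy after <=3 cycles equals exhaustive path enumeration over
        a chain restricted to three states."""
        t = TransitionInputs(background_mortality=0.1, omg_to_generalized=0.2,
                             incident_omg=0, incident_hypothyroid=0,
                             symptom_triggered_detection=0)
        m = mk.build_transition_matrix(t)
        start = IDX["omg_early_dx"]  # reaches only generalized_mg and death
        horizon = 3
        expected = np.zeros((horizon + 1, 7))
        expected[0, start] = 1.0
        for k in range(1, horizon + 1):
            for path in itertools.product(range(7), repeat=k):
                prob = 1.0
                prev = start
                for node in path:
                    prob *= m[prev, node]
                    prev = node
                if prob > 0:
                    expected[k, path[-1]] += prob
        spec = mk.MarkovSpec(m, uniform_init("omg_early_dx"))
        trace = mk.run_cohort(spec, horizon=horizon)
        assert np.allclose(trace.occupancy, expected, atol=1e-12)


class TestDiscounting:
    @pytest.mark.parametrize(
        "year, rate, expected",
        [(0, 0.03, 1.0), (1, 0.03, 1 / 1.03), (5, 0.0, 1.0), (0, 0.0, 1.0)],
    )
    def test_discount_factor(self, year, rate, expected):
        assert mk.discount_factor(year, rate) == pytest.approx(expected)

    def test_annuity_closed_form(self):
        total = sum(mk.discount_factor(y, 0.03) for y in range(1, 11))
        assert total == pytest.approx((1 - 1.03 ** -10) / 0.03)
        assert total == pytest.approx(8.530203, abs=1e-6)


class TestAccumulateQalys:
    def _full_health_trace(self, cohort=110, horizon=10):
        spec = mk.MarkovSpec(np.eye(7), uniform_init())
        return mk.run_cohort(spec, horizon=horizon, cohort_size=cohort)

    def test_full_health_undiscounted_ceiling(self):
        trace = self._full_health_trace()
        q = mk.accumulate_qalys(trace, np.ones(7), rate=0.0)
        assert q == pytest.approx(1100.0)

    def test_zero_utilities_give_zero(self):
        trace = self._full_health_trace()
        assert mk.accumulate_qalys(trace, np.zeros(7), rate=0.03) == 0.0

    def test_full_health_discounted_equals_annuity(self):
        trace = self._full_health_trace()
        q = mk.accumulate_qalys(trace, np.ones(7), rate=0.03)
        assert q == pytest.approx(110 * 8.530203, abs=1e-2)

    def test_endpoint_mode_bounded_by_cohort(self):
        trace = self._full_health_trace()
        q = mk.accumulate_qalys(trace, np.ones(7), rate=0.03, mode="endpoint")
        assert q == pytest.approx(110.0)

    def test_missing_state_utility_raises(self):
        trace = self._full_health_trace()
        broken = UtilityTable(ted_severe=None)
        object.__setattr__(broken, "idiopathic_ace", None)
        with pytest.raises(ValueError, match="utility"):
            mk.accumulate_qalys(trace, broken, rate=0.03)

    @settings(deadline=None, max_examples=60)
    @given(
        utilities=st.lists(st.floats(0.0, 1.0), min_size=6, max_size=6),
        drop=st.integers(0, 5),
        delta=st.floats(0.01, 0.5),
    )
    def test_lowering_any_utility_never_raises_qalys(self, utilities, drop, delta):
        from acescreen.parameters import load_default_parameters

        m = mk.build_transition_matrix(load_default_parameters().transitions)
        init = np.full(7, 1 / 7)
        trace = mk.run_cohort(mk.MarkovSpec(m, init), horizon=10)
        u = np.array(utilities + [0.0])
        q_base = mk.accumulate_qalys(trace, u, rate=0.03)
        u_low = u.copy()
        u_low[drop] = max(u_low[drop] - delta, 0.0)
        assert mk.accumulate_qalys(trace, u_low, rate=0.03) <= q_base + 1e-9

    def test_shifting_mass_to_lower_utility_state_lowers_qalys(self, base_params):
        # raising the generalization rate moves patients 0.872 -> 0.739
        base = base_params
        worse = base.replace(
            transitions=TransitionInputs(
                background_mortality=0.005, omg_to_generalized=0.3,
                incident_omg=0, incident_hypothyroid=0,
                symptom_triggered_detection=0.25,
            )
        )
        init = uniform_init("omg_early_dx")
        u = mk.state_utilities(base.utilities)
        q = []
        for params in (base, worse):
            m = mk.build_transition_matrix(params.transitions)
            trace = mk.run_cohort(mk.MarkovSpec(m, init), horizon=10)
            q.append(mk.accumulate_qalys(trace, u, rate=0.03))
        assert q[1] < q[0]


class TestAccumulateCosts:
    def _trace(self, horizon=10):
        spec = mk.MarkovSpec(np.eye(7), uniform_init())
        return mk.run_cohort(spec, horizon=horizon, cohort_size=1.0)

    def test_one_time_only(self):
        trace = self._trace()
        assert mk.accumulate_costs(trace, 12345.0, None, rate=0.03) == 12345.0

    def test_visit_schedule_undiscounted(self):
        # 750 per visit, two per year over three years -> 4500 per patient
        trace = self._trace()
        total = mk.accumulate_costs(
            trace, 0.0, None, rate=0.0, visit_cost_per_year=1500.0, visit_years=3
        )
        assert total == pytest.approx(4500.0)

    def test_negative_cost_rejected(self):
        with pytest.raises(ValueError):
            mk.accumulate_costs(self._trace(), -1.0, None, rate=0.0)

    def test_transition_toll_charges_flows(self):
        t = TransitionInputs(background_mortality=0, omg_to_generalized=0,
                             incident_omg=0, incident_hypothyroid=0,
                             symptom_triggered_detection=0.5)
        m = mk.build_transition_matrix(t)
        trace = mk.run_cohort(mk.MarkovSpec(m, uniform_init("omg_delayed")), horizon=2)
        total = mk.accumulate_costs(
            trace, 0.0, None, rate=0.0,
            transition_tolls={("omg_delayed", "omg_early_dx"): 1000.0},
            matrix=m,
        )
        # flows: 0.5 in cycle 1, 0.25 in cycle 2
        assert total == pytest.approx(750.0)

    def test_tolls_require_matrix(self):
        with pytest.raises(ValueError, match="matrix"):
            mk.accumulate_costs(
                self._trace(), 0.0, None, rate=0.0,
                transition_tolls={("omg_delayed", "omg_early_dx"): 1.0},
            )
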