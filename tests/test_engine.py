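import numpy as np
import pytest
from hypothesis import given, strategies as st

from afib_cea import (
    Strategy,
    build_cycle_kernel,
    build_strategy_kernels,
    closed_form_two_state,
    run_cohort,
    run_microsim,
    run_strategy,
    summarize_trace,
    two_state_inputs,
)
from afib_cea.engine import DEATH, MIN, MOD, SEV, KernelError
from afib_cea.parameters import EventRisks, SeveritySplit, SimpleFatality, RunConfig

from _oracles import min_row_enumeration


def kernel_for(inputs, strategy=Strategy.WARFARIN):
    return build_cycle_kernel(inputs.risks[strategy], inputs.is_split,
                              inputs.ich_split, inputs.ech_fate, inputs.mi_fate,
                              inputs.run, strategy=strategy.value)


class TestCycleKernel:
    def test_min_row_matches_enumeration_oracle(self, base_inputs):
        """Every Min-row transition equals the branch-by-branch enumeration."""
        k = kernel_for(base_inputs)
        expected = min_row_enumeration(
            base_inputs.risks[Strategy.WARFARIN], base_inputs.is_split,
            base_inputs.ich_split, base_inputs.ech_fate, base_inputs.mi_fate)
        assert k.transition[MIN, DEATH] == pytest.approx(0.0334817, abs=1e-12)
        assert k.transition[MIN, DEATH] == pytest.approx(expected["Death"], abs=1e-15)
        assert k.transition[MIN, MIN] == pytest.approx(expected["Min"], abs=1e-15)
        assert k.transition[MIN, MOD] == pytest.approx(expected["Mod"], abs=1e-15)
        assert k.transition[MIN, SEV] == pytest.approx(expected["Sev"], abs=1e-15)

    def test_zero_risk_kernel_is_identity(self, base_inputs):
        risks = EventRisks(0, 0, 0, 0, 0)
        k = build_cycle_kernel(risks, base_inputs.is_split, base_inputs.ich_split,
                               base_inputs.ech_fate, base_inputs.mi_fate,
                               base_inputs.run)
        assert np.allclose(k.transition, np.eye(4))

    def test_death_row_absorbing_and_eventless(self, base_inputs):
        for k in build_strategy_kernels(base_inputs).values():
            assert np.array_equal(k.transition[DEATH], [0, 0, 0, 1])
            assert np.all(k.event_incidence[DEATH] == 0)

    def test_severe_state_only_maintains_or_dies(self, base_inputs):
        k = kernel_for(base_inputs)
        p_death = base_inputs.risks[Strategy.WARFARIN].p_death
        assert k.transition[SEV, SEV] == pytest.approx(1 - p_death)
        assert k.transition[SEV, DEATH] == pytest.approx(p_death)
        assert k.transition[SEV, MIN] == 0 and k.transition[SEV, MOD] == 0

    def test_overflowing_probabilities_name_strategy(self, base_inputs):
        risks = EventRisks(0.5, 0.3, 0.2, 0.2, 0.2)
        with pytest.raises(KernelError, match="warfarin"):
            build_cycle_kernel(risks, base_inputs.is_split, base_inputs.ich_split,
                               base_inputs.ech_fate, base_inputs.mi_fate,
                               base_inputs.run, strategy="warfarin")

    def test_events_from_moderate_partition(self, base_inputs):
        base_inputs.run.events_from_moderate = True
        k = kernel_for(base_inputs)
        # moderate patients now face acute events; light outcomes cannot
        # improve their state, so Mod never transitions to Min
        assert k.event_incidence[MOD].sum() > 0
        assert k.transition[MOD, MIN] == 0
        assert k.transition[MOD].sum() == pytest.approx(1.0, abs=1e-12)

    @given(
        probs=st.lists(st.floats(0, 0.19), min_size=5, max_size=5),
        raw_split=st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
    )
    def test_rows_sum_to_one_property(self, probs, raw_split):
        """Transition rows sum to 1 for any valid competing-risk inputs."""
        risks = EventRisks(*probs)
        s = sum(raw_split)
        split = SeveritySplit(*[x / s for x in raw_split])
        k = build_cycle_kernel(risks, split, split, SimpleFatality(0.3),
                               SimpleFatality(0.1), RunConfig())
        assert np.allclose(k.transition.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(k.transition >= 0) and np.all(k.transition <= 1)


class TestCohort:
    def test_undiscounted_qaly_no_mortality(self):
        mi = two_state_inputs(p_death=0.0, u=0.76, c=0.0)
        mi.run.discount_rate = 0.0
        out = run_strategy(mi, "warfarin")
        assert out.total_qaly == pytest.approx(0.76 * 30, abs=1e-12)

    def test_discounted_annuity_closed_form(self):
        mi = two_state_inputs(p_death=0.0, u=0.76, c=0.0)
        out = run_strategy(mi, "warfarin")
        expected = 0.76 * sum(1.03 ** (-t) for t in range(30))
        assert out.total_qaly == pytest.approx(expected, abs=1e-9)

    def test_certain_death_accrues_exactly_one_cycle(self):
        mi = two_state_inputs(p_death=1.0, u=0.5, c=100.0)
        kernel = build_strategy_kernels(mi)["warfarin"]
        trace = run_cohort(kernel, mi.costs, mi.utilities, mi.run)
        assert trace.occupancy[1, DEATH] == pytest.approx(1.0)
        out = summarize_trace(trace, mi.run)
        assert out.total_qaly == pytest.approx(0.5)
        assert out.total_cost == pytest.approx(100.0)

    @pytest.mark.parametrize("p_death", [0.0, 0.02, 0.5, 1.0])
    @pytest.mark.parametrize("rate", [0.0, 0.03, 0.08])
    @pytest.mark.parametrize("horizon", [1, 7, 30])
    def test_matches_two_state_closed_form(self, p_death, rate, horizon):
        mi = two_state_inputs(p_death=p_death, u=0.7, c=1234.5)
        mi.run.discount_rate = rate
        mi.run.horizon_cycles = horizon
        out = run_strategy(mi, "rivaroxaban")
        cost, qaly = closed_form_two_state(p_death, 0.7, 1234.5, rate, horizon)
        assert out.total_cost == pytest.approx(cost, abs=1e-9)
        assert out.total_qaly == pytest.approx(qaly, abs=1e-9)

    def test_occupancy_rows_sum_to_one_and_death_monotone(self, base_inputs):
        kernel = build_strategy_kernels(base_inputs)["warfarin"]
        trace = run_cohort(kernel, base_inputs.costs, base_inputs.utilities,
                           base_inputs.run)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(trace.occupancy[:, DEATH]) >= -1e-15)
        assert trace.occupancy[0, MIN] == 1.0

    def test_zero_discount_equals_column_sums(self, base_inputs):
        base_inputs.run.discount_rate = 0.0
        kernel = build_strategy_kernels(base_inputs)["warfarin"]
        trace = run_cohort(kernel, base_inputs.costs, base_inputs.utilities,
                           base_inputs.run)
        out = summarize_trace(trace, base_inputs.run)
        assert out.total_cost == pytest.approx(trace.cost_per_cycle.sum())
        assert out.total_qaly == pytest.approx(trace.qaly_per_cycle.sum())

    def test_qaly_bounded_by_discounted_annuity_and_life_years(self, base_inputs):
        for s in Strategy:
            out = run_strategy(base_inputs, s)
            annuity = sum(1.03 ** (-t) for t in range(30))
            assert 0 < out.total_qaly <= annuity
            assert out.total_qaly <= out.life_years + 1e-12

    @pytest.mark.parametrize("pid, direction", [
        ("p_is.warfarin", -1), ("p_ich.warfarin", -1), ("p_ech.warfarin", -1),
        ("p_mi.warfarin", -1), ("p_death.warfarin", -1),
        ("u_min", +1), ("u_mod", +1), ("u_sev", +1), ("m_ich", +1),
    ])
    def test_qaly_monotone_in_risks_and_utilities(self, base_inputs, pid, direction):
        """QALYs fall when any event risk rises and rise with any utility."""
        from afib_cea.parameters import get_parameter, set_parameter
        before = run_strategy(base_inputs, "warfarin").total_qaly
        bumped = base_inputs.copy()
        set_parameter(bumped, pid, get_parameter(bumped, pid) + 0.01)
        after = run_strategy(bumped, "warfarin").total_qaly
        assert (after - before) * direction > 0

    def test_trace_frame_has_one_row_per_cycle(self, base_inputs):
        kernel = build_strategy_kernels(base_inputs)["rivaroxaban"]
        trace = run_cohort(kernel, base_inputs.costs, base_inputs.utilities,
                           base_inputs.run)
        df = trace.to_frame()
        assert len(df) == 30
        assert {"cycle", "occ_Min", "events_IS", "cost", "qaly"} <= set(df.columns)


class TestMicrosim:
    def test_same_seed_is_deterministic(self, base_inputs):
        kernel = build_strategy_kernels(base_inputs)["warfarin"]
        a = run_microsim(kernel, base_inputs.costs, base_inputs.utilities,
                         base_inputs.run, n_patients=500, seed=7)
        b = run_microsim(kernel, base_inputs.costs, base_inputs.utilities,
                         base_inputs.run, n_patients=500, seed=7)
        assert a.total_cost == b.total_cost and a.total_qaly == b.total_qaly

    def test_certain_death_zero_variance(self):
        mi = two_state_inputs(p_death=1.0, u=0.5, c=10.0)
        kernel = build_strategy_kernels(mi)["warfarin"]
        out = run_microsim(kernel, mi.costs, mi.utilities, mi.run,
                           n_patients=200, seed=1)
        assert out.total_qaly == pytest.approx(0.5)
        assert out.mc_stderr["qaly"] == 0.0

    def test_means_agree_with_cohort_expectation(self, base_inputs):
        """The cohort model is the exact expectation of the microsimulation."""
        kernel = build_strategy_kernels(base_inputs)["warfarin"]
        cohort = summarize_trace(
            run_cohort(kernel, base_inputs.costs, base_inputs.utilities,
                       base_inputs.run), base_inputs.run)
        micro = run_microsim(kernel, base_inputs.costs, base_inputs.utilities,
                             base_inputs.run, n_patients=20_000, seed=42)
        assert abs(micro.total_cost - cohort.total_cost) < 3 * micro.mc_stderr["cost"]
        assert abs(micro.total_qaly - cohort.total_qaly) < 3 * micro.mc_stderr["qaly"]
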