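"""Markov engine: transition matrices, cohort traces, payoffs, accrual."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cariescea.engine import (
    HealthState,
    accrue,
    annual_new_caries_probability,
    build_transition_matrix,
    initial_distribution,
    run_cohort,
    state_costs,
    CohortTrace,
    CyclePayoffs,
)
from cariescea.params import ModelSettings

H, A, U = HealthState.HEALTHY, HealthState.ACTIVE_CARIES, HealthState.UNTREATED


class TestTransitionMatrix:
    def test_treated_return_default_convention(self, params):
        """ACTIVE -> HEALTHY = p_seek x (p_rest + p_ext + p_pulp)."""
        m = build_transition_matrix(params, "intervention")
        assert m[A, H] == pytest.approx(0.90 * (0.40 + 0.06 + 0.04))
        mc = build_transition_matrix(params, "comparison")
        assert mc[A, H] == pytest.approx(0.68 * 0.50)

    def test_new_caries_probability_constant_hazard(self, params):
        hazard = params.with_settings(probability_conversion="constant_hazard")
        m = build_transition_matrix(hazard, "intervention")
        assert m[H, A] == pytest.approx(1 - (1 - 0.479) ** 0.5, abs=1e-9)

    def test_new_caries_probability_default_rate_convention(self, params):
        m = build_transition_matrix(params, "intervention")
        assert m[H, A] == pytest.approx(1 - np.exp(-0.479 / 2), abs=1e-9)
        assert annual_new_caries_probability(params, "intervention") == pytest.approx(m[H, A])

    def test_structural_zeros(self, params):
        for arm in ("intervention", "comparison"):
            m = build_transition_matrix(params, arm)
            assert m[H, U] == 0.0  # healthy children cannot become untreated
            assert m[U, H] == 0.0  # no route back to health without treatment
            assert m[U, A] == pytest.approx(m[H, A])  # same new-caries hazard

    @given(
        p2y=st.floats(0.0, 0.95),
        p_seek=st.floats(0.0, 1.0),
    )
    def test_rows_are_stochastic_for_any_inputs(self, params, p2y, p_seek):
        varied = params.with_overrides(
            {"intervention.p_new_caries": p2y, "intervention.p_seek_treatment": p_seek}
        )
        m = build_transition_matrix(varied, "intervention")
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert (m >= 0).all() and (m <= 1).all()


class TestInitialDistribution:
    @pytest.mark.parametrize(
        "arm, expected",
        [("intervention", (0.29, 0.71, 0.0)), ("comparison", (0.20, 0.80, 0.0))],
    )
    def test_baseline_prevalence_starts_active(self, params, arm, expected):
        assert initial_distribution(params, arm) == pytest.approx(expected)

    def test_zero_prevalence_scenario(self, params):
        p0 = params.with_overrides({"intervention.p_caries_baseline": 0.0})
        assert initial_distribution(p0, "intervention") == pytest.approx((1.0, 0.0, 0.0))


class TestCohortTrace:
    def test_identity_matrix_keeps_trace_constant(self):
        trace = run_cohort(np.eye(3), np.array([0.3, 0.5, 0.2]), 5)
        assert np.allclose(trace.occupancy, [0.3, 0.5, 0.2])

    def test_mass_conservation_over_horizon(self, params):
        for arm in ("intervention", "comparison"):
            trace = run_cohort(
                build_transition_matrix(params, arm),
                initial_distribution(params, arm),
                params.settings.horizon_cycles,
                arm=arm,
            )
            assert trace.occupancy.shape == (11, 3)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
            assert np.allclose(trace.occupancy[0], initial_distribution(params, arm))

    def test_long_format_export(self, params):
        trace = run_cohort(
            build_transition_matrix(params, "comparison"),
            initial_distribution(params, "comparison"),
            10,
            arm="comparison",
        )
        df = trace.to_frame()
        assert list(df.columns) == ["cycle", "arm", "state", "occupancy"]
        assert len(df) == 11 * 3
        assert df.groupby("cycle")["occupancy"].sum().round(9).eq(1.0).all()


class TestStateCosts:
    def test_intervention_prevention_bundle(self, params):
        costs = state_costs(params, "intervention").costs
        assert costs[H] == pytest.approx(53 + 38 + 47 + 30)  # 168

    def test_comparison_healthy_state_costs_nothing(self, params):
        assert state_costs(params, "comparison").costs[H] == 0.0

    def test_active_state_cost_composition(self, params):
        """p_seek x (clinic visit + shared services + expected treatment mix)."""
        mix = 0.40 * 145 + 0.06 * 195 + 0.04 * 77
        assert mix == pytest.approx(72.78)
        visit = 53 + 38 + 0.5 * (55 + 91) + 0.25 * (50 + 37)
        for arm, p_seek in (("intervention", 0.90), ("comparison", 0.68)):
            costs = state_costs(params, arm).costs
            assert costs[A] == pytest.approx(p_seek * (visit + mix))
            assert costs[U] == 0.0

    def test_sealant_fraction_scales_bundle(self, params):
        half = params.with_settings(fraction_sealant=0.5)
        assert state_costs(half, "intervention").costs[H] == pytest.approx(168 - 23.5)

    def test_utilities_shared_between_caries_states(self, params):
        u = state_costs(params, "intervention").utilities
        assert u[H] == 1.0
        assert u[A] == u[U] == 0.87


class TestAccrual:
    def test_maximal_qaly_accrual(self):
        trace = CohortTrace(arm="x", occupancy=np.tile([1.0, 0.0, 0.0], (11, 1)))
        payoffs = CyclePayoffs(arm="x", costs=np.zeros(3), utilities=np.array([1.0, 0.87, 0.87]))
        acc = accrue(trace, payoffs, ModelSettings(discount_rate_qalys=0.0))
        assert acc.qalys == pytest.approx(10.0)

    def test_all_caries_scales_by_utility(self):
        trace = CohortTrace(arm="x", occupancy=np.tile([0.0, 1.0, 0.0], (11, 1)))
        payoffs = CyclePayoffs(arm="x", costs=np.zeros(3), utilities=np.array([1.0, 0.87, 0.87]))
        acc = accrue(trace, payoffs, ModelSettings(discount_rate_qalys=0.0))
        assert acc.qalys == pytest.approx(8.7)

    def test_first_cycle_undiscounted(self):
        trace = CohortTrace(arm="x", occupancy=np.tile([1.0, 0.0, 0.0], (2, 1)))
        payoffs = CyclePayoffs(arm="x", costs=np.array([100.0, 0, 0]), utilities=np.ones(3))
        acc = accrue(trace, payoffs, ModelSettings(horizon_cycles=1, discount_rate_costs=0.05))
        assert acc.cost == pytest.approx(100.0)

    def test_discounting_reduces_costs(self, params):
        arm = "intervention"
        trace = run_cohort(
            build_transition_matrix(params, arm), initial_distribution(params, arm), 10, arm=arm
        )
        payoffs = state_costs(params, arm)
        disc = accrue(trace, payoffs, params.settings)
        undisc = accrue(trace, payoffs, ModelSettings(discount_rate_costs=0.0))
        assert disc.cost < undisc.cost

    def test_event_count_flags(self, params):
        arm = "comparison"
        trace = run_cohort(
            build_transition_matrix(params, arm), initial_distribution(params, arm), 10, arm=arm
        )
        payoffs = state_costs(params, arm)
        without = accrue(trace, payoffs, params.settings)
        with_init = accrue(
            trace, payoffs, ModelSettings(include_initial_lesions=True)
        )
        assert with_init.caries_events == pytest.approx(without.caries_events + 0.80)


class TestMicrosimulationOracle:
    def test_cohort_model_matches_individual_simulation(self, params):
        """An individual-level Monte-Carlo simulation with the same matrix and
        payoffs reproduces the cohort model's expected discounted cost and
        QALYs within three standard errors (100,000 children)."""
        rng = np.random.default_rng(20180101)
        n = 100_000
        for arm in ("intervention", "comparison"):
            matrix = build_transition_matrix(params, arm)
            init = initial_distribution(params, arm)
            payoffs = state_costs(params, arm)
            s = params.settings
            horizon = s.horizon_cycles

            states = rng.choice(3, size=n, p=init)
            cum = matrix.cumsum(axis=1)
            cost = np.zeros(n)
            qaly = np.zeros(n)
            for t in range(1, horizon + 1):
                draws = rng.random(n)
                states = (draws[:, None] > cum[states]).sum(axis=1)
                cost += (1 + s.discount_rate_costs) ** -(t - 1) * payoffs.costs[states]
                qaly += (1 + s.discount_rate_qalys) ** -(t - 1) * payoffs.utilities[states]

            trace = run_cohort(matrix, init, horizon, arm=arm)
            expected = accrue(trace, payoffs, s)
            for mc, ref in ((cost, expected.cost), (qaly, expected.qalys)):
                se = mc.std(ddof=1) / np.sqrt(n)
                assert abs(mc.mean() - ref) < 3 * se, arm
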