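"""Markov cohort engine: transition structure, trace invariants,
closed-form checks and convergence with the static model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_dynamic_params
from dyscue.errors import InvalidInputError
from dyscue.markov import (
    AP_ENTRY_STATES,
    DYSPHAGIA_STATES,
    N_STATES,
    CohortTrace,
    HealthState,
    accrue,
    build_transition_matrix,
    build_transition_row,
    dynamic_cea,
    run_cohort,
)
from dyscue.static_model import StaticParams, static_cea


class TestTransitionRows:
    def test_dead_state_is_absorbing(self, base_config):
        params = base_config.dynamic_params()
        row = build_transition_row(HealthState.DEAD, 20, "comparator", params)
        assert row[HealthState.DEAD] == 1.0 and row.sum() == 1.0

    def test_ap_onset_probability_before_competing_adjustment(self, base_config):
        # hazard-scale conversion: 1 - exp(-0.004036 * 8.27)
        params = base_config.dynamic_params()
        row = build_transition_row(HealthState.DYS_ASP, 20, "comparator", params)
        m = params.mortality.weekly_death_prob[19]
        onset = row[HealthState.AP1_FROM_ASP] / (1 - m)
        assert onset == pytest.approx(0.032827, rel=1e-4)

    def test_zero_hazards_give_identity_for_non_tunnel_states(
            self, zero_hazard_params):
        for state in (HealthState.NO_DYSPHAGIA, HealthState.DYS_NO_ASP,
                      HealthState.DYS_ASP, HealthState.DEAD):
            row = build_transition_row(state, 1, "intervention",
                                       zero_hazard_params)
            assert row[state] == 1.0

    def test_tunnel_chain_structure(self, base_config):
        params = base_config.dynamic_params()
        week1 = build_transition_row(HealthState.AP1_FROM_ASP, 2,
                                     "comparator", params)
        assert set(np.nonzero(week1)[0]) <= {HealthState.AP2_FROM_ASP,
                                             HealthState.DEAD}
        week2 = build_transition_row(HealthState.AP2_FROM_ASP, 2,
                                     "comparator", params)
        assert set(np.nonzero(week2)[0]) <= {HealthState.DYS_ASP,
                                             HealthState.DEAD}

    def test_tunnel_death_uses_scaled_hazard(self, base_config):
        params = base_config.dynamic_params()
        m = params.mortality.weekly_death_prob[0]
        row = build_transition_row(HealthState.AP1_FROM_ASP, 1,
                                   "comparator", params)
        expected = 1 - (1 - m) ** params.rr_death_ap
        assert row[HealthState.DEAD] == pytest.approx(expected)

    def test_week_out_of_range_rejected(self, base_config):
        params = base_config.dynamic_params()
        with pytest.raises(InvalidInputError):
            build_transition_row(HealthState.DYS_ASP, 0, "comparator", params)


class TestCohortTrace:
    def test_resolution_only_cohort_follows_geometric_decay(self):
        params = make_dynamic_params(
            horizon=30, resolution=0.05, baseline_ap_ir_weekly=0.0,
            deterioration_weekly=0.0, monitoring_weeks=frozenset())
        trace = run_cohort("intervention", params)
        dys = trace.occupancy[:, HealthState.DYS_NO_ASP]
        assert np.allclose(dys, 0.95 ** np.arange(31))

    def test_mortality_only_cohort_matches_survival_product(self, base_config):
        params = make_dynamic_params(
            horizon=52,
            mortality=base_config.dynamic_params().mortality,
            baseline_ap_ir_weekly=0.0, deterioration_weekly=0.0,
            monitoring_weeks=frozenset())
        trace = run_cohort("comparator", params)
        closed_form = (1 - 0.046) ** 4 * (1 - 0.0096) ** 9 * (1 - 0.0024) ** 39
        assert trace.alive()[-1] == pytest.approx(closed_form, rel=1e-12)

    def test_zero_horizon_trace_is_initial_occupancy(self):
        params = make_dynamic_params(horizon=0, monitoring_weeks=frozenset())
        trace = run_cohort("comparator", params)
        assert trace.occupancy.shape == (1, N_STATES)
        assert trace.occupancy[0, HealthState.DYS_ASP] == 1.0

    def test_base_case_trace_invariants(self, base_config):
        params = base_config.dynamic_params()
        for arm in ("intervention", "comparator"):
            occ = run_cohort(arm, params).occupancy
            assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-10)
            dead = occ[:, HealthState.DEAD]
            assert np.all(np.diff(dead) >= -1e-15)
            assert np.all((occ >= -1e-15) & (occ <= 1 + 1e-15))

    @given(
        m=st.floats(0.0, 0.2), r=st.floats(0.0, 0.5),
        ir=st.floats(0.0, 0.05), det=st.floats(0.0, 0.01),
        rr_asp=st.floats(1.0, 12.0), rr_death=st.floats(1.0, 5.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_occupancy_conserved_over_random_configs(self, m, r, ir, det,
                                                     rr_asp, rr_death):
        params = make_dynamic_params(
            horizon=20, resolution=r, mortality=m,
            baseline_ap_ir_weekly=ir, deterioration_weekly=det,
            rr_ap_asp=rr_asp, rr_death_ap=rr_death,
            monitoring_weeks=frozenset())
        for arm in ("intervention", "comparator"):
            occ = run_cohort(arm, params).occupancy
            assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(np.diff(occ[:, HealthState.DEAD]) >= -1e-12)

    @given(m=st.floats(0.0, 0.3), r=st.floats(0.0, 0.6))
    @settings(max_examples=60, deadline=None)
    def test_transition_matrices_row_stochastic(self, m, r):
        params = make_dynamic_params(horizon=5, resolution=r, mortality=m,
                                     monitoring_weeks=frozenset())
        for week in range(1, 6):
            matrix = build_transition_matrix(week, "comparator", params)
            assert np.allclose(matrix.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(matrix >= 0)


class TestAccrual:
    def test_all_dead_trace_accrues_nothing(self):
        params = make_dynamic_params(horizon=4, monitoring_weeks=frozenset())
        occ = np.zeros((5, N_STATES))
        occ[:, HealthState.DEAD] = 1.0
        result = accrue(CohortTrace(occ), "intervention", params)
        assert result.qaly == 0.0 and result.cost_total == 0.0

    def test_full_year_dysphagia_occupancy_yields_state_utility(self):
        params = make_dynamic_params(horizon=52, baseline_ap_ir_weekly=0.0,
                                     deterioration_weekly=0.0,
                                     monitoring_weeks=frozenset())
        trace = run_cohort("intervention", params)
        result = accrue(trace, "intervention", params)
        assert result.qaly == pytest.approx(0.37)
        assert result.cost_dysphagia_treatment == \
            pytest.approx(params.nutilis_weekly_cost * 52)

    def test_monitoring_bounded_by_visit_count(self, base_config):
        params = base_config.dynamic_params()
        for arm in ("intervention", "comparator"):
            result = accrue(run_cohort(arm, params), arm, params)
            assert 0 < result.cost_monitoring < \
                len(params.monitoring_weeks) * params.cost_monitoring_visit

    def test_ap_cost_charged_once_per_tunnel_entry(self, base_config):
        params = base_config.dynamic_params()
        trace = run_cohort("comparator", params)
        entries = trace.occupancy[1:, AP_ENTRY_STATES].sum()
        result = accrue(trace, "comparator", params)
        assert result.cost_ap_treatment == \
            pytest.approx(params.cost_ap_episode * entries)


class TestDynamicCEA:
    @staticmethod
    def _match_hazard(target_risk, arm, rr_field):
        """Weekly pneumonia hazard whose 8-week expected episode count in the
        cohort engine equals the static model's cumulative risk.  (The static
        model admits at most one episode; matching the cumulative burden is
        the degenerate configuration under which the two models describe the
        same process.)"""

        def entries(hazard):
            params = make_dynamic_params(
                horizon=8, baseline_ap_ir_weekly=1.0,
                deterioration_weekly=0.0, monitoring_weeks=frozenset(),
                **{rr_field: hazard})
            trace = run_cohort(arm, params)
            return trace.occupancy[1:, AP_ENTRY_STATES].sum()

        lo, hi = -np.log(1 - target_risk) / 8 * np.array([0.8, 1.2])
        for _ in range(40):  # bisection on the monotone entry count
            mid = 0.5 * (lo + hi)
            if entries(mid) < target_risk:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def test_static_dynamic_convergence_on_degenerate_config(self):
        """With the one-year features off and 8-week pneumonia burdens matched,
        the cohort engine reproduces the closed-form model within 1%."""
        params = make_dynamic_params(
            horizon=8,
            baseline_ap_ir_weekly=1.0,
            rr_ap_no_asp=self._match_hazard(1 / 57, "intervention",
                                            "rr_ap_no_asp"),
            rr_ap_asp=self._match_hazard(10 / 82, "comparator", "rr_ap_asp"),
            deterioration_weekly=0.0,
            monitoring_weeks=frozenset(),
        )
        dynamic = dynamic_cea(params)
        static = static_cea(StaticParams())
        for dyn_arm, stat_arm in ((dynamic.intervention, static.intervention),
                                  (dynamic.comparator, static.comparator)):
            assert dyn_arm.qaly == pytest.approx(stat_arm.qaly, rel=0.01)
            assert dyn_arm.cost_total == pytest.approx(stat_arm.cost_total,
                                                       rel=0.01)
        assert dynamic.icur == pytest.approx(static.icur, rel=0.02)

    def test_intervention_dominates_comparator_qaly(self, base_config):
        cmp = dynamic_cea(base_config.dynamic_params())
        assert cmp.intervention.qaly >= cmp.comparator.qaly
        assert cmp.delta_qaly > 0 and cmp.icur is not None

    def test_identical_arm_risks_give_near_zero_qaly_gain(self):
        params = make_dynamic_params(
            horizon=20, resolution=0.05, mortality=0.01,
            rr_ap_no_asp=4.0, rr_ap_asp=4.0,
            u_dys_asp=0.25, u_dys_no_asp=0.25,
            deterioration_weekly=0.0, monitoring_weeks=frozenset(),
            nutilis_weekly_cost=0.0)
        cmp = dynamic_cea(params)
        assert cmp.delta_qaly == pytest.approx(0.0, abs=1e-12)
        assert cmp.icur is None

    def test_monitoring_cost_difference_is_small(self, base_config):
        cmp = dynamic_cea(base_config.dynamic_params())
        mon_diff = abs(cmp.intervention.cost_monitoring
                       - cmp.comparator.cost_monitoring)
        assert mon_diff < 0.1 * cmp.intervention.cost_monitoring
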