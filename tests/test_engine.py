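"""Transition-matrix construction and the cohort recursion."""

import dataclasses

import numpy as np
import pytest

from asthmacea import engine
from asthmacea.params import CaseFatalityTable, HealthState
from conftest import constant_life_table, set_value

E, F, G, H = (HealthState[s].value for s in "EFGH")


def zero_asthma_deaths(params):
    set_value(params.exacerbation, "p_EG", 0.0)
    params.case_fatality = CaseFatalityTable([(50, 105, 0.0)])
    params.case_fatality_spec = params.case_fatality.to_dict()
    return params


class TestBuildMatrix:
    def test_rows_stochastic_all_ages_both_arms(self, base_params):
        for arm in ("RMTAC_UC", "UC"):
            for age in (50, 75, 104):
                M = engine.build_transition_matrix(base_params, age, arm)
                np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
                assert np.all(M >= 0)

    def test_death_states_absorbing(self, base_params):
        M = engine.build_transition_matrix(base_params, 60, "UC")
        for s in (G, H):
            expected = np.zeros(8)
            expected[s] = 1.0
            np.testing.assert_array_equal(M[s], expected)

    def test_no_return_to_low_adherence_after_exacerbation(self, base_params):
        M = engine.build_transition_matrix(base_params, 60, "RMTAC_UC")
        B, D = HealthState.B.value, HealthState.D.value
        assert M[E, B] == 0.0 and M[E, D] == 0.0
        assert M[F, B] == 0.0 and M[F, D] == 0.0

    def test_unit_hazard_ratio_equalizes_exacerbation_columns(self, params):
        set_value(params.exacerbation, "hr_good_control", 1.0)
        set_value(params.exacerbation, "hr_poor_control", 1.0)
        M = engine.build_transition_matrix(params, 50, "RMTAC_UC")
        A, B, C, D = range(4)
        assert M[A, E] == pytest.approx(M[B, E], abs=1e-14)
        assert M[A, F] == pytest.approx(M[B, F], abs=1e-14)
        assert M[C, E] == pytest.approx(M[D, E], abs=1e-14)
        assert M[C, F] == pytest.approx(M[D, F], abs=1e-14)

    def test_certain_background_death_boundary(self, params):
        params.life_table = constant_life_table(1.0)
        M = engine.build_transition_matrix(params, 70, "UC")
        for row in range(6):
            assert M[row, G] + M[row, H] == pytest.approx(1.0, abs=1e-12)
            assert M[row, :6].sum() == pytest.approx(0.0, abs=1e-12)

    def test_worked_row_a_exacerbation_entry(self, params):
        # (1 - q) * (1 - (1 - p_BE)^hr_good) with q = 0.0003
        params.life_table = constant_life_table(0.0003)
        M = engine.build_transition_matrix(params, 50, "RMTAC_UC")
        expected = (1 - 0.0003) * (1 - (1 - 0.09273) ** 0.72)
        assert M[0, E] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.0676483, abs=1e-7)

    def test_incompatible_parameters_error(self, params):
        set_value(params.exacerbation, "p_DE", 0.6)
        set_value(params.exacerbation, "p_DF", 0.3)
        with pytest.raises(ValueError, match="sum past 1"):
            engine.build_transition_matrix(params, 50, "RMTAC_UC")


class TestCohortRun:
    def test_probability_conservation(self, base_params):
        for arm in ("RMTAC_UC", "UC"):
            trace, _ = engine.run_cohort(base_params, arm)
            totals = trace.occupancy.sum(axis=1)
            np.testing.assert_allclose(totals, 1.0, atol=1e-9)

    def test_flows_redistribute_previous_occupancy(self, base_params):
        trace, _ = engine.run_cohort(base_params, "UC")
        for t in (1, 100, 660):
            np.testing.assert_allclose(trace.flows[t - 1].sum(axis=1),
                                       trace.occupancy[t - 1], atol=1e-12)
            np.testing.assert_allclose(trace.flows[t - 1].sum(axis=0),
                                       trace.occupancy[t], atol=1e-12)

    def test_full_horizon_survival_identity(self, params):
        # no deaths, unit utilities, zero discount: LY = QALY = 660/12 = 55
        params.life_table = constant_life_table(0.0)
        zero_asthma_deaths(params)
        for s in "ABCDEF":
            params.utility_sets["base_case"].values[s] = dataclasses.replace(
                params.utility_sets["base_case"].values[s], value=1.0, high=1.0)
        params.config.annual_discount_rate = 0.0
        _, oc = engine.run_cohort(params, "UC", record_trace=False)
        assert oc.life_years == pytest.approx(55.0, abs=1e-9)
        assert oc.qalys == pytest.approx(55.0, abs=1e-9)

    def test_identity_dynamics_keep_cohort_in_place(self):
        alive = np.eye(6)[None, :, :]
        init = np.zeros(8)
        init[HealthState.D.value] = 1.0
        res = engine.batch_simulate(
            alive, p_EG=np.zeros(1), q_by_year=np.zeros(55),
            cf_by_year=np.zeros(55), utilities=np.ones((1, 6)),
            state_costs=np.zeros((1, 6)), rmtac_costs=None, init=init,
            n_cycles=660, discount_rate=0.0, record_trace=True)
        assert res["hospitalizations"][0] == 0.0
        np.testing.assert_array_equal(res["occupancy"][-1, 0], init)

    def test_life_years_match_life_table_when_asthma_deaths_off(self, params):
        zero_asthma_deaths(params)
        _, oc = engine.run_cohort(params, "UC", record_trace=False)
        le = params.life_table.life_expectancy(50)
        assert abs(oc.life_years - le) < 0.1

    def test_qalys_bounded_by_life_years(self, base_params):
        for arm in ("RMTAC_UC", "UC"):
            _, oc = engine.run_cohort(base_params, arm, record_trace=False)
            assert 0 < oc.qalys <= oc.life_years

    def test_hospitalization_entries_vs_occupancy_metric(self, params):
        _, entries = engine.run_cohort(params, "UC", record_trace=False)
        params.config.hospitalization_metric = "occupancy_months"
        _, months = engine.run_cohort(params, "UC", record_trace=False)
        # stays in F last several months, so occupancy-months exceed entries
        assert months.hospitalizations > entries.hospitalizations

    def test_entries_metric_matches_trace_flows(self, base_params):
        trace, oc = engine.run_cohort(base_params, "UC")
        into_F = trace.flows[:, :, F].sum() - trace.flows[:, F, F].sum()
        assert oc.hospitalizations == pytest.approx(into_F, abs=1e-9)


class TestMonotonicity:
    def test_higher_utility_raises_qalys(self, params):
        _, base = engine.run_cohort(params, "UC", record_trace=False)
        for s in ("C", "D"):
            params.utility_sets["base_case"].values[s] = dataclasses.replace(
                params.utility_sets["base_case"].values[s], value=0.60)
        _, up = engine.run_cohort(params, "UC", record_trace=False)
        assert up.qalys > base.qalys

    def test_higher_discount_lowers_discounted_outcomes(self, params):
        _, base = engine.run_cohort(params, "UC", record_trace=False)
        params.config.annual_discount_rate = 0.05
        _, disc = engine.run_cohort(params, "UC", record_trace=False)
        assert disc.qalys < base.qalys
        assert disc.total_cost < base.total_cost
        assert disc.life_years == pytest.approx(base.life_years)  # undiscounted

    def test_intervention_dominates_good_control_occupancy(self, base_params):
        tr_r, _ = engine.run_cohort(base_params, "RMTAC_UC")
        tr_u, _ = engine.run_cohort(base_params, "UC")
        good_r = tr_r.occupancy[1:, :2].sum(axis=1)
        good_u = tr_u.occupancy[1:, :2].sum(axis=1)
        assert np.all(good_r >= good_u - 1e-12)

    def test_half_cycle_correction_switch_runs(self, params):
        params.config.half_cycle_correction = True
        _, oc = engine.run_cohort(params, "UC", record_trace=False)
        assert 0 < oc.qalys < oc.life_years
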