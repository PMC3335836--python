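"""Markov extrapolation: transition estimation, scenario adjustment,
background-mortality blending, cohort propagation and pay-offs."""

import warnings

import numpy as np
import pandas as pd
import pytest

from artcea.cohort import CYCLE_YEARS, CohortParams, generate_cohort
from artcea.costing import ScenarioSpec
from artcea.markov import (
    ALIVE_STATES,
    ARM_INDEX,
    DEAD_STATE,
    MARKOV_STATES,
    N_STATES,
    LifeTable,
    TransitionMatrix,
    apply_scenario,
    blend_background_mortality,
    estimate_payoffs,
    estimate_transition_matrix,
    estimate_transitions,
    initial_occupancy,
    run_cohort,
    state_index,
)


def _random_valid_matrix(rng) -> TransitionMatrix:
    p = np.eye(N_STATES)
    for s in ALIVE_STATES:
        allowed = list(range(N_STATES)) if s < 3 else [3, 4, 5, 6]
        row = np.zeros(N_STATES)
        row[allowed] = rng.dirichlet(np.ones(len(allowed)))
        p[s] = row
    return TransitionMatrix("LCM", p)


class TestTransitionEstimation:
    def test_stay_put_sequences_give_identity_rows(self):
        frm = np.repeat(np.arange(6), 50)
        to = frm.copy()
        tm = estimate_transition_matrix(frm, to)
        assert np.allclose(tm.p, np.eye(N_STATES))

    def test_unoccupied_state_warns_and_stays_identity(self):
        with pytest.warns(UserWarning, match="unoccupied"):
            tm = estimate_transition_matrix(np.array([0, 0]), np.array([0, 6]))
        assert tm.p[5, 5] == 1.0

    def test_cohort_estimates_are_valid_matrices(self, full_cohort):
        for arm in ("LCM", "CDM"):
            tm = estimate_transitions(full_cohort, arm)
            assert np.allclose(tm.p.sum(axis=1), 1.0, atol=1e-12)
            assert tm.p[DEAD_STATE, DEAD_STATE] == 1.0
            assert np.all(tm.p[np.ix_([3, 4, 5], [0, 1, 2])] == 0.0)

    def test_switch_rate_pattern_matches_monitoring_strategies(self, full_cohort):
        """The monitored arm switches less from high CD4 and far more
        from low CD4 than the clinically monitored arm."""
        tm_l = estimate_transitions(full_cohort, "LCM")
        tm_c = estimate_transitions(full_cohort, "CDM")
        sl = [3, 4, 5]
        assert tm_l.p[2, sl].sum() < tm_c.p[2, sl].sum()
        assert tm_l.p[0, sl].sum() > tm_c.p[0, sl].sum()


class TestScenario:
    def test_optimistic_is_identity(self, full_cohort):
        tm_l = estimate_transitions(full_cohort, "LCM")
        tm_c = estimate_transitions(full_cohort, "CDM")
        a, b = apply_scenario(tm_l, tm_c, "optimistic")
        assert np.allclose(a.p, tm_l.p) and np.allclose(b.p, tm_c.p)

    def test_conservative_equalises_high_cd4_switching(self, full_cohort):
        tm_l = estimate_transitions(full_cohort, "LCM")
        tm_c = estimate_transitions(full_cohort, "CDM")
        _, adj = apply_scenario(tm_l, tm_c, "conservative")
        sl = [3, 4, 5]
        assert np.allclose(adj.p[2, sl], tm_l.p[2, sl])
        assert np.allclose(adj.p.sum(axis=1), 1.0, atol=1e-12)

    def test_unknown_scenario_rejected(self, full_cohort):
        tm = estimate_transitions(full_cohort, "LCM")
        with pytest.raises(ValueError):
            apply_scenario(tm, tm, "pessimistic")


class TestBackgroundMortality:
    def test_zero_background_leaves_matrix_unchanged(self):
        rng = np.random.default_rng(0)
        tm = _random_valid_matrix(rng)
        lt = LifeTable(pd.DataFrame({"age": range(15, 100), "annual_q": 0.0}))
        assert np.allclose(blend_background_mortality(tm, lt, 40.0).p, tm.p)

    def test_pure_background_closed_form(self):
        p = np.eye(N_STATES)
        tm = TransitionMatrix("LCM", p)
        lt = LifeTable(pd.DataFrame({"age": range(15, 100), "annual_q": 0.04}))
        blended = blend_background_mortality(tm, lt, 40.0)
        expected = 1.0 - 0.96**CYCLE_YEARS
        for s in ALIVE_STATES:
            assert blended.p[s, DEAD_STATE] == pytest.approx(expected)

    def test_combined_death_dominates_components(self):
        rng = np.random.default_rng(3)
        lt = LifeTable(pd.DataFrame({"age": range(15, 100), "annual_q": 0.05}))
        for _ in range(5):
            tm = _random_valid_matrix(rng)
            blended = blend_background_mortality(tm, lt, 55.0)
            q = lt.cycle_q(55.0)
            for s in ALIVE_STATES:
                assert blended.p[s, DEAD_STATE] >= max(tm.p[s, DEAD_STATE], q) - 1e-12
            assert np.allclose(blended.p.sum(axis=1), 1.0, atol=1e-12)

    def test_life_table_validation(self):
        with pytest.raises(ValueError, match="contiguous"):
            LifeTable(pd.DataFrame({"age": [20, 22], "annual_q": [0.01, 0.01]}))
        lt = LifeTable.default()
        with pytest.warns(UserWarning, match="carried forward"):
            lt.annual_q(130.0)


class TestRunCohort:
    def test_identity_matrix_zero_payoffs(self):
        occ = np.zeros(N_STATES)
        occ[2] = 1.0
        tm = TransitionMatrix("LCM", np.eye(N_STATES))
        tr = run_cohort(occ, tm, np.zeros(6), np.zeros(6), 10, 6.0)
        assert np.allclose(tr["disc_cost"], 0.0)
        assert np.allclose(tr["occ_FL_gt200"], 1.0)

    def test_mass_conserved_under_random_matrix(self):
        rng = np.random.default_rng(7)
        tm = _random_valid_matrix(rng)
        occ = np.zeros(N_STATES)
        occ[:6] = 1.0 / 6.0
        tr = run_cohort(occ, tm, np.ones(6), np.ones(6) * CYCLE_YEARS * 0.9, 120, 6.0)
        occ_cols = [f"occ_{s}" for s in MARKOV_STATES]
        assert np.allclose(tr[occ_cols].sum(axis=1), 1.0, atol=1e-10)
        assert (np.diff(tr["prop_dead"]) >= -1e-12).all()

    def test_geometric_series_closed_form(self):
        """Single alive state dying at 10% per cycle, undiscounted:
        expected life-years follow the geometric series."""
        p = np.eye(N_STATES)
        p[2, 2], p[2, DEAD_STATE] = 0.9, 0.1
        tm = TransitionMatrix("LCM", p)
        occ = np.zeros(N_STATES)
        occ[2] = 1.0
        qaly = np.zeros(6)
        qaly[2] = CYCLE_YEARS
        n = 200
        tr = run_cohort(occ, tm, np.zeros(6), qaly, n, 6.0, discount_rate=0.0)
        expected = CYCLE_YEARS * (1 - 0.9**n) / 0.1
        assert tr["disc_qaly"].sum() == pytest.approx(expected, rel=1e-10)

    def test_unnormalised_occupancy_rejected(self):
        tm = TransitionMatrix("LCM", np.eye(N_STATES))
        with pytest.raises(ValueError):
            run_cohort(np.full(N_STATES, 0.5), tm, np.zeros(6), np.zeros(6), 5, 6.0)


class TestPayoffs:
    def test_routine_monitoring_only_in_lcm(self, full_cohort, unit_costs):
        payoffs = estimate_payoffs(full_cohort, unit_costs)
        assert np.all(payoffs.cd4_tests[ARM_INDEX["LCM"]] == 1.0)
        assert np.all(payoffs.cd4_tests[ARM_INDEX["CDM"]] == 0.0)
        # LCM deterministic cycle cost exceeds CDM's by the monitoring prices
        gap = payoffs.det_cost[0] - payoffs.det_cost[1]
        assert np.all(gap > 0)
        assert np.allclose(gap, gap[0])  # same monitoring add-on in every state

    def test_no_cd4_monitoring_scenario_removes_tests(self, full_cohort, unit_costs):
        payoffs = estimate_payoffs(full_cohort, unit_costs, ScenarioSpec(cd4_monitoring="never"))
        assert np.all(payoffs.cd4_tests == 0.0)
        assert np.allclose(payoffs.det_cost[0], payoffs.det_cost[1])

    def test_qaly_payoffs_within_cycle_bounds(self, full_cohort, unit_costs):
        payoffs = estimate_payoffs(full_cohort, unit_costs)
        q = payoffs.qaly()
        assert np.all(q >= 0) and np.all(q <= CYCLE_YEARS + 1e-12)

    def test_empty_stratum_borrows_pooled(self, unit_costs):
        params = CohortParams(n_per_arm=(40, 40), seed=2)
        cohort = generate_cohort(params)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            estimate_payoffs(cohort, unit_costs)
        assert any("borrowing pooled" in str(w.message) for w in rec)

    def test_second_line_drug_cost_exceeds_first_line(self, full_cohort, unit_costs):
        payoffs = estimate_payoffs(full_cohort, unit_costs)
        for ai in (0, 1):
            assert payoffs.det_cost[ai, 3:].mean() > payoffs.det_cost[ai, :3].mean()


def test_initial_occupancy_is_distribution(full_cohort):
    for arm in ("LCM", "CDM"):
        occ = initial_occupancy(full_cohort, arm)
        assert occ.sum() == pytest.approx(1.0)
        assert occ[DEAD_STATE] == 0.0


def test_state_index_layout():
    assert state_index(False, 0) == 0
    assert state_index(True, 2) == 5
    assert MARKOV_STATES[DEAD_STATE] == "DEAD"
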