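"""Within-trial CEA: survival areas, QALYs, discounting, the
censoring-adjusted mean estimator, ICER quadrants and the bootstrap."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.utils import restricted_mean_survival_time

from artcea.cohort import CYCLE_COLUMNS, CYCLE_YEARS, DAYS_PER_YEAR, Cohort, CohortParams, generate_cohort
from artcea.costing import cost_cycles
from artcea.trial import (
    DOMINANT,
    DOMINATED,
    UtilitySet,
    _km_rmst,
    arm_flow_matrices,
    bootstrap_ci,
    compute_qalys,
    discount,
    discount_factors,
    icer,
    km_area_survival,
    lin_adjusted_mean_cost,
    trial_cea,
)


def _tiny_cohort(lcm, cdm):
    """Hand-built cohort from (death_day, censor_day) tuples per arm."""
    rows, cycs = [], []
    pid = 0
    for arm, specs in (("LCM", lcm), ("CDM", cdm)):
        for death, censor in specs:
            rows.append(
                {"id": pid, "arm": arm, "centre": "Entebbe", "age_at_entry": 37.0,
                 "death_day": death, "censor_day": censor, "dropped_out": False}
            )
            end = death if death is not None and not np.isnan(death) else censor
            k = 0
            while k * 84.0 < end:
                frac = min(1.0, (end - k * 84.0) / 84.0)
                base = {c: 0 for c in CYCLE_COLUMNS}
                base.update({"id": pid, "cycle": k, "t_start_day": k * 84.0, "fraction": frac,
                             "cd4": 150.0, "art_line": "first", "health_state": 1,
                             "who34_ongoing": 0})
                cycs.append(base)
                k += 1
            pid += 1
    return Cohort(
        patients=pd.DataFrame(rows),
        cycles=pd.DataFrame(cycs, columns=list(CYCLE_COLUMNS)),
    )


class TestSurvival:
    def test_single_death_is_direct_integral(self):
        cohort = _tiny_cohort([(100.0, np.nan)], [(None, 200.0)])
        out = km_area_survival(cohort, horizon_days=200.0)
        assert out["LCM"] == pytest.approx(100.0 / DAYS_PER_YEAR)
        assert out["CDM"] == pytest.approx(200.0 / DAYS_PER_YEAR)
        assert out["difference"] == pytest.approx(-100.0 / DAYS_PER_YEAR)

    def test_no_deaths_gives_zero_difference(self):
        cohort = _tiny_cohort([(None, 300.0)] * 3, [(None, 300.0)] * 3)
        out = km_area_survival(cohort, horizon_days=300.0)
        assert out["LCM"] == pytest.approx(300.0 / DAYS_PER_YEAR)
        assert out["difference"] == pytest.approx(0.0)

    def test_fast_rmst_matches_lifelines(self):
        rng = np.random.default_rng(42)
        T = rng.exponential(500, 200)
        E = (rng.random(200) < 0.7).astype(int)
        T = np.where(E == 1, T, T * rng.random(200))
        kmf = KaplanMeierFitter().fit(T, E)
        expected = float(restricted_mean_survival_time(kmf, t=600.0))
        assert _km_rmst(T, E, 600.0) == pytest.approx(expected, rel=1e-10)

    def test_horizon_beyond_data_errors(self):
        cohort = _tiny_cohort([(None, 300.0)], [(None, 300.0)])
        with pytest.raises(ValueError):
            km_area_survival(cohort, horizon_days=301.0)


class TestQalys:
    def test_identity_weight(self, small_cohort):
        rec = small_cohort.record(int(small_cohort.patients["id"].iloc[0]))
        rec.cycles["health_state"] = 1
        u = UtilitySet()
        t_alive = rec.cycles["fraction"].sum() * CYCLE_YEARS
        assert compute_qalys(rec, u) == pytest.approx(t_alive)

    def test_two_cycle_arithmetic(self):
        cohort = _tiny_cohort([(None, 168.0)], [(None, 168.0)])
        rec = cohort.record(0)
        rec.cycles.loc[1, "health_state"] = 3
        u = UtilitySet(u2=0.85, u3=0.60, u4=0.40)
        assert compute_qalys(rec, u) == pytest.approx(CYCLE_YEARS * (1.0 + 0.60))

    def test_general_anchor_is_exact_ratio(self, small_cohort):
        u = UtilitySet()
        for pid in small_cohort.patients["id"].iloc[:20]:
            rec = small_cohort.record(int(pid))
            p = compute_qalys(rec, u, "patient")
            g = compute_qalys(rec, u, "general")
            assert g == pytest.approx(0.81 * p, rel=1e-12)

    def test_qalys_never_exceed_life_years(self, small_cohort):
        u = UtilitySet()
        for pid in small_cohort.patients["id"].iloc[:50]:
            rec = small_cohort.record(int(pid))
            ly = rec.cycles["fraction"].sum() * CYCLE_YEARS
            assert compute_qalys(rec, u) <= ly + 1e-12

    def test_utility_ordering_enforced(self):
        with pytest.raises(ValueError):
            UtilitySet(u2=0.5, u3=0.8, u4=0.4)


class TestDiscounting:
    def test_zero_rate_is_raw_sum(self):
        assert discount([100, 50], [0.5, 3.0], rate=0.0) == pytest.approx(150.0)

    def test_closed_form_after_year_one(self):
        # $100 at exactly two years: one year of discounting at 3%
        assert discount([100.0], [2.0], 0.03) == pytest.approx(100.0 / 1.03)

    def test_first_year_undiscounted(self):
        t = np.linspace(0.05, 0.95, 10)
        assert discount(np.full(10, 10.0), t, 0.03) == pytest.approx(100.0)

    def test_discounted_never_exceeds_undiscounted(self):
        rng = np.random.default_rng(0)
        amounts = rng.gamma(2.0, 50.0, 100)
        t = rng.uniform(0, 6, 100)
        assert discount(amounts, t, 0.03) <= amounts.sum()
        assert discount(amounts, t, 0.0) == pytest.approx(amounts.sum())

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factors([1.0], rate=-0.01)


class TestLinEstimator:
    def test_hand_worked_three_patients(self):
        """One complete, one dying, one censored mid-way; the weighted
        interval sum is worked out by hand."""
        C = np.array([[10.0, 10.0, 10.0], [10.0, 5.0, 0.0], [10.0, 4.0, 0.0]])
        d = np.array([99, 1, 99])
        c = np.array([99, 99, 1])
        # interval 0: S=1, mean 10 -> 10
        # interval 1: S=1 (no deaths yet), mean (10+5+4)/3 -> 19/3
        # interval 2: S=2/3 after the death, only the survivor at risk -> (2/3)*10
        expected = 10.0 + 19.0 / 3.0 + (2.0 / 3.0) * 10.0
        assert lin_adjusted_mean_cost(C, d, c) == pytest.approx(expected)

    def test_reduces_to_naive_mean_without_censoring(self, unit_costs):
        params = CohortParams(n_per_arm=(120, 120), dropout_rate=0.0, seed=9)
        cohort = generate_cohort(params)
        per_cycle = cost_cycles(cohort, unit_costs)
        mats = arm_flow_matrices(cohort, per_cycle[["id", "cycle", "total"]], ["total"], 0.0)
        for arm in ("LCM", "CDM"):
            d = mats[arm]
            est = lin_adjusted_mean_cost(d["mats"]["total"], d["death_int"], d["censor_int"])
            naive = d["mats"]["total"].sum(axis=1).mean()
            assert est == pytest.approx(naive, rel=1e-12)

    def test_empty_risk_set_with_remaining_flows_errors(self):
        C = np.array([[5.0, 5.0], [5.0, 5.0]])
        d = np.array([0, 0])
        c = np.array([9, 9])
        with pytest.raises(ValueError, match="under observation"):
            lin_adjusted_mean_cost(C, d, c)


class TestIcer:
    def test_published_arithmetic(self):
        res = icer(748.0, 0.096)
        assert res.icer == pytest.approx(748.0 / 0.096)
        assert res.quadrant == "NE"

    def test_quadrants_are_exhaustive(self):
        assert icer(100.0, 0.0).icer == DOMINATED
        assert icer(-1.0, 0.1).icer == DOMINANT
        sw = icer(-10.0, -0.1)
        assert sw.quadrant == "SW"
        assert sw.icer == pytest.approx(100.0)


class TestBootstrap:
    def test_degenerate_data_gives_point_interval(self):
        data = {"LCM": np.full(40, 5.0), "CDM": np.full(40, 5.0)}
        lo, hi, _ = bootstrap_ci(data, lambda d: d["LCM"].mean() - d["CDM"].mean(), B=200, seed=0)
        assert lo == hi == 0.0

    def test_seeded_repeatability(self):
        rng = np.random.default_rng(1)
        data = {"LCM": rng.gamma(2, 100, 80), "CDM": rng.gamma(2, 90, 80)}
        stat = lambda d: d["LCM"].mean() - d["CDM"].mean()  # noqa: E731
        a = bootstrap_ci(data, stat, B=300, seed=5)
        b = bootstrap_ci(data, stat, B=300, seed=5)
        assert a[0] == b[0] and a[1] == b[1]

    def test_minimum_replicates_enforced(self):
        with pytest.raises(ValueError):
            bootstrap_ci({"LCM": np.ones(5), "CDM": np.ones(5)}, lambda d: 0.0, B=50)


def test_trial_cea_table_is_consistent(small_cohort, unit_costs):
    per_cycle = cost_cycles(small_cohort, unit_costs)
    res = trial_cea(small_cohort, per_cycle, B=120, seed=2)
    t = res.table.set_index("outcome")
    # general-anchor QALY difference is exactly 0.81 x patient-anchor
    assert t.loc["qalys_general_values", "difference"] == pytest.approx(
        0.81 * t.loc["qalys_patient_values", "difference"]
    )
    # adjusted (discounted) totals below unadjusted in both arms
    assert t.loc["total_cost_adjusted", "lcm"] <= t.loc["total_cost_unadjusted", "lcm"] * 1.02
    r = res.results["icer_adjusted_qaly_patient"]
    if isinstance(r.icer, float):
        assert r.icer == pytest.approx(r.delta_cost / r.delta_effect)


class TestHypothesisProperties:
    from hypothesis import given, settings, strategies as st

    @given(
        dc=st.floats(-1e6, 1e6, allow_nan=False),
        de=st.floats(-10, 10, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_icer_quadrants_exhaustive_and_exclusive(self, dc, de):
        res = icer(dc, de)
        assert res.quadrant in ("NE", "NW", "SE", "SW")
        if res.quadrant == "NE":
            assert res.icer == pytest.approx(dc / de)
        elif res.quadrant == "NW":
            assert res.icer == DOMINATED
        elif res.quadrant == "SE":
            assert res.icer == DOMINANT

    @given(
        st.lists(st.tuples(st.floats(0, 1e4), st.floats(0, 8)), min_size=1, max_size=40),
        st.floats(0, 0.2),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_discounted_total_bounded_by_undiscounted(self, flows, rate):
        amounts = np.array([a for a, _ in flows])
        t = np.array([tt for _, tt in flows])
        pv = discount(amounts, t, rate)
        assert pv <= amounts.sum() + 1e-9
        if rate == 0.0 or (t <= 1.0).all():
            assert pv == pytest.approx(amounts.sum())
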