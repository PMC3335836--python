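"""Markov cohort extrapolation of costs and QALYs beyond the trial.

Seven states: first-line or second-line ART crossed with CD4 bands
<100, 100-200 and >200 cells/mm^3, plus an absorbing DEAD state.  Cycle
length is 12 weeks (84 days; a year is 52.18 weeks).  Arm-specific
transition probabilities are maximum-likelihood multinomial estimates
from consecutive 12-week observations in the last two trial years.
State pay-offs combine deterministic components under full compliance
with the follow-up schedule (one routine CD4 test per cycle in the
laboratory-monitored arm, one clinic visit, 84 days of line-appropriate
ART) with observed per-cycle means of random events (hospitalisation,
clinically driven investigations, cotrimoxazole/antimalarial use)
matched to the latest CD4 band.  Background mortality from an
HIV-excluded counterfactual life table is blended into every cycle's
matrix as a competing risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from artcea.cohort import (
    CENTRES,
    CYCLE_DAYS,
    CYCLE_YEARS,
    DAYS_PER_YEAR,
    Cohort,
    cd4_band,
)
from artcea.costing import ScenarioSpec, UnitCostTable, cd4_price_per_centre
from artcea.trial import UtilitySet

MARKOV_STATES = (
    "FL_lt100",
    "FL_100to200",
    "FL_gt200",
    "SL_lt100",
    "SL_100to200",
    "SL_gt200",
    "DEAD",
)
N_STATES = 7
DEAD_STATE = 6
ALIVE_STATES = tuple(range(6))
FL_STATES = (0, 1, 2)
SL_STATES = (3, 4, 5)


def state_index(on_second_line, band) -> np.ndarray:
    """Markov state index from treatment line and CD4 band."""
    return np.asarray(band) + 3 * np.asarray(on_second_line).astype(int)


@dataclass
class TransitionMatrix:
    """Arm-specific row-stochastic 7x7 matrix per 12-week cycle, with the
    transition counts it was estimated from (PSA concentration
    parameters)."""

    arm: str
    p: np.ndarray
    counts: Optional[np.ndarray] = None

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.p.shape != (N_STATES, N_STATES):
            raise ValueError("transition matrix must be 7x7")
        if np.any(self.p < -1e-15) or np.any(self.p > 1 + 1e-12):
            raise ValueError("transition probabilities outside [0, 1]")
        if np.max(np.abs(self.p.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("rows must sum to 1")
        dead = np.zeros(N_STATES)
        dead[DEAD_STATE] = 1.0
        if not np.allclose(self.p[DEAD_STATE], dead, atol=1e-12):
            raise ValueError("DEAD must be absorbing")
        if np.any(self.p[np.ix_(SL_STATES, FL_STATES)] > 1e-15):
            raise ValueError("second-line to first-line transitions are not allowed")

    def copy(self) -> "TransitionMatrix":
        return TransitionMatrix(self.arm, self.p.copy(), None if self.counts is None else self.counts.copy())


def _transition_pairs(cohort: Cohort, arm: str, window_years) -> pd.DataFrame:
    pat = cohort.patients
    ids = pat.loc[pat["arm"] == arm, "id"]
    cyc = cohort.cycles[cohort.cycles["id"].isin(ids)].copy()
    cyc["state"] = state_index(cyc["art_line"].to_numpy() == "second", cd4_band(cyc["cd4"]))
    nxt = cyc[["id", "cycle", "state"]].copy()
    nxt["cycle"] -= 1
    pairs = cyc[["id", "cycle", "state", "t_start_day"]].merge(
        nxt, on=["id", "cycle"], suffixes=("", "_next"), how="left"
    )
    death_cycle = np.floor(pat.set_index("id")["death_day"] / CYCLE_DAYS)
    dc = death_cycle.reindex(pairs["id"]).to_numpy()
    # a death in the following interval is a transition to DEAD; pairs with
    # no successor and no death (censoring) are dropped
    to_dead = dc == pairs["cycle"].to_numpy() + 1
    pairs.loc[to_dead, "state_next"] = DEAD_STATE
    t_years = pairs["t_start_day"].to_numpy() / DAYS_PER_YEAR
    lo, hi = window_years
    keep = pairs["state_next"].notna() & (t_years >= lo) & (t_years < hi)
    return pairs.loc[keep, ["state", "state_next"]].astype(int)


def estimate_transition_matrix(pairs_from: np.ndarray, pairs_to: np.ndarray, arm: str = "") -> TransitionMatrix:
    """Multinomial MLE from (from, to) state pairs; unoccupied alive rows
    become identity rows with a warning."""
    counts = np.zeros((N_STATES, N_STATES))
    np.add.at(counts, (pairs_from, pairs_to), 1.0)
    p = np.eye(N_STATES)
    rowsum = counts.sum(axis=1)
    for s in ALIVE_STATES:
        if rowsum[s] > 0:
            p[s] = counts[s] / rowsum[s]
        else:
            warnings.warn(f"state {MARKOV_STATES[s]} unoccupied; identity row used", stacklevel=2)
    return TransitionMatrix(arm=arm, p=p, counts=counts)


def estimate_transitions(cohort: Cohort, arm: str, window_years=(4.0, 6.0)) -> TransitionMatrix:
    """Estimate an arm's 12-week transition matrix from consecutive cycle
    observations whose source cycle starts within ``window_years``
    (default: the last two trial years)."""
    pairs = _transition_pairs(cohort, arm, window_years)
    if pairs.empty:
        raise ValueError(f"no observed transitions for arm {arm} in window {window_years}")
    return estimate_transition_matrix(pairs["state"].to_numpy(), pairs["state_next"].to_numpy(), arm)


def apply_scenario(tm_lcm: TransitionMatrix, tm_cdm: TransitionMatrix, scenario: str):
    """Switch-rate scenario for the extrapolation.

    ``optimistic`` keeps the arm-specific matrices (the monitored arm's
    lower switch rate at high CD4 persists).  ``conservative`` assigns
    the CDM arm the LCM probability of switching to second line from
    FL_>200, renormalising the difference into the stay probability.
    """
    if scenario not in ("optimistic", "conservative"):
        raise ValueError("scenario must be 'optimistic' or 'conservative'")
    if scenario == "optimistic":
        return tm_lcm.copy(), tm_cdm.copy()
    new_cdm = tm_cdm.copy()
    row = new_cdm.p[2].copy()  # FL_gt200
    lcm_row = tm_lcm.p[2]
    delta = row[list(SL_STATES)].sum() - lcm_row[list(SL_STATES)].sum()
    row[list(SL_STATES)] = lcm_row[list(SL_STATES)]
    row[2] += delta
    if row[2] < 0:
        raise ValueError("conservative renormalisation produced a negative stay probability")
    new_cdm.p[2] = row
    new_cdm.validate()
    return tm_lcm.copy(), new_cdm


@dataclass
class LifeTable:
    """Age-indexed annual background death probabilities (an HIV-excluded
    counterfactual schedule)."""

    frame: pd.DataFrame

    def __post_init__(self):
        if not {"age", "annual_q"}.issubset(self.frame.columns):
            raise ValueError("life table needs columns age, annual_q")
        ages = self.frame["age"].to_numpy()
        if np.any(np.diff(ages) != 1):
            raise ValueError("life-table ages must be contiguous")
        q = self.frame["annual_q"].to_numpy(float)
        if np.any((q < 0) | (q > 1)):
            raise ValueError("annual probabilities must lie in [0, 1]")
        self._ages = ages
        self._q = q

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path))

    @classmethod
    def default(cls) -> "LifeTable":
        """Packaged synthetic East-African background schedule (a stand-in
        constructed from a Gompertz-Makeham fit; see data file)."""
        with resources.files("artcea.data").joinpath("background_mortality_synthetic.csv").open() as f:
            return cls(pd.read_csv(f))

    def annual_q(self, age: float) -> float:
        if age > self._ages[-1]:
            warnings.warn("age beyond life table; last rate carried forward", stacklevel=2)
            return float(self._q[-1])
        if age < self._ages[0]:
            raise ValueError("age below life-table range")
        return float(self._q[int(np.floor(age)) - int(self._ages[0])])

    def cycle_q(self, age: float) -> float:
        """Per-12-week-cycle background death probability."""
        return 1.0 - (1.0 - self.annual_q(age)) ** CYCLE_YEARS


def blend_background_mortality(tm: TransitionMatrix, life_table: LifeTable, cohort_age: float) -> TransitionMatrix:
    """Combine state-specific death with age-specific background death as
    independent competing risks; surviving mass is rescaled
    proportionally so rows remain stochastic."""
    q = life_table.cycle_q(cohort_age)
    p = tm.p.copy()
    for s in ALIVE_STATES:
        p_dead = p[s, DEAD_STATE]
        combined = 1.0 - (1.0 - p_dead) * (1.0 - q)
        alive_mass = 1.0 - p_dead
        if alive_mass > 0:
            p[s, :DEAD_STATE] *= (1.0 - combined) / alive_mass
        p[s, DEAD_STATE] = combined
    return TransitionMatrix(tm.arm, p, tm.counts)


@dataclass
class PayoffTable:
    """Per-cycle cost and QALY pay-offs per arm and alive state.

    ``det_cost`` holds the compliance-schedule components (ART, clinic
    visit, routine monitoring), ``stoch_mean``/``stoch_se`` the observed
    means of random events, ``state_mix`` the health-state composition
    of each stratum (used to recompute QALY pay-offs when utilities are
    redrawn), ``cd4_tests`` the routine CD4 tests costed per cycle.
    Arrays are indexed [arm][state] with arm 0 = LCM, 1 = CDM.
    """

    det_cost: np.ndarray
    stoch_mean: np.ndarray
    stoch_se: np.ndarray
    state_mix: np.ndarray  # (2, 6, 4)
    cd4_tests: np.ndarray
    cd4_price: np.ndarray  # price applied per test, per arm
    utilities: UtilitySet = field(default_factory=UtilitySet)

    @property
    def cost(self) -> np.ndarray:
        return self.det_cost + self.stoch_mean

    def qaly(self, utilities: Optional[UtilitySet] = None) -> np.ndarray:
        u = (utilities or self.utilities).as_array()
        q = CYCLE_YEARS * (self.state_mix @ u)
        if np.any(q < 0) or np.any(q > CYCLE_YEARS + 1e-12):
            raise ValueError("QALY pay-off per cycle outside [0, cycle length]")
        return q

    def validate(self) -> None:
        if np.any(self.cost < 0):
            raise ValueError("pay-off costs must be non-negative")
        self.qaly()


ARM_INDEX = {"LCM": 0, "CDM": 1}


def estimate_payoffs(
    cohort: Cohort,
    costs: UnitCostTable,
    scenario: Optional[ScenarioSpec] = None,
    utilities: Optional[UtilitySet] = None,
    concomitant_share: float = 0.8,
) -> PayoffTable:
    """Estimate per-cycle pay-offs by arm and Markov state.

    Deterministic components assume full compliance with the follow-up
    schedule: 84 days of line-appropriate ART, one clinic visit, and —
    for the CD4-monitored arm when the scenario retains CD4 monitoring —
    one routine CD4 test (plus toxicity panels if monitored).  Random
    components (hospital nights, clinically driven investigations,
    health-centre visits, and the cotrimoxazole/antimalarial share of
    concomitant medication) are observed per-cycle means matched to the
    latest CD4 band and arm; empty strata borrow the pooled mean with a
    warning.
    """
    scenario = scenario or ScenarioSpec()
    utilities = utilities or UtilitySet()
    pat = cohort.patients.set_index("id")
    cyc = cohort.cycles
    arm_of_row = pat["arm"].reindex(cyc["id"]).to_numpy()
    centre_share = (
        cohort.patients["centre"].value_counts(normalize=True).reindex(list(CENTRES)).fillna(0.0).to_numpy()
    )

    visit_price = float(costs.centre_prices("clinic_visit") @ centre_share)
    hc_price = float(costs.centre_prices("health_centre_visit") @ centre_share)
    cd4_price = float(cd4_price_per_centre(costs, scenario) @ centre_share)
    haem_price = float(costs.centre_prices("haematology_panel", scenario.lab_set) @ centre_share)
    bio_price = float(costs.centre_prices("biochemistry_panel", scenario.lab_set) @ centre_share)
    perdiem = costs.price("hospital_per_diem")
    diag_price = costs.price("other_diagnostic")
    fl_daily = costs.daily_drug_cost("first", scenario.first_line_mix, scenario.fl_set)
    sl_daily = costs.daily_drug_cost("second", scenario.second_line_mix, scenario.sl_set)

    det = np.zeros((2, 6))
    tests = np.zeros((2, 6))
    for arm, ai in ARM_INDEX.items():
        for s in ALIVE_STATES:
            daily = fl_daily if s in FL_STATES else sl_daily
            c = CYCLE_DAYS * daily + visit_price
            if arm == "LCM" and scenario.cd4_monitoring != "never":
                tests[ai, s] = 1.0
                c += cd4_price
                if scenario.toxicity_monitoring:
                    c += haem_price + bio_price
            det[ai, s] = c

    state = state_index(cyc["art_line"].to_numpy() == "second", cd4_band(cyc["cd4"]))
    stoch_value = (
        cyc["hospital_nights"].to_numpy() * perdiem
        + cyc["diagnostic_investigations"].to_numpy() * diag_price
        + cyc["health_centre_visits"].to_numpy() * hc_price
    )
    flat = np.where(arm_of_row == "LCM", costs.price("concomitant_flat_lcm"), costs.price("concomitant_flat_cdm"))
    person_cycles = cyc.groupby("id")["fraction"].transform("sum").to_numpy()
    stoch_value = stoch_value + concomitant_share * flat * cyc["fraction"].to_numpy() / person_cycles

    stoch_mean = np.zeros((2, 6))
    stoch_se = np.zeros((2, 6))
    mix = np.zeros((2, 6, 4))
    frac = cyc["fraction"].to_numpy()
    hstate = cyc["health_state"].to_numpy(int)
    for arm, ai in ARM_INDEX.items():
        sel_arm = arm_of_row == arm
        for s in ALIVE_STATES:
            sel = sel_arm & (state == s)
            n = int(sel.sum())
            if n == 0:
                pooled = state == s
                if pooled.sum() == 0:
                    raise ValueError(f"state {MARKOV_STATES[s]} never observed")
                warnings.warn(
                    f"empty stratum {arm}/{MARKOV_STATES[s]}; borrowing pooled arms", stacklevel=2
                )
                sel = pooled
                n = int(sel.sum())
            w = frac[sel]
            v = stoch_value[sel]
            stoch_mean[ai, s] = v.sum() / w.sum()
            stoch_se[ai, s] = v.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
            for h in range(4):
                mix[ai, s, h] = np.sum(w * (hstate[sel] == h + 1)) / w.sum()

    table = PayoffTable(
        det_cost=det,
        stoch_mean=stoch_mean,
        stoch_se=stoch_se,
        state_mix=mix,
        cd4_tests=tests,
        cd4_price=np.array([cd4_price if tests[0].any() else 0.0, 0.0]),
        utilities=utilities,
    )
    table.validate()
    return table


def initial_occupancy(cohort: Cohort, arm: str) -> np.ndarray:
    """Empirical (line, CD4-band) distribution of the arm's survivors at
    their last trial visit, as a 7-vector with zero DEAD mass."""
    pat = cohort.patients
    alive_ids = pat.loc[(pat["arm"] == arm) & pat["death_day"].isna(), "id"]
    cyc = cohort.cycles[cohort.cycles["id"].isin(alive_ids)]
    last = cyc.loc[cyc.groupby("id")["cycle"].idxmax()]
    states = state_index(last["art_line"].to_numpy() == "second", cd4_band(last["cd4"]))
    occ = np.zeros(N_STATES)
    for s in range(N_STATES):
        occ[s] = np.mean(states == s)
    return occ


def run_cohort(
    initial_occ: np.ndarray,
    tm: TransitionMatrix,
    payoff_cost: np.ndarray,
    payoff_qaly: np.ndarray,
    n_cycles: int,
    t0_years: float,
    discount_rate: float = 0.03,
    life_table: Optional[LifeTable] = None,
    age0: Optional[float] = None,
    payoff_tests: Optional[np.ndarray] = None,
    test_price: float = 0.0,
) -> pd.DataFrame:
    """Propagate state occupancy through ``n_cycles`` 12-week cycles from
    ``t0_years`` after ART initiation, accruing discounted per-cycle
    pay-offs over the alive states (occupancy evaluated at cycle start).

    Returns a per-cycle trace with occupancies, the proportion on
    second-line therapy, the proportion dead, and discounted cost, QALY
    and routine-CD4-test accruals.  Occupancy mass is checked to 1e-10
    every cycle.
    """
    occ = np.asarray(initial_occ, dtype=float)
    if abs(occ.sum() - 1.0) > 1e-9:
        raise ValueError("initial occupancy must sum to 1")
    payoff_cost = np.asarray(payoff_cost, float)
    payoff_qaly = np.asarray(payoff_qaly, float)
    tests = np.zeros(6) if payoff_tests is None else np.asarray(payoff_tests, float)
    rows = []
    from artcea.trial import discount_factors  # local import to avoid cycle

    for j in range(n_cycles):
        t = t0_years + j * CYCLE_YEARS
        if life_table is not None:
            p = blend_background_mortality(tm, life_table, (age0 or 37.0) + t).p
        else:
            p = tm.p
        df = float(discount_factors(t + 0.5 * CYCLE_YEARS, discount_rate))
        alive = occ[:DEAD_STATE]
        rows.append(
            {
                "cycle": j,
                "t_years": t,
                "prop_second_line": float(alive[list(SL_STATES)].sum()),
                "prop_dead": float(occ[DEAD_STATE]),
                "disc_cost": float(alive @ payoff_cost) * df,
                "disc_qaly": float(alive @ payoff_qaly) * df,
                "disc_cd4_tests": float(alive @ tests) * df,
                "disc_cd4_cost": float(alive @ (tests * test_price)) * df,
                **{f"occ_{MARKOV_STATES[s]}": float(occ[s]) for s in range(N_STATES)},
            }
        )
        occ = occ @ p
        if abs(occ.sum() - 1.0) > 1e-10:
            raise ValueError("occupancy mass not conserved")
    return pd.DataFrame(rows)


@dataclass
class ExtrapolationResult:
    """Per-arm traces and cumulative discounted increments from trial end
    to the model horizon, plus the combined ICER trajectory."""

    traces: pd.DataFrame  # per arm per cycle
    delta_cost: float
    delta_qaly: float
    delta_cd4_tests: float
    icer_trajectory: pd.DataFrame
    trial_end_years: float
    total_delta_cost: float = np.nan  # trial + extrapolation
    total_delta_qaly: float = np.nan


def extrapolate(
    cohort: Cohort,
    costs: UnitCostTable,
    scenario: Optional[ScenarioSpec] = None,
    switch_scenario: str = "optimistic",
    utilities: Optional[UtilitySet] = None,
    life_table: Optional[LifeTable] = None,
    horizon_years: float = 25.0,
    trial_end_years: Optional[float] = None,
    discount_rate: float = 0.03,
    trial_delta_cost: float = 0.0,
    trial_delta_qaly: float = 0.0,
    transition_window=(4.0, 6.0),
) -> ExtrapolationResult:
    """Full extrapolation: estimate matrices and pay-offs from the
    cohort, apply the switch scenario, blend background mortality and
    run both arms to ``horizon_years`` after ART initiation."""
    utilities = utilities or UtilitySet()
    life_table = life_table or LifeTable.default()
    tm_l = estimate_transitions(cohort, "LCM", transition_window)
    tm_c = estimate_transitions(cohort, "CDM", transition_window)
    tm_l, tm_c = apply_scenario(tm_l, tm_c, switch_scenario)
    payoffs = estimate_payoffs(cohort, costs, scenario, utilities)

    if trial_end_years is None:
        pat = cohort.patients
        exit_day = np.where(pat["death_day"].notna(), pat["death_day"], pat["censor_day"])
        trial_end_years = float(exit_day.max()) / DAYS_PER_YEAR
    n_cycles = int(np.ceil((horizon_years - trial_end_years) / CYCLE_YEARS))
    age0 = float(cohort.patients["age_at_entry"].mean())

    qaly_p = payoffs.qaly(utilities)
    traces = []
    acc = {}
    for arm, tm in (("LCM", tm_l), ("CDM", tm_c)):
        ai = ARM_INDEX[arm]
        occ = initial_occupancy(cohort, arm)
        tr = run_cohort(
            occ,
            tm,
            payoffs.cost[ai],
            qaly_p[ai],
            n_cycles,
            trial_end_years,
            discount_rate,
            life_table,
            age0,
            payoffs.cd4_tests[ai],
            payoffs.cd4_price[ai],
        )
        tr["arm"] = arm
        traces.append(tr)
        acc[arm] = tr
    trace = pd.concat(traces, ignore_index=True)

    dc = acc["LCM"]["disc_cost"].cumsum() - acc["CDM"]["disc_cost"].cumsum()
    dq = acc["LCM"]["disc_qaly"].cumsum() - acc["CDM"]["disc_qaly"].cumsum()
    dn = acc["LCM"]["disc_cd4_tests"].cumsum() - acc["CDM"]["disc_cd4_tests"].cumsum()
    with np.errstate(divide="ignore", invalid="ignore"):
        traj = pd.DataFrame(
            {
                "t_years": acc["LCM"]["t_years"] + CYCLE_YEARS,
                "cum_delta_cost": trial_delta_cost + dc,
                "cum_delta_qaly": trial_delta_qaly + dq,
                "icer": (trial_delta_cost + dc) / (trial_delta_qaly + dq),
            }
        )
    return ExtrapolationResult(
        traces=trace,
        delta_cost=float(dc.iloc[-1]),
        delta_qaly=float(dq.iloc[-1]),
        delta_cd4_tests=float(dn.iloc[-1]),
        icer_trajectory=traj,
        trial_end_years=trial_end_years,
        total_delta_cost=float(trial_delta_cost + dc.iloc[-1]),
        total_delta_qaly=float(trial_delta_qaly + dq.iloc[-1]),
    )
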