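"""Within-trial effectiveness and cost-effectiveness.

Survival benefit is the difference in area under the Kaplan-Meier
survival curve (restricted mean survival time) between arms up to the
trial horizon.  QALYs weight time in four health states (1 asymptomatic
... 4 bed-ridden >50% of the previous month) by utilities anchored at 1
for the asymptomatic HIV-infected state, or rescaled by 0.81 to the
general population's valuation of that state.  Costs and benefits
beyond 12 months are discounted at 3% per annum, and means are adjusted
for censoring with an interval-partition (Lin-type) estimator: the sum
over 12-week intervals of the product-limit probability of surviving to
the interval start times the mean flow in the interval among patients
under observation at the interval start.  Uncertainty is quantified by
within-arm patient-level bootstrap with percentile intervals; dominated
replicates are ordered above any finite cost-effectiveness ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import restricted_mean_survival_time

from artcea.cohort import ARMS, CYCLE_DAYS, CYCLE_YEARS, DAYS_PER_YEAR, Cohort, PatientRecord

DOMINATED = "Dominated"
DOMINANT = "Dominant"


@dataclass
class UtilitySet:
    """Health-state utility weights, anchored so state 1 (asymptomatic,
    HIV-infected) is worth 1 to patients and 0.81 to the general
    population."""

    u1: float = 1.0
    u2: float = 0.85
    u3: float = 0.60
    u4: float = 0.40
    general_population_anchor: float = 0.81

    def __post_init__(self):
        if not (0.0 <= self.u4 <= self.u3 <= self.u2 <= self.u1):
            raise ValueError("utilities must satisfy 0 <= u4 <= u3 <= u2 <= u1")
        if abs(self.u1 - 1.0) > 1e-12:
            raise ValueError("u1 is the anchor and must equal 1")
        if not (0.0 < self.general_population_anchor <= 1.0):
            raise ValueError("general population anchor must lie in (0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.u1, self.u2, self.u3, self.u4])


@dataclass
class CEAResult:
    """Incremental cost, incremental effect, ICER and its bootstrap CI.

    ``icer`` and CI bounds are dollars per unit effect, or the labels
    "Dominated" / "Dominant" outside the north-east quadrant."""

    delta_cost: float
    delta_effect: float
    icer: Union[float, str]
    ci_lower: Union[float, str, None] = None
    ci_upper: Union[float, str, None] = None
    adjusted: bool = False
    quadrant: str = "NE"


def _surv_arrays(cohort: Cohort, arm: str):
    pat = cohort.patients[cohort.patients["arm"] == arm]
    if pat.empty:
        raise ValueError(f"arm {arm} has zero at-risk time")
    dead = pat["death_day"].notna().to_numpy()
    T = np.where(dead, pat["death_day"].to_numpy(float), pat["censor_day"].to_numpy(float))
    return T, dead.astype(int)


def km_area_survival(cohort: Cohort, horizon_days: Optional[float] = None) -> dict:
    """Per-arm restricted mean survival (years) up to the horizon and the
    LCM - CDM difference, by step integration of the product-limit curve."""
    maxes = []
    for arm in ARMS:
        T, _ = _surv_arrays(cohort, arm)
        maxes.append(T.max())
    if horizon_days is None:
        horizon_days = min(maxes)
    if horizon_days > max(maxes):
        raise ValueError("horizon exceeds the maximum observed time")
    out = {}
    for arm in ARMS:
        T, E = _surv_arrays(cohort, arm)
        kmf = KaplanMeierFitter().fit(T, E)
        out[arm] = float(restricted_mean_survival_time(kmf, t=horizon_days)) / DAYS_PER_YEAR
    out["difference"] = out["LCM"] - out["CDM"]
    out["horizon_days"] = float(horizon_days)
    return out


def _km_rmst(T: np.ndarray, E: np.ndarray, horizon: float) -> float:
    """Restricted mean survival time by exact step integration of the
    product-limit estimator (same convention as lifelines)."""
    order = np.argsort(T, kind="stable")
    T, E = T[order], E[order]
    uniq, idx = np.unique(T, return_index=True)
    n = len(T)
    at_risk = n - idx
    deaths = np.add.reduceat(E, idx)
    s = np.cumprod(1.0 - deaths / at_risk)
    # survival is 1 on [0, t1), s[i] on [t_i, t_{i+1})
    times = np.concatenate([[0.0], uniq])
    surv = np.concatenate([[1.0], s])
    times = np.minimum(times, horizon)
    widths = np.diff(np.append(times, horizon))
    return float(np.sum(surv * widths))


def compute_qalys(record: PatientRecord, utilities: UtilitySet, anchor: str = "patient") -> float:
    """Quality-adjusted life years over the record's observed cycles:
    sum of cycle duration (years) times the state's utility weight."""
    if anchor not in ("patient", "general"):
        raise ValueError("anchor must be 'patient' or 'general'")
    states = record.cycles["health_state"]
    if states.isna().any():
        raise ValueError("missing health state while alive")
    u = utilities.as_array()[states.to_numpy(int) - 1]
    q = float(np.sum(record.cycles["fraction"].to_numpy() * CYCLE_YEARS * u))
    if anchor == "general":
        q *= utilities.general_population_anchor
    return q


def discount_factors(t_years, rate: float = 0.03) -> np.ndarray:
    """Discount factors for flows at times ``t_years``: flows within the
    first year are undiscounted; later flows are discounted at
    ``(1+rate)^-(t-1)`` (discount time runs from the end of year 1)."""
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    t = np.asarray(t_years, dtype=float)
    return np.where(t <= 1.0, 1.0, (1.0 + rate) ** (-(t - 1.0)))


def discount(amounts, t_years, rate: float = 0.03) -> float:
    """Present value of a flow stream (amounts at times ``t_years``)."""
    amounts = np.asarray(amounts, dtype=float)
    return float(np.sum(amounts * discount_factors(t_years, rate)))


def _interval_index_of_censor(censor_day: np.ndarray) -> np.ndarray:
    """Interval containing the censoring time; exits exactly on an
    interval boundary close out the preceding interval."""
    div = censor_day / CYCLE_DAYS
    idx = np.floor(div).astype(int)
    on_boundary = np.isclose(div, np.round(div)) & (idx > 0)
    return np.where(on_boundary, np.round(div).astype(int) - 1, idx)


def lin_adjusted_mean_cost(
    interval_values: np.ndarray,
    death_interval: np.ndarray,
    censor_interval: np.ndarray,
) -> float:
    """Censoring-adjusted mean of per-patient accumulated flows.

    ``interval_values``: (n, K) flows per 12-week interval.
    ``death_interval``: interval of death, or >= K when the patient did
    not die under observation.  ``censor_interval``: interval of
    censoring, >= K if followed to the end of the partition.

    Estimate = sum_k S(t_k) * mean(flow in k | under observation at the
    start of k), with S the product-limit survival of the death process.
    Reduces exactly to the naive mean when there is no censoring.
    """
    C = np.asarray(interval_values, dtype=float)
    n, K = C.shape
    d = np.asarray(death_interval)
    c = np.asarray(censor_interval)
    exit_int = np.minimum(d, c)
    total = 0.0
    s = 1.0
    for k in range(K):
        at_risk = exit_int >= k
        n_k = int(at_risk.sum())
        if n_k == 0:
            if np.any(C[:, k:]) or np.any(d[np.isfinite(d.astype(float))] >= k):
                remaining = C[:, k:].sum()
                if remaining != 0:
                    raise ValueError(
                        f"no patients under observation at interval {k} but flows remain"
                    )
            break
        total += s * C[at_risk, k].sum() / n_k
        deaths_k = int(np.sum(at_risk & (d == k)))
        s *= 1.0 - deaths_k / n_k
    return float(total)


def icer(delta_cost: float, delta_effect: float, adjusted: bool = False) -> CEAResult:
    """ICER with exhaustive quadrant handling: NE -> ratio; higher cost
    with no effect gain -> Dominated; effect gain at no extra cost ->
    Dominant; SW quadrant -> ratio flagged."""
    dc, de = float(delta_cost), float(delta_effect)
    if de > 0 and dc > 0:
        return CEAResult(dc, de, dc / de, adjusted=adjusted, quadrant="NE")
    if de <= 0 and dc > 0:
        return CEAResult(dc, de, DOMINATED, adjusted=adjusted, quadrant="NW")
    if de > 0 and dc <= 0:
        return CEAResult(dc, de, DOMINANT, adjusted=adjusted, quadrant="SE")
    return CEAResult(dc, de, (dc / de) if de != 0 else np.nan, adjusted=adjusted, quadrant="SW")


def _icer_order_key(dc: np.ndarray, de: np.ndarray) -> np.ndarray:
    """Ordering for bootstrap ICER replicates: Dominant < ratios <
    Dominated."""
    key = np.empty(len(dc))
    ne = (de > 0) & (dc > 0)
    key[ne] = dc[ne] / de[ne]
    key[(de <= 0) & (dc > 0)] = np.inf
    key[(de > 0) & (dc <= 0)] = -np.inf
    sw = (de <= 0) & (dc <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        key[sw] = np.where(de[sw] != 0, dc[sw] / de[sw], np.inf)
    return key


_LABEL_SENTINEL = 1e18


def _quantile_or_label(key: np.ndarray, q: float):
    # labels sit at +/- a large finite sentinel so percentile interpolation
    # stays defined; any bound pulled near a label is reported as the label
    v = float(np.quantile(np.clip(key, -_LABEL_SENTINEL, _LABEL_SENTINEL), q))
    if v >= _LABEL_SENTINEL / 1e3:
        return DOMINATED
    if v <= -_LABEL_SENTINEL / 1e3:
        return DOMINANT
    return v


def bootstrap_ci(
    data: Union[Cohort, dict],
    statistic: Callable,
    B: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
):
    """Percentile bootstrap CI, resampling patients with replacement
    within arm.

    ``data`` is either a Cohort (``statistic`` receives a resampled
    Cohort) or a dict arm -> per-patient array (``statistic`` receives
    the resampled dict).  Returns (lower, upper, replicates).
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    rng = np.random.default_rng(seed)
    reps = np.empty(B)
    if isinstance(data, Cohort):
        ids = {a: data.arm_ids(a) for a in ARMS}
        for b in range(B):
            take = np.concatenate([rng.choice(ids[a], size=len(ids[a])) for a in ARMS])
            # resampling with replacement duplicates ids; rebuild via concat
            reps[b] = statistic(_resample_cohort(data, take))
    else:
        arms = list(data)
        for b in range(B):
            sample = {a: np.asarray(data[a])[rng.integers(0, len(data[a]), len(data[a]))] for a in arms}
            reps[b] = statistic(sample)
    lower = float(np.quantile(reps, alpha / 2))
    upper = float(np.quantile(reps, 1 - alpha / 2))
    return lower, upper, reps


def _resample_cohort(cohort: Cohort, ids: np.ndarray) -> Cohort:
    pats = cohort.patients.set_index("id").loc[ids].reset_index()
    new_ids = np.arange(len(ids))
    cyc_groups = {pid: g for pid, g in cohort.cycles.groupby("id")}
    frames = []
    for new, old in zip(new_ids, ids):
        g = cyc_groups[old].copy()
        g["id"] = new
        frames.append(g)
    pats["id"] = new_ids
    return Cohort(patients=pats, cycles=pd.concat(frames, ignore_index=True), params=cohort.params)


# ---------------------------------------------------------------------------
# vectorised arm matrices and the full trial CEA


def arm_flow_matrices(
    cohort: Cohort,
    per_cycle_values: pd.DataFrame,
    value_cols,
    discount_rate: float = 0.0,
    censoring: str = "dropout_only",
) -> dict:
    """Per-arm (n, K) matrices of (optionally discounted) per-interval
    flows plus death/censor interval indices, for the Lin estimator and
    its bootstrap.

    ``censoring`` selects what the adjustment corrects for.  For costs
    ("dropout_only") the scheduled administrative trial end completes
    observation — it terminates accrual of the quantity of interest —
    so it counts as an event alongside death and only loss to follow-up
    censors.  For health outcomes ("all") any censoring is adjusted
    for, so the estimate refers to survival experience up to the common
    partition horizon, like the restricted-mean survival area."""
    K = int(cohort.cycles["cycle"].max()) + 1
    t_mid = (np.arange(K) + 0.5) * CYCLE_YEARS
    df = discount_factors(t_mid, discount_rate)
    out = {}
    pat_all = cohort.patients
    for arm in ARMS:
        pats = pat_all[pat_all["arm"] == arm].reset_index(drop=True)
        ids = pats["id"].to_numpy()
        pos = {pid: i for i, pid in enumerate(ids)}
        sel = per_cycle_values[per_cycle_values["id"].isin(ids)]
        rows = np.array([pos[i] for i in sel["id"].to_numpy()])
        cols = sel["cycle"].to_numpy(int)
        mats = {}
        for col in value_cols:
            M = np.zeros((len(ids), K))
            np.add.at(M, (rows, cols), sel[col].to_numpy(float))
            M *= df[None, :]
            mats[col] = M
        dead = pats["death_day"].notna().to_numpy()
        dropped = pats["dropped_out"].to_numpy(bool) if "dropped_out" in pats else np.zeros(len(pats), bool)
        censor_filled = _interval_index_of_censor(np.nan_to_num(pats["censor_day"].to_numpy(float)))
        death_filled = np.floor(np.nan_to_num(pats["death_day"].to_numpy(float)) / CYCLE_DAYS)
        if censoring == "dropout_only":
            d_int = np.where(dead, death_filled, np.where(dropped, K + 1, censor_filled)).astype(int)
            c_int = np.where(dropped, censor_filled, K + 1).astype(int)
        elif censoring == "all":
            d_int = np.where(dead, death_filled, K + 1).astype(int)
            c_int = np.where(dead, K + 1, censor_filled).astype(int)
        else:
            raise ValueError("censoring must be 'dropout_only' or 'all'")
        T = np.where(dead, pats["death_day"].to_numpy(float), pats["censor_day"].to_numpy(float))
        out[arm] = dict(mats=mats, death_int=d_int, censor_int=c_int, T=T, E=dead.astype(int), ids=ids)
    return out


def qaly_flows(cohort: Cohort, utilities: UtilitySet) -> pd.DataFrame:
    """Per-cycle life-year and (patient-anchored) QALY flows."""
    cyc = cohort.cycles
    u = utilities.as_array()[cyc["health_state"].to_numpy(int) - 1]
    return pd.DataFrame(
        {
            "id": cyc["id"].to_numpy(),
            "cycle": cyc["cycle"].to_numpy(),
            "ly": cyc["fraction"].to_numpy() * CYCLE_YEARS,
            "qaly": cyc["fraction"].to_numpy() * CYCLE_YEARS * u,
        }
    )


@dataclass
class TrialCEA:
    """Bundle of within-trial results (the main-results table)."""

    table: pd.DataFrame
    results: dict  # name -> CEAResult
    horizon_days: float
    rep_sd: Optional[dict] = None  # bootstrap SDs of the incremental quantities


def adjusted_arm_means(
    cohort: Cohort,
    flows: pd.DataFrame,
    value_cols,
    discount_rate: float = 0.03,
    censoring: str = "dropout_only",
) -> dict:
    """Censoring-adjusted discounted per-arm means of arbitrary per-cycle
    flow columns (point estimates, no bootstrap)."""
    mats = arm_flow_matrices(cohort, flows, value_cols, discount_rate, censoring)
    out = {}
    for arm in ARMS:
        d = mats[arm]
        out[arm] = {
            name: lin_adjusted_mean_cost(M, d["death_int"], d["censor_int"])
            for name, M in d["mats"].items()
        }
    return out


def trial_cea(
    cohort: Cohort,
    cost_per_cycle: pd.DataFrame,
    utilities: Optional[UtilitySet] = None,
    B: int = 2000,
    seed: int = 0,
    discount_rate: float = 0.03,
    horizon_days: Optional[float] = None,
) -> TrialCEA:
    """Full within-trial cost-effectiveness analysis.

    Produces unadjusted mean costs and KM survival, censoring-adjusted
    discounted costs, life years and QALYs (both utility anchors), and
    ICERs with percentile bootstrap CIs (patients resampled within arm).
    """
    utilities = utilities or UtilitySet()
    rng = np.random.default_rng(seed)

    q = qaly_flows(cohort, utilities)
    flows = cost_per_cycle[["id", "cycle", "total"]].merge(q, on=["id", "cycle"])
    disc = arm_flow_matrices(cohort, flows, ["total"], discount_rate, censoring="dropout_only")
    disc_eff = arm_flow_matrices(cohort, flows, ["ly", "qaly"], discount_rate, censoring="all")
    undisc = arm_flow_matrices(cohort, flows, ["total"], 0.0, censoring="dropout_only")

    if horizon_days is None:
        horizon_days = min(disc[a]["T"].max() for a in ARMS)

    def arm_stats(mats_by_arm, idx=None):
        stats = {}
        for arm in ARMS:
            d = mats_by_arm[arm]
            n = len(d["ids"])
            take = np.arange(n) if idx is None else idx[arm]
            di, ci = d["death_int"][take], d["censor_int"][take]
            s = {}
            for name, M in d["mats"].items():
                s[name] = lin_adjusted_mean_cost(M[take], di, ci)
            e = disc_eff[arm]
            for name, M in e["mats"].items():
                s[name] = lin_adjusted_mean_cost(M[take], e["death_int"][take], e["censor_int"][take])
            s["naive_cost"] = float(undisc[arm]["mats"]["total"][take].sum(axis=1).mean())
            s["rmst_years"] = _km_rmst(d["T"][take], d["E"][take], horizon_days) / DAYS_PER_YEAR
            stats[arm] = s
        return stats

    point = arm_stats(disc)

    def diffs(stats):
        g = utilities.general_population_anchor
        return {
            "naive_cost": stats["LCM"]["naive_cost"] - stats["CDM"]["naive_cost"],
            "adj_cost": stats["LCM"]["total"] - stats["CDM"]["total"],
            "rmst": stats["LCM"]["rmst_years"] - stats["CDM"]["rmst_years"],
            "adj_ly": stats["LCM"]["ly"] - stats["CDM"]["ly"],
            "adj_qaly_patient": stats["LCM"]["qaly"] - stats["CDM"]["qaly"],
            "adj_qaly_general": g * (stats["LCM"]["qaly"] - stats["CDM"]["qaly"]),
        }

    d0 = diffs(point)

    names = list(d0)
    reps = {k: np.empty(B) for k in names}
    n_by_arm = {a: len(disc[a]["ids"]) for a in ARMS}
    for b in range(B):
        idx = {a: rng.integers(0, n_by_arm[a], n_by_arm[a]) for a in ARMS}
        db = diffs(arm_stats(disc, idx))
        for k in names:
            reps[k][b] = db[k]

    def pct(arr, q_):
        return float(np.quantile(arr, q_))

    results = {}
    # mean-difference CIs
    for key, label in [("naive_cost", "delta_cost_unadjusted"), ("adj_cost", "delta_cost_adjusted")]:
        results[label] = CEAResult(
            d0[key], np.nan, np.nan, pct(reps[key], 0.025), pct(reps[key], 0.975),
            adjusted=key == "adj_cost",
        )
    results["delta_survival_years"] = CEAResult(
        np.nan, d0["rmst"], np.nan, pct(reps["rmst"], 0.025), pct(reps["rmst"], 0.975)
    )
    # ICERs
    icer_specs = [
        ("icer_unadjusted_lyg", "naive_cost", "rmst", False),
        ("icer_adjusted_lyg", "adj_cost", "adj_ly", True),
        ("icer_adjusted_qaly_patient", "adj_cost", "adj_qaly_patient", True),
        ("icer_adjusted_qaly_general", "adj_cost", "adj_qaly_general", True),
    ]
    for label, ckey, ekey, adj in icer_specs:
        res = icer(d0[ckey], d0[ekey], adjusted=adj)
        key = _icer_order_key(reps[ckey], reps[ekey])
        res.ci_lower = _quantile_or_label(key, 0.025)
        res.ci_upper = _quantile_or_label(key, 0.975)
        results[label] = res

    rows = []
    g = utilities.general_population_anchor
    table_entries = [
        ("survival_years_undiscounted", point["LCM"]["rmst_years"], point["CDM"]["rmst_years"], d0["rmst"]),
        ("total_cost_unadjusted", point["LCM"]["naive_cost"], point["CDM"]["naive_cost"], d0["naive_cost"]),
        ("total_cost_adjusted", point["LCM"]["total"], point["CDM"]["total"], d0["adj_cost"]),
        ("life_years_adjusted", point["LCM"]["ly"], point["CDM"]["ly"], d0["adj_ly"]),
        ("qalys_patient_values", point["LCM"]["qaly"], point["CDM"]["qaly"], d0["adj_qaly_patient"]),
        ("qalys_general_values", g * point["LCM"]["qaly"], g * point["CDM"]["qaly"], d0["adj_qaly_general"]),
    ]
    for name, l, c, dd in table_entries:
        rows.append({"outcome": name, "lcm": l, "cdm": c, "difference": dd})
    for label, *_ in icer_specs:
        r = results[label]
        rows.append(
            {
                "outcome": label,
                "lcm": np.nan,
                "cdm": np.nan,
                "difference": r.icer if isinstance(r.icer, float) else np.nan,
                "ci_lower": r.ci_lower,
                "ci_upper": r.ci_upper,
            }
        )
    table = pd.DataFrame(rows)
    rep_sd = {k: float(np.std(v, ddof=1)) for k, v in reps.items()}
    return TrialCEA(table=table, results=results, horizon_days=float(horizon_days), rep_sd=rep_sd)
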