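"""Valuation of patient-level resource utilisation with unit costs.

Prices are 2008 US$. Laboratory tests and visits carry centre-specific
prices (Entebbe, Kampala, Harare; the Kampala satellite uses main-centre
prices); drugs, hospital per-diems and other diagnostics are priced
globally. Antiretroviral drug costs are annual costs of keeping one
patient on a regimen for 365 days, so the daily cost is annual/365.
Monitoring-strategy scenarios rewrite which routine tests attract cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from artcea.cohort import ARMS, CENTRES, Cohort, PatientRecord, CYCLE_COLUMNS

FIRST_LINE_REGIMENS = ("first_line_zdv3tc_tdf", "first_line_zdv3tc_nvp", "first_line_zdv3tc_abc")
SECOND_LINE_REGIMENS = ("second_line_ddi_efv_kal", "second_line_ddi_nvp_kal", "second_line_ddi_abc_kal")

#: the ten reporting categories of the trial's resource-use table
COST_CATEGORIES = (
    "first_line_therapy",
    "second_line_therapy",
    "cd4_monitoring",
    "haematology_monitoring",
    "biochemistry_monitoring",
    "diagnostics",
    "clinic_visits",
    "health_centre_visits",
    "hospital",
    "concomitant_medications",
)

_CATEGORY_OF_COUNT = {
    "cd4_tests": "cd4_monitoring",
    "haematology_tests": "haematology_monitoring",
    "biochemistry_tests": "biochemistry_monitoring",
    "diagnostic_investigations": "diagnostics",
    "clinic_visits": "clinic_visits",
    "health_centre_visits": "health_centre_visits",
    "hospital_nights": "hospital",
}


class UnitCostTable:
    """Long-format price table: item, centre (or "all"), price, scenario_set.

    Scenario sets other than ``observed`` are sparse overrides (e.g.
    ``lower_bound_second_line`` re-prices only second-line regimens).
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"item", "centre", "price_usd_2008", "scenario_set"}
        if not required.issubset(frame.columns):
            raise ValueError(f"unit-cost table needs columns {sorted(required)}")
        if (frame["price_usd_2008"] < 0).any():
            raise ValueError("unit costs must be non-negative")
        self.frame = frame.reset_index(drop=True)
        self._lookup = {
            (r.item, r.centre, r.scenario_set): float(r.price_usd_2008)
            for r in frame.itertuples()
        }

    @classmethod
    def from_csv(cls, path) -> "UnitCostTable":
        return cls(pd.read_csv(path))

    @classmethod
    def default(cls) -> "UnitCostTable":
        """The packaged price fixture (observed plus sensitivity sets)."""
        with resources.files("artcea.data").joinpath("unit_costs.csv").open() as f:
            return cls(pd.read_csv(f))

    def price(self, item: str, centre: str = "all", scenario_set: str = "observed") -> float:
        for key in (
            (item, centre, scenario_set),
            (item, "all", scenario_set),
            (item, centre, "observed"),
            (item, "all", "observed"),
        ):
            if key in self._lookup:
                return self._lookup[key]
        raise KeyError(f"no price for item={item!r} centre={centre!r} set={scenario_set!r}")

    def centre_prices(self, item: str, scenario_set: str = "observed") -> np.ndarray:
        return np.array([self.price(item, c, scenario_set) for c in CENTRES])

    def daily_drug_cost(self, line: str, mix: Optional[dict] = None, scenario_set: str = "observed") -> float:
        """Mean daily ART cost for a regimen mix (default uniform)."""
        regimens = FIRST_LINE_REGIMENS if line == "first" else SECOND_LINE_REGIMENS
        if mix is None:
            mix = {r: 1.0 / len(regimens) for r in regimens}
        total_w = sum(mix.values())
        return sum(w * self.price(r, "all", scenario_set) / 365.0 for r, w in mix.items()) / total_w


@dataclass
class ScenarioSpec:
    """Monitoring-strategy and price-set rewrites applied during costing.

    ``cd4_monitoring``: "always", "from_year2" (no routine CD4 cost in
    the first year on ART) or "never".  ``toxicity_monitoring=False``
    zeroes routine haematology/biochemistry.  ``cd4_unit_cost_override``
    replaces every centre's CD4 test price (threshold analyses).
    """

    toxicity_monitoring: bool = True
    cd4_monitoring: str = "always"
    second_line_prices: str = "midpoint"  # or "lower_bound"
    first_line_prices: str = "midpoint"  # or "generic"
    lab_prices: str = "centre"  # or "national_referral"
    cd4_unit_cost_override: Optional[float] = None
    first_line_mix: Optional[dict] = None
    second_line_mix: Optional[dict] = None

    def __post_init__(self):
        if self.cd4_monitoring not in ("always", "from_year2", "never"):
            raise ValueError("cd4_monitoring must be always/from_year2/never")
        if self.second_line_prices not in ("midpoint", "lower_bound"):
            raise ValueError("second_line_prices must be midpoint/lower_bound")
        if self.first_line_prices not in ("midpoint", "generic"):
            raise ValueError("first_line_prices must be midpoint/generic")
        if self.lab_prices not in ("centre", "national_referral"):
            raise ValueError("lab_prices must be centre/national_referral")
        if self.cd4_unit_cost_override is not None and self.cd4_unit_cost_override < 0:
            raise ValueError("cd4_unit_cost_override must be non-negative")

    @property
    def lab_set(self) -> str:
        return "national_referral_lab" if self.lab_prices == "national_referral" else "observed"

    @property
    def fl_set(self) -> str:
        return "generic_first_line" if self.first_line_prices == "generic" else "observed"

    @property
    def sl_set(self) -> str:
        return "lower_bound_second_line" if self.second_line_prices == "lower_bound" else "observed"


@dataclass
class CostBreakdown:
    """Per-patient cost (US$) by reporting category."""

    categories: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.categories.values()))

    def __getitem__(self, key):
        return self.categories[key]


def cd4_price_per_centre(costs: UnitCostTable, scenario: ScenarioSpec) -> np.ndarray:
    if scenario.cd4_unit_cost_override is not None:
        return np.full(len(CENTRES), float(scenario.cd4_unit_cost_override))
    return costs.centre_prices("cd4_test", scenario.lab_set)


def cost_cycles(
    cohort: Cohort, costs: UnitCostTable, scenario: Optional[ScenarioSpec] = None
) -> pd.DataFrame:
    """Per patient-cycle costs by category (columns ``COST_CATEGORIES``
    plus ``total``), aligned with ``cohort.cycles`` rows.

    Concomitant medications are costed as a flat per-arm per-patient
    amount spread over the patient's observed cycle fractions, so the
    per-patient total equals the flat amount.
    """
    scenario = scenario or ScenarioSpec()
    cyc = cohort.cycles
    pat = cohort.patients.set_index("id")
    centre = pat["centre"].reindex(cyc["id"]).to_numpy()
    arm = pat["arm"].reindex(cyc["id"]).to_numpy()
    unknown = set(np.unique(centre)) - set(CENTRES)
    if unknown:
        raise KeyError(f"unknown centre(s) in cohort: {sorted(unknown)}")
    for cat in _CATEGORY_OF_COUNT:
        if (cyc[cat].to_numpy() < 0).any():
            raise ValueError(f"negative counts in {cat}")
    centre_idx = pd.Categorical(centre, categories=list(CENTRES)).codes

    out = pd.DataFrame(index=cyc.index)
    out["id"] = cyc["id"].to_numpy()
    out["cycle"] = cyc["cycle"].to_numpy()
    out["t_start_day"] = cyc["t_start_day"].to_numpy()
    out["fraction"] = cyc["fraction"].to_numpy()

    fl_daily = costs.daily_drug_cost("first", scenario.first_line_mix, scenario.fl_set)
    sl_daily = costs.daily_drug_cost("second", scenario.second_line_mix, scenario.sl_set)
    out["first_line_therapy"] = cyc["first_line_days"].to_numpy() * fl_daily
    out["second_line_therapy"] = cyc["second_line_days"].to_numpy() * sl_daily

    cd4_price = cd4_price_per_centre(costs, scenario)[centre_idx]
    if scenario.cd4_monitoring == "never":
        cd4_price = np.zeros_like(cd4_price)
    elif scenario.cd4_monitoring == "from_year2":
        cd4_price = np.where(cyc["t_start_day"].to_numpy() < 365.0, 0.0, cd4_price)
    out["cd4_monitoring"] = cyc["cd4_tests"].to_numpy() * cd4_price

    haem_price = costs.centre_prices("haematology_panel", scenario.lab_set)[centre_idx]
    bio_price = costs.centre_prices("biochemistry_panel", scenario.lab_set)[centre_idx]
    if not scenario.toxicity_monitoring:
        haem_price = np.zeros_like(haem_price)
        bio_price = np.zeros_like(bio_price)
    out["haematology_monitoring"] = cyc["haematology_tests"].to_numpy() * haem_price
    out["biochemistry_monitoring"] = cyc["biochemistry_tests"].to_numpy() * bio_price

    out["diagnostics"] = cyc["diagnostic_investigations"].to_numpy() * costs.price("other_diagnostic")
    out["clinic_visits"] = cyc["clinic_visits"].to_numpy() * costs.centre_prices("clinic_visit")[centre_idx]
    out["health_centre_visits"] = (
        cyc["health_centre_visits"].to_numpy() * costs.centre_prices("health_centre_visit")[centre_idx]
    )
    out["hospital"] = cyc["hospital_nights"].to_numpy() * costs.price("hospital_per_diem")

    # analysed by group, not per patient: a flat per-arm amount spread over
    # the patient's observed cycles (zero for records with no recorded use)
    flat = np.where(
        arm == "LCM", costs.price("concomitant_flat_lcm"), costs.price("concomitant_flat_cdm")
    )
    frac_total = cyc.groupby("id")["fraction"].transform("sum").to_numpy()
    any_units = (cyc.groupby("id")["concomitant_med_units"].transform("max") > 0).to_numpy()
    out["concomitant_medications"] = np.where(any_units, flat * cyc["fraction"].to_numpy() / frac_total, 0.0)

    out["total"] = out[list(COST_CATEGORIES)].sum(axis=1)
    return out


def cost_patient(
    record: PatientRecord, costs: UnitCostTable, scenario: Optional[ScenarioSpec] = None
) -> CostBreakdown:
    """Total cost of one participant's utilisation, by category."""
    pat = pd.DataFrame(
        {
            "id": [record.id],
            "arm": [record.arm],
            "centre": [record.centre],
            "age_at_entry": [record.age_at_entry],
            "death_day": [record.death_day],
            "censor_day": [record.censor_day],
        }
    )
    mini = Cohort(patients=pat, cycles=record.cycles[list(CYCLE_COLUMNS)])
    per_cycle = cost_cycles(mini, costs, scenario)
    if record.cycles.empty:
        return CostBreakdown({c: 0.0 for c in COST_CATEGORIES})
    return CostBreakdown({c: float(per_cycle[c].sum()) for c in COST_CATEGORIES})


def patient_totals(
    cohort: Cohort, costs: UnitCostTable, scenario: Optional[ScenarioSpec] = None
) -> pd.DataFrame:
    """Per-patient category totals (one row per randomised patient)."""
    per_cycle = cost_cycles(cohort, costs, scenario)
    totals = per_cycle.groupby("id")[list(COST_CATEGORIES) + ["total"]].sum()
    totals = totals.reindex(cohort.patients["id"]).fillna(0.0)
    totals["arm"] = cohort.patients.set_index("id")["arm"]
    return totals.reset_index()


def summarize_arms(
    cohort: Cohort, costs: UnitCostTable, scenario: Optional[ScenarioSpec] = None
) -> pd.DataFrame:
    """Intention-to-treat per-arm category means/SDs and LCM-CDM differences.

    Mirrors the structure of the trial's resource-utilisation table:
    one row per cost category plus ``total``.
    """
    totals = patient_totals(cohort, costs, scenario)
    for a in ARMS:
        if not (totals["arm"] == a).any():
            raise ValueError(f"empty arm {a}")
    rows = []
    for cat in list(COST_CATEGORIES) + ["total"]:
        l = totals.loc[totals["arm"] == "LCM", cat]
        c = totals.loc[totals["arm"] == "CDM", cat]
        rows.append(
            {
                "category": cat,
                "lcm_mean": l.mean(),
                "lcm_sd": l.std(),
                "cdm_mean": c.mean(),
                "cdm_sd": c.std(),
                "difference": l.mean() - c.mean(),
            }
        )
    return pd.DataFrame(rows)
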