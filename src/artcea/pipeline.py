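"""Configuration, orchestration and tabular reporting.

``run_pipeline`` ties the stages together — simulate (or load) the
cohort, cost its utilisation, run the within-trial CEA, extrapolate
with the Markov model, run the PSA, and solve the threshold analyses —
writing one CSV per report plus a run log.  Every source of randomness
flows from the single configured seed.
"""

from __future__ import annotations

import dataclasses
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

import artcea
from artcea.cohort import CohortParams, Cohort, generate_cohort, CYCLE_COLUMNS, PATIENT_COLUMNS
from artcea.costing import (
    ScenarioSpec,
    UnitCostTable,
    cost_cycles,
    summarize_arms,
)
from artcea.decision import (
    CostDecomposition,
    PSAInputs,
    cd4_price_threshold,
    ceac,
    fixed_budget_threshold,
    psa,
    who_threshold,
)
from artcea.markov import (
    LifeTable,
    estimate_payoffs,
    estimate_transitions,
    apply_scenario,
    extrapolate,
    initial_occupancy,
)
from artcea.trial import UtilitySet, adjusted_arm_means, qaly_flows, trial_cea

#: named monitoring strategies exposed on the command line
NAMED_SCENARIOS = {
    "lcm-vs-cdm": {},
    "limited-cd4": {"toxicity_monitoring": False, "cd4_monitoring": "from_year2"},
    "low-cost-second-line": {
        "toxicity_monitoring": False,
        "cd4_monitoring": "from_year2",
        "second_line_prices": "lower_bound",
    },
}

STAGES = ("simulate", "cost", "cea", "extrapolate", "psa", "threshold")


@dataclass
class RunConfig:
    """Run settings; every numeric default is the base-case analysis."""

    seed: int = 1
    out_dir: str = "artcea_out"
    patients_csv: Optional[str] = None  # simulate when absent
    unit_costs_csv: Optional[str] = None  # packaged fixture when absent
    life_table_csv: Optional[str] = None
    bootstrap_reps: int = 2000
    psa_draws: int = 500
    discount_rate: float = 0.03
    horizon_years: float = 25.0
    switch_scenario: str = "optimistic"
    scenario: dict = field(default_factory=dict)  # ScenarioSpec overrides
    cohort: dict = field(default_factory=dict)  # CohortParams overrides
    utilities: dict = field(default_factory=dict)  # UtilitySet overrides
    utility_se: float = 0.05
    gdp_per_capita: dict = field(default_factory=lambda: {"uganda": 415.0, "zimbabwe": 365.0})
    gdp_weights: dict = field(default_factory=lambda: {"uganda": 0.7, "zimbabwe": 0.3})
    no_art_cost: float = 250.0
    no_art_qaly: float = 1.5
    lambda_grid: dict = field(default_factory=lambda: {"start": 0.0, "stop": 5000.0, "step": 50.0})
    transition_window: tuple = (4.0, 6.0)

    def validate(self) -> None:
        if self.bootstrap_reps < 100 or self.psa_draws < 100:
            raise ValueError("bootstrap_reps and psa_draws must be at least 100")
        if not (0.0 <= self.discount_rate < 1.0):
            raise ValueError("discount rate must lie in [0, 1)")
        if self.horizon_years <= 6.0:
            raise ValueError("horizon must extend beyond the trial")
        if self.switch_scenario not in ("optimistic", "conservative"):
            raise ValueError("switch_scenario must be optimistic/conservative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def scenario_spec(self, name: Optional[str] = None) -> ScenarioSpec:
        overrides = dict(NAMED_SCENARIOS.get(name or "lcm-vs-cdm", {}))
        overrides.update(self.scenario)
        return ScenarioSpec(**overrides)

    def cohort_params(self) -> CohortParams:
        params = CohortParams(**self.cohort) if self.cohort else CohortParams()
        params.seed = self.seed
        return params

    def utility_set(self) -> UtilitySet:
        return UtilitySet(**self.utilities) if self.utilities else UtilitySet()


def validate_inputs(paths: dict) -> list:
    """Schema checks on the input CSVs; returns diagnostics (empty when
    everything is well-formed).  Row-level problems name the line."""
    diags = []
    patients = paths.get("patients_csv")
    if patients:
        try:
            df = pd.read_csv(patients)
        except Exception as exc:  # malformed file
            return [f"{patients}: unreadable ({exc})"]
        needed = set(PATIENT_COLUMNS + [c for c in CYCLE_COLUMNS if c != "id"])
        missing = needed - set(df.columns)
        if missing:
            diags.append(f"{patients}: missing columns {sorted(missing)}")
        else:
            from artcea.cohort import COUNT_CATEGORIES

            for cat in COUNT_CATEGORIES:
                bad = np.where(df[cat].to_numpy() < 0)[0]
                for i in bad[:10]:
                    diags.append(f"{patients}: line {i + 2}: negative {cat}")
            bad_state = np.where(~df["health_state"].isin([1, 2, 3, 4]))[0]
            for i in bad_state[:10]:
                diags.append(f"{patients}: line {i + 2}: health_state outside 1..4")
    uc = paths.get("unit_costs_csv")
    if uc:
        try:
            df = pd.read_csv(uc)
        except Exception as exc:
            return diags + [f"{uc}: unreadable ({exc})"]
        needed = {"item", "centre", "price_usd_2008", "scenario_set"}
        if not needed.issubset(df.columns):
            diags.append(f"{uc}: missing columns {sorted(needed - set(df.columns))}")
        else:
            for i in np.where(df["price_usd_2008"].to_numpy() < 0)[0][:10]:
                diags.append(f"{uc}: line {i + 2}: negative price")
    lt = paths.get("life_table_csv")
    if lt:
        try:
            df = pd.read_csv(lt)
        except Exception as exc:
            return diags + [f"{lt}: unreadable ({exc})"]
        if not {"age", "annual_q"}.issubset(df.columns):
            diags.append(f"{lt}: missing columns age/annual_q")
        else:
            gaps = np.where(np.diff(df["age"].to_numpy()) != 1)[0]
            for i in gaps[:10]:
                diags.append(f"{lt}: line {i + 3}: gap in ages")
            for i in np.where((df["annual_q"] < 0) | (df["annual_q"] > 1))[0][:10]:
                diags.append(f"{lt}: line {i + 2}: probability out of range")
    return diags


def cd4_cost_decomposition(
    cohort: Cohort,
    costs: UnitCostTable,
    scenario: ScenarioSpec,
    switch_scenario: str,
    utilities: UtilitySet,
    life_table: LifeTable,
    horizon_years: float = 25.0,
    discount_rate: float = 0.03,
    transition_window=(4.0, 6.0),
) -> CostDecomposition:
    """Decompose the full (trial + extrapolation) incremental cost into
    its CD4-price-free part and the discounted incremental number of
    costed CD4 tests, for the closed-form threshold solver."""
    zero = dataclasses.replace(scenario, cd4_unit_cost_override=0.0)
    per_cycle = cost_cycles(cohort, costs, zero)
    # costed tests: respect the scenario's monitoring window
    tests = cohort.cycles[["id", "cycle", "t_start_day", "cd4_tests"]].copy()
    if scenario.cd4_monitoring == "never":
        tests["cd4_tests"] = 0
    elif scenario.cd4_monitoring == "from_year2":
        tests.loc[tests["t_start_day"] < 365.0, "cd4_tests"] = 0
    flows = per_cycle[["id", "cycle", "total"]].merge(
        tests[["id", "cycle", "cd4_tests"]], on=["id", "cycle"]
    )
    adj = adjusted_arm_means(cohort, flows, ["total", "cd4_tests"], discount_rate)
    q = qaly_flows(cohort, utilities)
    adj_e = adjusted_arm_means(cohort, q, ["qaly"], discount_rate, censoring="all")

    ex0 = extrapolate(
        cohort,
        costs,
        scenario=zero,
        switch_scenario=switch_scenario,
        utilities=utilities,
        life_table=life_table,
        horizon_years=horizon_years,
        discount_rate=discount_rate,
        transition_window=transition_window,
    )
    dc0 = (adj["LCM"]["total"] - adj["CDM"]["total"]) + ex0.delta_cost
    dn = (adj["LCM"]["cd4_tests"] - adj["CDM"]["cd4_tests"]) + ex0.delta_cd4_tests
    de = (adj_e["LCM"]["qaly"] - adj_e["CDM"]["qaly"]) + ex0.delta_qaly
    return CostDecomposition(delta_cost_at_zero=dc0, delta_tests=dn, delta_effect=de)


def run_pipeline(config: RunConfig, stages=STAGES, scenario_name: Optional[str] = None) -> dict:
    """Execute the requested stages (dependencies are run regardless) and
    write the report CSVs under ``config.out_dir``.

    Returns a bundle with the in-memory objects and output paths.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = set(stages)
    log_lines = [
        f"artcea {artcea.__version__} | python {platform.python_version()}"
        f" | numpy {np.__version__} | pandas {pd.__version__}",
        f"seed {config.seed} | scenario {scenario_name or 'lcm-vs-cdm'}"
        f" | switch {config.switch_scenario}",
    ]
    bundle = {"out_dir": str(out)}
    t_all = time.time()

    def _stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
            log_lines.append(f"stage {name}: {time.time() - t0:.1f}s")
            return result

        return wrap

    scenario = config.scenario_spec(scenario_name)
    utilities = config.utility_set()
    costs = (
        UnitCostTable.from_csv(config.unit_costs_csv)
        if config.unit_costs_csv
        else UnitCostTable.default()
    )
    life_table = (
        LifeTable.from_csv(config.life_table_csv) if config.life_table_csv else LifeTable.default()
    )

    @_stage("simulate")
    def cohort() -> Cohort:
        if config.patients_csv:
            return Cohort.from_csv(config.patients_csv)
        return generate_cohort(config.cohort_params())

    if "simulate" in stages:
        cohort.to_csv(out / "patients.csv")
        bundle["patients_csv"] = str(out / "patients.csv")
    bundle["cohort"] = cohort

    @_stage("cost")
    def costing():
        per_cycle = cost_cycles(cohort, costs, scenario)
        table2 = summarize_arms(cohort, costs, scenario)
        return per_cycle, table2

    per_cycle, table2 = costing
    if "cost" in stages:
        table2.to_csv(out / "resource_costs.csv", index=False)
        bundle["resource_costs_csv"] = str(out / "resource_costs.csv")
    bundle["table2"] = table2

    need_cea = stages & {"cea", "extrapolate", "psa", "threshold"}
    if need_cea:

        @_stage("cea")
        def cea_result():
            return trial_cea(
                cohort,
                per_cycle,
                utilities=utilities,
                B=config.bootstrap_reps,
                seed=config.seed + 1,
                discount_rate=config.discount_rate,
            )

        if "cea" in stages:
            cea_result.table.to_csv(out / "trial_cea.csv", index=False)
            bundle["trial_cea_csv"] = str(out / "trial_cea.csv")
        bundle["cea"] = cea_result
        trial_dc = cea_result.results["delta_cost_adjusted"].delta_cost
        trial_dq = cea_result.results["icer_adjusted_qaly_patient"].delta_effect

    if stages & {"extrapolate", "psa", "threshold"}:

        @_stage("extrapolate")
        def extrap():
            return extrapolate(
                cohort,
                costs,
                scenario=scenario,
                switch_scenario=config.switch_scenario,
                utilities=utilities,
                life_table=life_table,
                horizon_years=config.horizon_years,
                discount_rate=config.discount_rate,
                trial_delta_cost=trial_dc,
                trial_delta_qaly=trial_dq,
                transition_window=tuple(config.transition_window),
            )

        if "extrapolate" in stages:
            extrap.traces.to_csv(out / "markov_traces.csv", index=False)
            extrap.icer_trajectory.to_csv(out / "icer_trajectory.csv", index=False)
            bundle["markov_traces_csv"] = str(out / "markov_traces.csv")
        bundle["extrapolation"] = extrap

    if "psa" in stages:

        @_stage("psa")
        def ceac_curve():
            tm_l = estimate_transitions(cohort, "LCM", tuple(config.transition_window))
            tm_c = estimate_transitions(cohort, "CDM", tuple(config.transition_window))
            tm_l, tm_c = apply_scenario(tm_l, tm_c, config.switch_scenario)
            payoffs = estimate_payoffs(cohort, costs, scenario, utilities)
            inputs = PSAInputs(
                tm_lcm=tm_l,
                tm_cdm=tm_c,
                payoffs=payoffs,
                initial_occ_lcm=initial_occupancy(cohort, "LCM"),
                initial_occ_cdm=initial_occupancy(cohort, "CDM"),
                trial_end_years=extrap.trial_end_years,
                horizon_years=config.horizon_years,
                discount_rate=config.discount_rate,
                life_table=life_table,
                age0=float(cohort.patients["age_at_entry"].mean()),
                utilities=utilities,
                utility_se=config.utility_se,
                trial_delta_cost=trial_dc,
                trial_delta_cost_se=cea_result.rep_sd["adj_cost"],
                trial_delta_qaly=trial_dq,
                trial_delta_qaly_se=cea_result.rep_sd["adj_qaly_patient"],
            )
            samples = psa(inputs, S=config.psa_draws, seed=config.seed + 2)
            grid = np.arange(
                config.lambda_grid["start"],
                config.lambda_grid["stop"] + config.lambda_grid["step"] / 2,
                config.lambda_grid["step"],
            )
            return samples, ceac(samples, grid)

        samples, curve = ceac_curve
        cf = curve.frame
        cf["scenario"] = scenario_name or "lcm-vs-cdm"
        cf["switch_scenario"] = config.switch_scenario
        cf.to_csv(out / "ceac.csv", index=False)
        bundle["ceac_csv"] = str(out / "ceac.csv")
        bundle["psa_samples"] = samples
        bundle["ceac"] = curve

    if "threshold" in stages:

        @_stage("threshold")
        def thresholds():
            lam_who = who_threshold(config.gdp_per_capita, config.gdp_weights)
            decomp = cd4_cost_decomposition(
                cohort,
                costs,
                scenario,
                config.switch_scenario,
                utilities,
                life_table,
                config.horizon_years,
                config.discount_rate,
                tuple(config.transition_window),
            )
            rows = [
                {
                    "threshold_rule": "who_3x_gdp",
                    "lambda_usd_per_qaly": lam_who,
                    "cd4_break_even_cost": cd4_price_threshold(decomp, lam_who),
                }
            ]
            lam_budget = fixed_budget_threshold(
                cdm_cost=float(
                    np.nan_to_num(
                        adjusted_arm_means(cohort, per_cycle[["id", "cycle", "total"]], ["total"], config.discount_rate)[
                            "CDM"
                        ]["total"]
                    )
                )
                + float(extrap.traces.query("arm == 'CDM'")["disc_cost"].sum()),
                cdm_effect=float(
                    adjusted_arm_means(
                        cohort, qaly_flows(cohort, utilities), ["qaly"], config.discount_rate, censoring="all"
                    )["CDM"]["qaly"]
                )
                + float(extrap.traces.query("arm == 'CDM'")["disc_qaly"].sum()),
                no_art_cost=config.no_art_cost,
                no_art_effect=config.no_art_qaly,
            )
            rows.append(
                {
                    "threshold_rule": "fixed_budget",
                    "lambda_usd_per_qaly": lam_budget,
                    "cd4_break_even_cost": cd4_price_threshold(decomp, lam_budget),
                }
            )
            df = pd.DataFrame(rows)
            df["scenario"] = scenario_name or "lcm-vs-cdm"
            df["switch_scenario"] = config.switch_scenario
            return df, decomp

        thresh_df, decomp = thresholds
        thresh_df.to_csv(out / "thresholds.csv", index=False)
        bundle["thresholds_csv"] = str(out / "thresholds.csv")
        bundle["thresholds"] = thresh_df
        bundle["decomposition"] = decomp

    log_lines.append(f"total: {time.time() - t_all:.1f}s")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    bundle["log"] = log_lines
    return bundle
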