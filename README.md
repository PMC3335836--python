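# artcea

Economic evaluation of **routine laboratory monitoring versus clinically
driven monitoring of antiretroviral therapy (ART)** in low-income
settings, built as a reusable Python pipeline and exercised end-to-end
on a synthetic two-arm patient cohort.

HIV programmes must decide whether the benefit of routine 12-weekly
laboratory monitoring — CD4 counts for efficacy, haematology and
biochemistry for toxicity — justifies its cost, relative to monitoring
driven by clinical events alone. The package is aimed at health
economists and trial statisticians who want the full chain of such an
evaluation in testable, scriptable form:

* a **synthetic individual-patient-data generator** calibrated to the
  published summaries of a 3,316-adult African ART-monitoring trial
  (two arms, LCM = laboratory plus clinical monitoring, CDM =
  clinically driven monitoring; baseline CD4 median 86 cells/mm³,
  median follow-up 4.9 years);
* **costing** of per-patient resource utilisation with centre-specific
  2008 US$ unit costs and monitoring-strategy scenario rewrites;
* a **within-trial cost-effectiveness analysis**: restricted mean
  survival (area under the Kaplan–Meier curve), QALYs over four
  performance-scale health states, 3 %/year discounting after month 12,
  censoring-adjusted mean costs (interval-partition Lin-type
  estimator), and ICERs with within-arm patient bootstrap percentile
  confidence intervals;
* a **Markov cohort extrapolation** to 25 years after ART initiation
  over states {first/second line} × {CD4 <100, 100–200, >200}, with
  background mortality from an HIV-excluded counterfactual life table;
* **decision analysis**: probabilistic sensitivity analysis
  (Dirichlet transition rows, Gamma cost pay-offs, Beta utilities),
  cost-effectiveness acceptability curves, the WHO 3×GDP and
  fixed-budget willingness-to-pay thresholds, and a closed-form
  **CD4-test price-threshold solver** — because the model's incremental
  cost is affine in the CD4 test price,
  `c* = (λ·ΔE − ΔC₀)/Δn` solves `ICER(c*) = λ` exactly.

The core quantities follow standard health-economics notation: for
incremental cost ΔC and incremental effect ΔE (life-years or QALYs),
the incremental cost-effectiveness ratio is `ICER = ΔC/ΔE`; a strategy
is cost-effective at willingness-to-pay λ when the incremental net
monetary benefit `λ·ΔE − ΔC` is positive.

## Worked example

```bash
artcea all --seed 1 --out run1
```

runs every stage (simulate → cost → trial CEA → extrapolate → PSA →
thresholds) in about half a minute and prints the stage log. Key rows
of `run1/trial_cea.csv` from that exact run:

| outcome | LCM | CDM | difference |
|---|---|---|---|
| survival_years_undiscounted | 5.179 | 5.044 | +0.134 |
| total_cost_unadjusted (US$) | 3400 | 2614 | +786 |
| total_cost_adjusted (US$) | 3335 | 2577 | +758 |
| qalys_patient_values | 4.530 | 4.412 | +0.118 |
| icer_adjusted_qaly_patient | | | 6409 [3884, 19035] |

Reading: laboratory monitoring buys a ~0.13-year survival advantage at
~$786 extra cost per patient (≈$758 after censoring adjustment and
discounting), i.e. roughly $6,400 per QALY — far above the ~$1,200
(3× weighted per-capita GDP) threshold for the two countries, so
routine laboratory monitoring at observed prices is not cost-effective.
Arm-level resource costs by category are in `run1/resource_costs.csv`,
Markov occupancy traces and the ICER-versus-time trajectory in
`run1/markov_traces.csv` / `run1/icer_trajectory.csv`, the
acceptability curve in `run1/ceac.csv`.

Under the limited-monitoring scenario (no routine toxicity testing,
CD4 monitoring from year 2 on ART):

```bash
artcea threshold --seed 1 --scenario limited-cd4 --out run2
```

the threshold report shows a positive break-even CD4 test price
(≈$14 at λ=$1,200, ≈$9 under the fixed-budget rule in that run):
the cheaper the CD4 test, the closer restricted CD4 monitoring comes
to cost-effectiveness.

The same stages are available as a library:

```python
from artcea import CohortParams, generate_cohort, UnitCostTable, summarize_arms

cohort = generate_cohort(CohortParams(), seed=1)
table = summarize_arms(cohort, UnitCostTable.default())
print(table[["category", "lcm_mean", "cdm_mean", "difference"]])
```

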