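# Methods

This note documents the models behind `artcea`, the choices made where
the design was genuinely open, and what the synthetic cohort does and
does not establish about real trial data.

## 1. The evaluation problem

Two randomised monitoring strategies for adults starting ART with
symptomatic HIV disease and CD4 < 200 cells/mm³:

* **LCM** — routine 12-weekly laboratory monitoring (CD4 for efficacy;
  haematology/biochemistry for toxicity) plus clinical monitoring.
  Switch to second-line ART on an observed CD4 < 100 cells/mm³ (from
  48 weeks on ART).
* **CDM** — clinically driven monitoring; CD4 results are never
  available to clinicians, and switching follows WHO stage 4 events.

The pipeline estimates the incremental cost and health benefit of LCM
over CDM during the trial (~6 years) and extrapolates both to 25 years
after ART initiation. Analyses are intention-to-treat from the public
healthcare sector perspective, prices in 2008 US$.

## 2. Synthetic cohort (`artcea.cohort`)

No individual patient data are public, so every stage runs on a seeded
synthetic cohort whose *summary statistics* are calibrated to the
published per-arm tables. Time is discretised into 84-day (12-week)
cycles; a year is 52.18 weeks (365.26 days).

Structure per patient: centre (Entebbe 0.30 / Kampala 0.40 /
Harare 0.30 — weights chosen so the centre-weighted CD4 test price
reproduces the published $14.46 weighted average), age from a
triangular distribution matching median 37 (IQR 32–42), baseline CD4
from quantile interpolation through the published quartiles
(31/86/139, capped below 200), administrative follow-up uniform on
4.9 ± 0.7 years (median 4.9, IQR ≈ 4.55–5.25).

**CD4 trajectory.** On effective first-line therapy CD4 rises from
baseline toward baseline + gain with time constant 1 year; the gain is
Normal(190, 95) truncated at 20, so ~8 % of patients are persistent
non-responders who hover near or below 100 cells/mm³. A latent
first-line failure process (0.006/cycle) sends CD4 into a linear
decline (50 cells/cycle). Second-line response is an *independent*
gain draw — failure is regimen-specific, not a patient trait — so
switching genuinely rescues. Measurement noise is Normal(0, 12).

**Switching.** LCM: per-cycle probability 0.9 of switching when the
observed CD4 is below 100 and the patient has been on ART ≥ 4 cycles.
CDM: per-cycle probability of a switch-triggering WHO 4 event of
(0.013, 0.010, 0.0065) by CD4 band, applied after a 1-cycle lag. The
band pattern is deliberate: it makes CDM switch *more* than LCM at
CD4 > 200 (events unrelated to true failure) and far *less* at
CD4 < 100, reproducing the published switch-rate asymmetry that drives
the optimistic/conservative extrapolation scenarios.

**Mortality.** Per-cycle death probabilities by CD4 band
(0.018, 0.0055, 0.0012), a profound-immunosuppression tier of 0.055
below 50 cells/mm³, a ×3 multiplier while failing untreated on first
line, and ×1.35 on second line (residual post-failure risk; it also
gives the estimated matrices the second-line excess mortality that
sustains the long-term survival differential). Dropout (true loss to
follow-up) is 0.003/cycle.

These event parameters were tuned once, jointly, so that the generated
cohort reproduces the published first-/second-line drug exposure
(≈1465/153 days LCM, ≈1482/103 days CDM), the ≈41-day KM-area survival
benefit, and plausible overall mortality; they are frozen as the
`CohortParams` defaults and are not re-tuned anywhere.

**Resource utilisation.** Counts (tests, visits, hospital nights,
investigations) are drawn per cycle as negative-binomial variables.
Per-cycle intensities are calibrated so expected per-arm totals equal
the published per-patient means — either analytically
(`calibrate_to_targets`: intensity × expected person-cycles = target,
with a deterministic closed-form expectation of person-cycles) or,
inside `generate_cohort`, against the realised per-arm mean
person-cycles of the simulated histories (exact conditional
calibration). The NB dispersion is solved per category so the variance
of per-patient totals approximates the published SDs; routine CD4/
haematology/biochemistry tests accrue only in LCM.

**Health states.** Four performance-scale states (1 asymptomatic … 4
bed-ridden > 50 %), drawn per cycle from band-specific mixtures with
persistence 0.4; an ongoing WHO 3/4 event (band-dependent hazard,
doubled while failing) forces state ≥ 2. This yields the published
pattern that the QALY gain is slightly below the survival gain.

## 3. Costing (`artcea.costing`)

Each cycle's counts are valued with the unit-cost table
(`data/unit_costs.csv`): centre-specific prices for CD4, haematology,
biochemistry, clinic and health-centre visits; global prices for
hospital per-diems and other diagnostics; annual drug prices per
regimen (daily cost = annual/365). The regimen mix is configurable and
defaults to uniform over the three first-line and three second-line
regimens. Sensitivity price sets (generic first-line, lower-bound
second-line, national-referral laboratory) are sparse overrides.
Concomitant medications are costed as a flat per-arm amount
($46 LCM / $48 CDM), spread over the patient's observed cycles, zero
for patients with no recorded use.

Scenario rewrites: `toxicity_monitoring=False` zeroes routine
haematology/biochemistry; `cd4_monitoring="from_year2"` removes routine
CD4 cost from cycles starting in the first year; `"never"` removes it
entirely; `cd4_unit_cost_override` replaces every centre's CD4 price
(the lever the threshold solver moves). All costing is linear in
prices, which the threshold analysis exploits.

## 4. Within-trial CEA (`artcea.trial`)

* **Survival**: restricted mean survival time to the trial horizon by
  step integration of the Kaplan–Meier curve (lifelines), per arm.
* **QALYs**: state utilities default to (1.00, 0.85, 0.60, 0.40) —
  assumptions, clearly overridable, since the elicitation sub-study
  values are not published — anchored at 1 for the asymptomatic
  HIV-infected state; the general-population anchor rescales by 0.81.
* **Discounting**: flows are bucketed by cycle midpoint; cycles inside
  year 1 undiscounted, later cycles discounted at
  1.03^−(t−1) (discount time measured from the end of year 1).
* **Censoring adjustment**: interval-partition estimator
  Σₖ S(tₖ) · mean(flow in k | under observation at start of k), with S
  the product-limit survival of the "event" process. Two conventions
  are used deliberately: for **costs**, the scheduled administrative
  trial end is an observation-completing event and only loss to
  follow-up censors (the estimand is mean cost over scheduled trial
  participation; adjusted costs sit ~3 % below unadjusted once
  discounted). For **effects**, all censoring is adjusted for, so
  adjusted life-years/QALYs refer to the common partition horizon,
  like the RMST. A single convention cannot reproduce both published
  adjusted/unadjusted ratios.
* **Uncertainty**: percentile bootstrap, patients resampled with
  replacement within arm, default B = 2000. ICER replicates are
  ordered with "Dominated" above any finite ratio (and "Dominant"
  below), so CI bounds can be labels.

## 5. Markov extrapolation (`artcea.markov`)

Seven states (line × CD4 band + DEAD), 12-week cycles. Transition
matrices are multinomial MLEs from consecutive cycle pairs whose
source cycle starts in trial years 4–6; a death in the following
interval is a transition to DEAD; censored pairs are dropped.
Scenarios: *optimistic* keeps the arm-specific matrices;
*conservative* gives CDM the LCM switch probability out of FL_>200
(difference folded into the stay probability).

Pay-offs per (arm, state): deterministic full-compliance components
(84 days of line-appropriate ART, one clinic visit, one routine CD4
test plus toxicity panels in LCM when the scenario retains them) plus
observed per-cycle means of random components (hospital nights,
clinically driven investigations, health-centre visits, and a
configurable cotrimoxazole/antimalarial share — default 0.8 — of the
flat concomitant amount), matched to the latest CD4 band. QALY
pay-offs come from each stratum's health-state mix times the
utilities, so PSA utility draws propagate exactly.

Background mortality uses an age-indexed HIV-excluded life table
(`data/background_mortality_synthetic.csv`, a synthetic Gompertz–
Makeham stand-in for an East-African counterfactual schedule; any
`age,annual_q` CSV can be substituted). Annual probabilities convert
to cycles as 1−(1−q)^(12/52.18) and combine with state-specific death
as independent competing risks, surviving mass rescaled
proportionally. The cohort ages as a single representative (mean entry
age + elapsed time).

Initial occupancy is the empirical (line, band) distribution of each
arm's survivors at their last trial visit. Occupancy is propagated
o⁺ = o·P with pay-offs accrued at cycle-start occupancy and discounted
to randomisation; mass conservation is checked to 1e-10 each cycle.
The ICER trajectory adds cumulative extrapolated increments to the
trial-period adjusted ΔC/ΔE.

## 6. Decision analysis (`artcea.decision`)

PSA families are standard practice (the source analysis does not print
its choices): Dirichlet rows with observed counts as concentration
(structural second→first-line zeros preserved; other zero-count
destinations get a 0.5 pseudo-count — sparse rows are therefore
slightly shrunk), Gamma cost pay-offs matched to stratum mean/SE, Beta
utilities for states 2–4 (SE 0.05, draws re-ordered to preserve
monotonicity), Normal draws for the trial-period base ΔC/ΔE using
bootstrap SDs. The CEAC reports the fraction of draws with positive
net monetary benefit on a $0–5000 grid ($50 steps).

Thresholds: WHO benchmark λ = 3 × weighted per-capita GDP (defaults —
Uganda $415, Zimbabwe $365, weights 0.7/0.3 — are config inputs chosen
to reproduce the $1,200 2008 benchmark for the two countries); the
fixed-budget rule uses the ICER of CDM against a configurable "no ART"
comparator (cost $250, 1.5 QALYs by default; the comparator of the
source analysis is unpublished, so these are illustrative config
inputs, and the resulting λ is lower than published per-centre
values). The break-even CD4 price is the exact affine inversion
c* = (λ·ΔE − ΔC₀)/Δn with Δn the discounted incremental number of
costed CD4 tests (trial + extrapolation).

## 7. Numerical and degenerate-input choices

* Ties and boundaries: an exit exactly on an 84-day interval boundary
  closes the preceding interval; deaths occurring after a patient's
  scheduled end within the same cycle are recorded as administrative
  censoring.
* Empty pay-off strata borrow the pooled-arm mean with a warning;
  unoccupied transition rows become identity rows with a warning; ages
  beyond the life table carry the last rate forward with a warning.
* Bootstrap label ordering uses ±1e18 sentinels so percentile
  interpolation stays defined near "Dominated"/"Dominant".
* The analytic person-cycle expectation used by `calibrate_to_targets`
  averages mortality over a fixed band-occupancy profile
  (0.09/0.27/0.64, with 0.03 of person-time at the sub-50 hazard)
  describing a recovering cohort; it agrees with realised person-cycles
  to well under 1 cycle, which is inside the Monte-Carlo tolerance of
  every calibration target.

## 8. What the synthetic cohort shows — and does not

Passing tests establish that the *estimators and models are correct
and internally consistent* (exact reductions, closed forms, parameter
recovery, conservation, affine inversion) and that a cohort matching
the published summary statistics reproduces the published incremental
costs within Monte-Carlo tolerance. They do not validate the clinical
realism of individual trajectories: CD4 dynamics, event correlations,
per-centre case-mix and adherence behaviour are stylised. Quantities
that depend on unpublished micro-structure (e.g. the exact last-two-
year transition matrices, hence the extrapolated QALY gain and the
absolute break-even CD4 prices) match the published results in shape
and ordering but not necessarily in magnitude; our optimistic
extrapolation accrues a larger long-term QALY gain than the source
analysis, so its break-even prices are correspondingly higher.

Problem sizes used by the default test run: the full 3,316-patient
cohort for calibration and qualitative checks, 2,000 bootstrap
replicates, 100–200 PSA draws in tests (500 by default in the CLI),
200 simulated datasets × 400 replicates for bootstrap coverage, and
10⁵ simulated transitions for matrix recovery.
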