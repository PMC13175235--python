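# Methods

This note documents the model as implemented: its structure and
assumptions, how every input is turned into a per-cycle quantity, the cost
and QALY rules, the sensitivity-analysis design, what the synthetic-data
generator does and does not emulate, and the places where the published
source material is internally inconsistent and a choice had to be made.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model structure

A Markov cohort model with daily cycles over four states — stable at home
(HOME), emergency-department visit (ED), hospital (HOSPITAL), dead (DEAD)
— run for 3,652 cycles (10 years × 365.25 d/y). Expected-value occupancy
is propagated deterministically; an individual-level microsimulation with
the identical transition rules acts as an independent oracle (the two must
agree within Monte-Carlo error, which the tests enforce).

Per cycle, in order:

1. **Death first.** A constant all-cause daily hazard applies in every
   alive state; survivors' remaining transition probabilities act on the
   surviving mass. Resolving death first avoids probability overflow when
   per-day probabilities are perturbed upward in sensitivity analyses.
2. **HOME** survivors visit the ED (p_ed), are admitted directly
   (p_hosp_direct), or stay home.
3. **ED** occupancy lasts exactly one cycle: survivors are admitted with
   probability 71% (SOC) / 69% (EPOCA) or return home. ED visits are
   events, not durations, in the source data.
4. **HOSPITAL** stays are geometric: daily discharge probability
   1/mean LOS (7.7 d SOC, 7.3 d EPOCA). A memoryless stay is the only
   structure a daily Markov model supports without tunnel states; a
   fixed-length tunnel variant (`los_model: fixed`, stay = round(mean LOS))
   is provided for structural sensitivity.
5. **DEAD** is absorbing.

Entry: 22% of the SOC cohort starts in the ED (their enrolment visit),
EPOCA starts entirely at home — patients enrolled during an ED visit avoid
the immediate admission. By default the enrolment-day ED visit and its
next-day admission are *excluded* from event counts and costs
(`count_entry_events: false`): the published per-patient totals equal
annual rate × mean survival with no entry increment (6.1 ≈ 3.4 × 1.77),
so the source analysis evidently did not count the inclusion visit as
follow-up use. The entry occupancy still shapes day-0/1 dynamics and
hospital days.

No half-cycle correction is applied; at daily cycle length it changes
totals by well under 0.1%.

## From published inputs to per-cycle quantities

**Rates → probabilities.** Annual event rates were measured per calendar
(alive) person-year, but events can only fire on at-home days. The daily
at-home probability is `1 − exp(−(r/c)/365.25)` with the occupancy
correction c chosen by fixed point against the cohort engine itself:
run the arm, measure realized events per alive person-year, rescale c
until realized = r (tolerance 1e−10, converges in ~8 rounds; c ≈ 0.89 for
SOC, 0.94 for EPOCA). The direct-admission rate is the total
hospitalization rate minus the post-ED admission flow
(r_hosp − r_ed × p_admit), so total hospitalizations — direct plus
post-ED — reproduce the observed rate.

The published *monthly* transition probabilities (1.9/3.5 SOC, 1.3/1.6
EPOCA) are numerically irreconcilable with the published event totals
under any cycle interpretation; the annual rates are used instead, and the
monthly rows serve only as relative uncertainty anchors in the sensitivity
analyses.

**Mortality.** A constant daily hazard (no age trend; no life table is
named by the source) calibrated by root bracketing against the engine's
alive-day sum so that undiscounted mean survival over the horizon equals
1.766 years — the value implied by published outpatient totals
(10,277 € ÷ 5,820 €/y), which the source text rounds to 1.8. Calibrated
value: p ≈ 1/647 per day. Set `target_mean_survival_years: 1.8` to
calibrate to the rounded figure instead.

**Programme participation.** 59% exit at day 183, 41% at day 365; 22% of
the year-1 cohort continues at each subsequent year start (geometric).
This reproduces the published 8.1-month average enrolled duration once
mortality is applied.

## Costs and QALYs

Costs are €2025, accrued per expected flow with daily discounting
(1.025^(−day/365.25)); undiscounted twins are always carried.

* **Hospitalization**: a lump sum per admission. Default: every admission
  in an arm is priced at that arm's per-hospitalization unit cost (€3,714
  EPOCA / €3,773 SOC), because the published cost table equals
  count × arm unit cost exactly. The separately published post-ED
  admission price (€4,249) is retained and applied when
  `use_post_ed_admission_cost: true`. Collective perspective uses these
  production costs; the payer divides them by the tariff ratio 1.27.
* **ED visits**: €165.25/visit collective (back-derived from the published
  collective ED totals, 1,008 € ÷ 6.1 visits — the only self-consistent
  value; no collective unit price is printed) and €52/visit payer. The
  source text restricts payer ED costs to non-admitted visits, but its
  results table charges all visits; the default follows the table, with
  `nhi_ed_nonadmitted_only: true` for the textual rule.
* **Outpatient care**: arm annual cost ÷ 365.25 per alive day, identical
  in both perspectives by default (again matching the results table); the
  stated 65% payer reimbursement fraction is available via
  `nhi_outpatient_fraction_applied: true`.
* **Programme** (EPOCA only): €2,210 at each year start × enrolled
  fraction × surviving fraction, identical across perspectives. This
  yields ≈ €2,526/patient; the published €2,850 matches the same schedule
  *without* the mortality adjustment (2,210 × Σ 0.22^y ≈ €2,833), which
  `program_cost_mortality_adjusted: false` reproduces. The model reports
  its own value by default.

**QALYs** add 0.8/365.25 per alive day (age-adjusted population utility)
and subtract 0.0013 per hospital day (a heart-failure-derived inpatient
disutility, the closest available source population); both discounted.
QALYs are perspective-independent. The entire QALY gain in this model
comes from avoided hospital days; survival is identical across arms by
construction (same mortality hazard).

## Waning scenarios

Base case: patients retain EPOCA event rates for life after exit (the
pilot observed post-exit rates close to on-programme rates). Under waning,
the fraction of the cohort that exited more than L days ago (L = 0, 91,
183) reverts to SOC transition rates, unit costs and outpatient intensity;
per-day probabilities are the enrolment-lagged mixture of the two arms'
values.

The implementation reproduces the published *ordering* of payer savings
(immediate < 3-month lag < 6-month lag < lifelong) and dominance in every
scenario, but not the published magnitudes: with this package the
immediate-waning saving is ≈ €1,237 vs a published €3,912. Working
backwards, the published waning results imply roughly 14 months of
effective on-EPOCA exposure under *immediate* waning, while the same
paper's participation schedule — which this model reproduces exactly,
including the 8.1-month average duration — caps it at ~8 months. No
reading of the source text reconciles the two; the package reports its own
schedule-consistent values and flags the discrepancy rather than fitting
to the published waning table.

## Deterministic sensitivity analysis

Each registry parameter moves one-way to its published 95% CI bounds
(monthly-probability CIs applied as relative bounds on the annual rates;
±20% where no CI exists: baseline utility, programme cost). Output is the
incremental discounted cost (net monetary benefit at €30,000/QALY via
`metric="nmb"`), in tornado order. Two additions:

* a joint entry scaling both arms' admission prices by one relative
  factor — the claim that the intervention stays cost-saving or
  cost-neutral under low hospitalization costs only holds when the arms
  move together (at the SOC lower bound alone the intervention is
  dominated, since the comparator becomes artificially cheap);
* mean age is carried (it has a printed CI) but has no effect: the model
  has no age-dependent rates and time runs from enrolment. The published
  tornado names age as influential in the collective perspective; that
  cannot be reproduced without an unstated age–mortality link.

## Probabilistic sensitivity analysis

2,000 draws by default (the source does not state its number), fixed seed,
independent across parameters and across arms (separate rows with separate
CIs). Mortality is held fixed (not varied in the published table). CEAC
grid: €0–100,000/QALY in €1,000 steps.

Distributions follow the published families and are fitted to the printed
mean plus the printed 95% CI — the column explicitly labelled as the
PSA/DSA input. Normal/gamma/beta use sd = CI width/3.92 (beta
moment-matched); lognormal takes σ from the CI in log space with μ
anchored so the distribution mean equals the printed mean. The printed SDs
for unit costs are patient-level dispersions (for the post-ED price the SD
exceeds the mean), not standard errors, and are therefore not used as
parameter-level uncertainty.

Unit costs are propagated at the *event* level: their printed CIs span
per-admission cost variability, so one model draw re-draws the cost of
each expected admission, making the uncertainty of an arm's mean admission
cost shrink as σ/√N with N that draw's admissions per patient. Treating
those wide CIs as uncertainty about the population mean would swamp every
other parameter; treating them as standard errors of the pilot mean would
make the PSA nearly degenerate. The event-level reading is also the
natural one for a patient-level simulation, which the per-patient SDs in
the published results table indicate the original Excel model was.

Draws violating model support (negative rates or LOS < 1 day, direct
admission rate below zero, probabilities outside (0,1)) are resampled and
counted; at the default inputs no resampling occurs.

## Synthetic pilot data

`generate_cohort` emulates the pilot's observation structure: a 183-day
retrospective baseline window at SOC rates (no mortality — pilot patients
survived to inclusion), a 229-day follow-up window at intervention rates,
30% ED-route enrolment, administrative censoring at window end. Events are
daily Bernoulli processes on at-home days; each ED visit may be admitted
the next day; stays are geometric; per-admission costs are lognormal with
the published patient-level moments. A per-patient gamma frailty
(shape 1.0, mean 1, shared across event types) reproduces the
overdispersion of the published annualized counts; the at-home correction
is computed under the frailty distribution (fixed point on E[g·home(g)])
so realized calendar-time rates still equal the targets. Shape 1.0 matches
the published baseline hospitalization SD; the intervention-phase SD
(4.2 around 2.4) would need shape ≈ 0.4 — no single shape matches all four
printed SDs, and 1.0 is kept.

Estimators: rates = events / person-years (calendar alive time by default,
mirroring how the pilot measured; out-of-hospital time via
`exposure="at_home"` recovers the generating hazards directly), with
cluster-robust ratio-estimator SEs valid under frailty; the post-ED
admission probability is estimated over the risk set of ED visits whose
following day is observable, removing censoring bias; LOS and admission
costs as sample means of event records.

What the generator does **not** emulate: claims-data coding artefacts,
readmission clustering beyond frailty, seasonality, covariates (age, sex),
the pilot's exact censoring pattern (why a third of participants lacked
sufficient follow-up is unknown; administrative censoring is assumed), or
informative dropout. Passing recovery tests therefore show estimator
correctness under the model's own assumptions, not robustness to real
claims data.

## Numerical choices and degenerate inputs

* Year length 365.25 d; year starts at day round(365.25·y).
* Occupancy fixed point: tolerance 1e−10, ≤30 rounds; mortality
  calibration: brentq on (1e−9, 0.5), xtol 1e−14; unattainable targets
  (≥ horizon-limited maximum) raise a calibration error.
* Occupancy conservation is maintained to 1e−12 per cycle (tested).
* Zero rates, zero discount and zero mortality are exact special cases
  (no divisions by zero; tested identities).
* Batched evaluation: PSA/DSA stack parameter sets into array-valued
  fields and run the engine once with a leading batch axis; scalar and
  batched paths share the same code.
* All stochastic components (microsimulation, PSA, generator) take a seed
  and are reproducible bit-for-bit; the packaged config carries a required
  seed field.

## Problem sizes

The shipped analyses use 3,652 daily cycles, 2,000 PSA draws, 50,000
microsimulation patients for oracle checks and 5,000 synthetic patients
for recovery checks — sizes at which Monte-Carlo error is well below the
decision margins while the full pipeline runs in minutes on one CPU.

## Known limitations

* Constant mortality shared by both arms: the intervention cannot extend
  life here, so QALY gains are bounded by hospital-day disutility; the
  published 0.04 QALY gain is matched at ≈ 0.037 but any survival effect
  of the programme is outside the model.
* SOC hospital days come out at ≈ 60 vs a published 55.6 (the published
  value implies a realized stay of 7.1 d, below its own 7.7 d input);
  the discrepancy is not resolvable from the source and does not affect
  the intervention arm.
* Effectiveness inputs derive from a pre/post comparison without a control
  group; the model inherits any regression-to-the-mean bias in them.
* The waning magnitudes and the payer PSA dominance probability of the
  original analysis are not fully reproducible from its stated methods
  (see the waning and PSA sections above); the package prefers internal
  consistency over curve-fitting to the published numbers.
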