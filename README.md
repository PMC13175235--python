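# epoca-model

A cost-utility model of the EPOCA remote tele-monitoring programme versus
standard of care (SOC) for frail, polypathological adults aged ≥75 — the
population in which avoidable emergency-department (ED) visits and
hospitalizations concentrate. The package is written for health economists
and HTA analysts who want a tested, scriptable re-implementation of the
published analysis: a daily-cycle Markov cohort model with four health
states (stable at home, ED visit, hospital, dead), two-perspective cost
accounting (French National Health Insurance payer vs collective), QALY
accrual, waning scenarios, one-way and probabilistic sensitivity analysis,
and a synthetic patient-trajectory generator that stands in for the pilot
data the original inputs came from.

## The model

Patients enter at enrolment (SOC: 22% in the ED, the rest at home; EPOCA:
all at home) and move daily for 10 years. Death is resolved first each
cycle with a constant hazard calibrated so undiscounted mean survival
matches the observed 1.8 years. Annual event rates r (ED visits 3.4 → 1.6,
hospitalizations 4.4 → 2.4 per person-year under SOC → EPOCA) convert to
daily at-home probabilities

    p = 1 − exp(−(r / c) / 365.25)

where the occupancy correction *c* (fraction of alive time at home, found
by fixed point against the engine itself) keeps the *realized* events per
alive person-year equal to r. ED occupancy lasts one cycle, after which
71%/69% of visits are admitted; hospital stays are geometric with mean
7.7/7.3 days. Costs accrue per admission, per ED visit, per outpatient day
and per programme-year; QALYs accrue at the age-adjusted baseline utility
0.8/year minus 0.0013 per hospital day; everything is discounted at
2.5%/year. The incremental result is Δcost/ΔQALY (EPOCA − SOC), with
dominance when Δcost < 0 and ΔQALY > 0.

An individual-level microsimulation implements the identical transition
rules and serves as an independent oracle for the cohort engine.

## Worked example

```python
import epoca_model as em

params = em.load_params()                  # published inputs (€2025)
inputs = em.derive_model_inputs(params)    # calibrate mortality + occupancy

soc = em.run_cohort(em.Arm.SOC, params, inputs=inputs)
epoca = em.run_cohort(em.Arm.EPOCA, params, inputs=inputs)
print(soc.events_total("ed_visits", params),
      epoca.events_total("ed_visits", params))
# 6.004399999982257 2.8255999999988695

for persp in em.Perspective:
    e, s, inc = em.evaluate_strategies(params, persp, inputs=inputs)
    print(persp.value, round(inc.delta_cost), round(inc.delta_qaly, 4),
          inc.status)
# collective -10195 0.0372 dominant
# nhi -7081 0.0372 dominant
```

Per patient over ten years, EPOCA averages 2.8 ED visits and 4.2
hospitalizations (30.6 hospital days) against 6.0 and 7.8 under SOC,
saving €10,195 discounted (€10,734 undiscounted) from the collective
perspective and €7,081 (€7,485) from the payer perspective while adding
0.037 QALYs — dominant under both perspectives. A 2,000-draw PSA
(`em.run_psa`) puts the probability of dominance at 90.9% and the
probability of cost-effectiveness at €30,000/QALY at 93.0% (collective).

The same computations are packaged as a CLI (`epoca-model run|psa|dsa|
synth|estimate`) and as narrative drivers under `analysis/`
(`01_base_case.py` … `05_synthetic_pilot.py`), which write their tables
under `results/`.

## Configuration

All inputs live in a YAML file (`src/epoca_model/data/default_params.yaml`
is the packaged default reproducing the published table); pass an
alternative via `load_params(path)` or `--config`. Structural switches
(entry-event counting, post-ED admission pricing, the payer ED and
outpatient rules, programme-cost mortality adjustment, fixed-length
hospital stays) are documented in `docs/methods.md`.
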