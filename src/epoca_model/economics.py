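"""Health-economic layer: costs by category under the payer (NHI) and
collective perspectives, QALY accrual, discounting and incremental results.

Cost rules
----------
* Hospitalizations are lump sums per admission.  By default every admission
  is priced at the arm's per-hospitalization unit cost (the published
  per-arm averages); a switch prices post-ED admissions separately.
  The collective perspective uses production costs; the payer perspective
  divides them by the tariff ratio (tariffs ≈ production costs / 1.27).
* ED visits are priced per visit: a collective unit cost (back-derived from
  the published totals) and a payer tariff of €52.  By default the payer is
  charged for all visits (matching the published payer totals); a switch
  restricts payer ED costs to visits that did not end in admission.
* Outpatient care accrues per alive day at the arm's annual cost; identical
  in both perspectives by default, with a switch applying the 65% NHI
  reimbursement fraction.
* The programme cost is charged at the start of each year to the fraction
  still enrolled (by default also scaled by the surviving fraction), in
  both perspectives.

QALYs add the age-adjusted baseline utility per alive day and subtract a
disutility per hospital day; they are perspective-independent.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd

from .parameters import (
    Arm,
    BASE_SCENARIO,
    DAYS_PER_YEAR,
    ModelInputs,
    ParameterSet,
    Scenario,
    _year_start_days,
    derive_model_inputs,
    enrolled_fraction,
)
from .markov import TrajectoryResult, run_cohort


class Perspective(enum.Enum):
    COLLECTIVE = "collective"
    NHI = "nhi"


COST_CATEGORIES = ("program", "ed_visits", "hospitalization", "outpatient")


def discount_factor(day_index, rate: float = 0.025):
    """Continuous-time annual discounting applied at daily resolution."""
    day_index = np.asarray(day_index, dtype=float)
    out = (1.0 + rate) ** (-day_index / DAYS_PER_YEAR)
    return out if out.ndim else float(out)


@dataclass
class ArmOutcome:
    """Per-patient expected events, costs (€, by category) and QALYs for
    one arm under one perspective.  Values may carry a batch axis."""

    arm: Arm
    perspective: Perspective
    events: dict[str, Any]
    costs: dict[str, Any]          # category -> undiscounted
    costs_disc: dict[str, Any]     # category -> discounted
    qaly: Any
    qaly_disc: Any
    life_years: Any
    life_years_disc: Any

    @property
    def total_cost(self):
        return self.costs["total"]

    @property
    def total_cost_disc(self):
        return self.costs_disc["total"]


@dataclass
class IncrementalResult:
    """EPOCA minus SOC on discounted values, with dominance classification."""

    delta_cost: float
    delta_qaly: float
    status: str            # "dominant" | "dominated" | "icer" | "equivalent"
    icer: float            # €/QALY, NaN unless status == "icer"
    delta_cost_undiscounted: float | None = None


def _admission_unit_costs(params: ParameterSet, perspective: Perspective):
    c_e = np.asarray(params.cost_hosp.epoca, dtype=float)
    c_s = np.asarray(params.cost_hosp.soc, dtype=float)
    c_p = np.asarray(params.cost_hosp_post_ed, dtype=float)
    if perspective is Perspective.NHI:
        tr = np.asarray(params.tariff_ratio, dtype=float)
        return c_e / tr, c_s / tr, c_p / tr
    return c_e, c_s, c_p


def accrue_costs(traj: TrajectoryResult, arm: Arm, params: ParameterSet,
                 perspective: Perspective,
                 unit_cost_overrides: dict[str, Any] | None = None,
                 ) -> tuple[dict, dict]:
    """Cost components (€/person) from a trajectory, as
    ``(undiscounted, discounted)`` dicts over categories plus ``total``.

    ``unit_cost_overrides`` lets the PSA substitute per-draw unit-cost
    arrays (keys ``cost_hosp_epoca``, ``cost_hosp_soc``, ``cost_hosp_post_ed``,
    ``cost_ed_visit`` as a multiplier on both perspectives' ED prices).
    """
    t = traj.totals
    ov = unit_cost_overrides or {}
    include_entry = params.count_entry_events

    c_e, c_s, c_p = _admission_unit_costs(params, perspective)
    if "cost_hosp_epoca" in ov or "cost_hosp_soc" in ov or "cost_hosp_post_ed" in ov:
        c_e = np.asarray(ov.get("cost_hosp_epoca", params.cost_hosp.epoca), dtype=float)
        c_s = np.asarray(ov.get("cost_hosp_soc", params.cost_hosp.soc), dtype=float)
        c_p = np.asarray(ov.get("cost_hosp_post_ed", params.cost_hosp_post_ed), dtype=float)
        if perspective is Perspective.NHI:
            tr = np.asarray(params.tariff_ratio, dtype=float)
            c_e, c_s, c_p = c_e / tr, c_s / tr, c_p / tr

    costs_u: dict[str, Any] = {}
    costs_d: dict[str, Any] = {}
    for sfx, out in (("", costs_u), ("_disc", costs_d)):
        direct = t["adm_direct" + sfx]
        direct_fw = t["adm_direct_fw" + sfx]
        post = t["adm_post" + sfx]
        post_fw = t["adm_post_fw" + sfx]
        if include_entry:
            post = post + t["adm_entry" + sfx]
            post_fw = post_fw + t["adm_entry_fw" + sfx]
        if params.use_post_ed_admission_cost:
            hosp_cost = (direct_fw * c_e + (direct - direct_fw) * c_s
                         + post * c_p)
        else:
            adm = direct + post
            adm_fw = direct_fw + post_fw
            hosp_cost = adm_fw * c_e + (adm - adm_fw) * c_s
        out["hospitalization"] = hosp_cost

        visits = t["ed_visits" + sfx]
        nonadmitted = t["ed_nonadmitted" + sfx]
        if include_entry:
            visits = visits + t["ed_visits_entry" + sfx]
            nonadmitted = nonadmitted + t["ed_nonadmitted_entry" + sfx]
        ed_mult = np.asarray(ov.get("cost_ed_visit", 1.0), dtype=float)
        if perspective is Perspective.COLLECTIVE:
            out["ed_visits"] = visits * np.asarray(
                params.cost_ed_visit_collective, dtype=float) * ed_mult
        else:
            charged = nonadmitted if params.nhi_ed_nonadmitted_only else visits
            out["ed_visits"] = charged * np.asarray(
                params.cost_ed_visit_payer, dtype=float) * ed_mult

        alive = t["alive_days" + sfx]
        alive_fw = t["alive_fw_days" + sfx]
        out_e = np.asarray(params.outpatient_annual.epoca, dtype=float)
        out_s = np.asarray(params.outpatient_annual.soc, dtype=float)
        outp = (alive_fw * out_e + (alive - alive_fw) * out_s) / DAYS_PER_YEAR
        if (perspective is Perspective.NHI
                and params.nhi_outpatient_fraction_applied):
            outp = outp * np.asarray(params.outpatient_nhi_fraction, dtype=float)
        out["outpatient"] = outp

    costs_u["program"], costs_d["program"] = _program_cost(traj, arm, params)
    for out in (costs_u, costs_d):
        out["total"] = sum(out[c] for c in COST_CATEGORIES)
    return costs_u, costs_d


def _program_cost(traj: TrajectoryResult, arm: Arm, params: ParameterSet):
    """Annual programme payments to the enrolled (surviving) fraction;
    identical across perspectives."""
    if arm is not Arm.EPOCA:
        zero = np.zeros(np.shape(traj.totals["alive_days"]))
        z = zero if zero.ndim else 0.0
        return z, z
    r_disc = float(np.asarray(params.discount_rate_annual, dtype=float).ravel()[0])
    year_starts = _year_start_days(params.horizon_years)
    year_starts = year_starts[year_starts < traj.n_days]
    annual = np.asarray(params.program_cost_annual, dtype=float)
    total_u = 0.0
    total_d = 0.0
    for i, day in enumerate(year_starts):
        frac = enrolled_fraction(int(day), params)
        alive = (traj.alive_at_year_start[..., i]
                 if params.program_cost_mortality_adjusted else 1.0)
        pay = annual * frac * alive
        total_u = total_u + pay
        total_d = total_d + pay * discount_factor(int(day), r_disc)
    return total_u, total_d


def accrue_qalys(traj: TrajectoryResult, params: ParameterSet):
    """QALYs/person: baseline utility per alive day minus the per-day
    hospitalization disutility, as ``(undiscounted, discounted)``."""
    u = np.asarray(params.utility_baseline, dtype=float)
    dis = np.asarray(params.disutility_hosp_day, dtype=float)
    t = traj.totals
    q_u = u * t["alive_days"] / DAYS_PER_YEAR - dis * t["hosp_days"]
    q_d = u * t["alive_days_disc"] / DAYS_PER_YEAR - dis * t["hosp_days_disc"]
    return q_u, q_d


def evaluate_arm(arm: Arm, params: ParameterSet,
                 perspective: Perspective,
                 scenario: Scenario = BASE_SCENARIO,
                 inputs: ModelInputs | None = None,
                 traj: TrajectoryResult | None = None,
                 unit_cost_overrides: dict | None = None) -> ArmOutcome:
    """Run (or reuse) a trajectory and convert it into an ArmOutcome."""
    if traj is None:
        if inputs is None:
            inputs = derive_model_inputs(params)
        traj = run_cohort(arm, params, scenario=scenario, inputs=inputs)
    costs_u, costs_d = accrue_costs(traj, arm, params, perspective,
                                    unit_cost_overrides)
    q_u, q_d = accrue_qalys(traj, params)
    t = traj.totals
    events = {
        "ed_visits": traj.events_total("ed_visits", params),
        "hospitalizations": traj.events_total("hospitalizations", params),
        "hospital_days": t["hosp_days"],
    }
    return ArmOutcome(
        arm=arm, perspective=perspective, events=events,
        costs=costs_u, costs_disc=costs_d,
        qaly=q_u, qaly_disc=q_d,
        life_years=t["alive_days"] / DAYS_PER_YEAR,
        life_years_disc=t["alive_days_disc"] / DAYS_PER_YEAR,
    )


def incremental(epoca: ArmOutcome, soc: ArmOutcome) -> IncrementalResult:
    """EPOCA vs SOC on discounted cost and QALYs."""
    dc = float(np.asarray(epoca.total_cost_disc - soc.total_cost_disc))
    dq = float(np.asarray(epoca.qaly_disc - soc.qaly_disc))
    dcu = float(np.asarray(epoca.total_cost - soc.total_cost))
    if dc == 0.0 and dq == 0.0:
        return IncrementalResult(0.0, 0.0, "equivalent", float("nan"), dcu)
    if dc < 0 and dq > 0:
        return IncrementalResult(dc, dq, "dominant", float("nan"), dcu)
    if dc > 0 and dq < 0:
        return IncrementalResult(dc, dq, "dominated", float("nan"), dcu)
    icer = dc / dq if dq != 0 else float("inf")
    return IncrementalResult(dc, dq, "icer", icer, dcu)


def evaluate_strategies(params: ParameterSet, perspective: Perspective,
                        scenario: Scenario = BASE_SCENARIO,
                        inputs: ModelInputs | None = None):
    """Both arms plus the incremental result (SOC always runs base-case:
    waning only alters the intervention arm)."""
    if inputs is None:
        inputs = derive_model_inputs(params)
    epoca = evaluate_arm(Arm.EPOCA, params, perspective, scenario, inputs)
    soc = evaluate_arm(Arm.SOC, params, perspective, BASE_SCENARIO, inputs)
    return epoca, soc, incremental(epoca, soc)


def results_table(params: ParameterSet,
                  scenario: Scenario = BASE_SCENARIO,
                  inputs: ModelInputs | None = None) -> pd.DataFrame:
    """Tidy results table: resource use, per-category costs under both
    perspectives (discounted and undiscounted), QALYs and increments."""
    if inputs is None:
        inputs = derive_model_inputs(params)
    rows = []
    outcomes = {}
    for persp in Perspective:
        e, s, inc = evaluate_strategies(params, persp, scenario, inputs)
        outcomes[persp] = (e, s, inc)
    e0, s0, _ = outcomes[Perspective.COLLECTIVE]
    for name in ("ed_visits", "hospitalizations", "hospital_days"):
        rows.append(("resource_use", name, "", float(np.asarray(e0.events[name])),
                     float(np.asarray(s0.events[name]))))
    for persp in Perspective:
        e, s, inc = outcomes[persp]
        p = persp.value
        for cat in COST_CATEGORIES + ("total",):
            rows.append((f"cost_undiscounted_{p}", cat, "€",
                         float(np.asarray(e.costs[cat])),
                         float(np.asarray(s.costs[cat]))))
        for cat in COST_CATEGORIES + ("total",):
            rows.append((f"cost_discounted_{p}", cat, "€",
                         float(np.asarray(e.costs_disc[cat])),
                         float(np.asarray(s.costs_disc[cat]))))
        rows.append((f"cost_effectiveness_{p}", "discounted_qaly", "QALY",
                     float(np.asarray(e.qaly_disc)), float(np.asarray(s.qaly_disc))))
    df = pd.DataFrame(rows, columns=["section", "category", "unit",
                                     "epoca", "soc"])
    df["difference"] = df["epoca"] - df["soc"]
    return df
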