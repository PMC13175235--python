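"""Deterministic (tornado) and probabilistic sensitivity analysis.

The uncertain-parameter registry mirrors the published parameter table:
each entry carries its deterministic bounds (the printed 95% CI, or ±20%
where no CI exists) and, where applicable, a PSA sampling family fitted to
the printed mean and CI.

Two kinds of uncertainty are propagated in the PSA:

* ``param``-level entries (event rates, admission probability, length of
  stay, outpatient annual cost, disutility) are drawn once per draw —
  classic parameter uncertainty;
* ``event``-level entries (per-admission and per-visit unit costs, whose
  printed CIs span patient-level cost variability rather than uncertainty
  of a mean) are re-drawn for every admission the draw produces, so the
  uncertainty of the arm's mean unit cost shrinks with the number of
  admissions per patient (σ/√N on the log scale).

Mean age is carried in the registry (it has a printed CI and PSA family)
but has no effect on outputs: the model has no age-dependent rates and
time runs from enrolment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .parameters import (
    Arm,
    BASE_SCENARIO,
    DistributionSpec,
    ParameterSet,
    Sampler,
    Scenario,
    derive_model_inputs,
    fit_distribution,
    stack_parameter_sets,
)
from .markov import run_cohort
from .economics import Perspective, evaluate_arm

log = logging.getLogger(__name__)

DEFAULT_WTP_GRID = np.arange(0, 100_001, 1_000)


@dataclass(frozen=True)
class SensitivityParam:
    """One uncertain parameter: deterministic bounds and PSA distribution."""

    name: str
    base: float
    low: float
    high: float
    setter: Callable[[ParameterSet, object], ParameterSet]
    family: str | None = None      # None -> deterministic analysis only
    level: str = "param"           # "param" | "event" | "inert"

    def sampler(self) -> Sampler | None:
        if self.family is None:
            return None
        return fit_distribution(DistributionSpec(
            family=self.family, mean=self.base, ci95=(self.low, self.high)))


def _arm_setter(field: str, arm: Arm):
    def setter(p: ParameterSet, v):
        return p.with_arm_value(field, arm, v)
    return setter


def _field_setter(field: str):
    def setter(p: ParameterSet, v):
        return p.replace(**{field: v})
    return setter


def _hosp_cost_both_setter(p: ParameterSet, rel):
    """Scale both arms' per-hospitalization production costs jointly."""
    av = p.cost_hosp
    return p.replace(cost_hosp=type(av)(epoca=av.epoca * rel, soc=av.soc * rel),
                     cost_hosp_post_ed=p.cost_hosp_post_ed * rel)


def _ed_cost_setter(p: ParameterSet, v):
    """Move the payer ED tariff; the collective unit cost scales with it."""
    ratio = p.cost_ed_visit_collective / p.cost_ed_visit_payer
    return p.replace(cost_ed_visit_payer=v, cost_ed_visit_collective=v * ratio)


def build_registry(params: ParameterSet) -> list[SensitivityParam]:
    """Uncertain parameters with printed-CI bounds (±20% where absent).

    The monthly-probability rows of the published table are numerically
    irreconcilable with the reported event totals; their CIs are used only
    as *relative* uncertainty anchors on the annual event rates.
    """
    reg: list[SensitivityParam] = []

    def rel(base, lo_anchor, mid_anchor, hi_anchor):
        return base * lo_anchor / mid_anchor, base * hi_anchor / mid_anchor

    lo, hi = rel(params.annual_hosp_rate.soc, 1.8, 1.9, 2.0)
    reg.append(SensitivityParam("annual_hosp_rate.soc", params.annual_hosp_rate.soc,
                                lo, hi, _arm_setter("annual_hosp_rate", Arm.SOC),
                                "normal"))
    lo, hi = rel(params.annual_hosp_rate.epoca, 1.2, 1.3, 1.4)
    reg.append(SensitivityParam("annual_hosp_rate.epoca",
                                params.annual_hosp_rate.epoca, lo, hi,
                                _arm_setter("annual_hosp_rate", Arm.EPOCA),
                                "normal"))
    lo, hi = rel(params.annual_ed_rate.soc, 3.4, 3.5, 3.6)
    reg.append(SensitivityParam("annual_ed_rate.soc", params.annual_ed_rate.soc,
                                lo, hi, _arm_setter("annual_ed_rate", Arm.SOC),
                                "normal"))
    lo, hi = rel(params.annual_ed_rate.epoca, 1.5, 1.6, 1.7)
    reg.append(SensitivityParam("annual_ed_rate.epoca", params.annual_ed_rate.epoca,
                                lo, hi, _arm_setter("annual_ed_rate", Arm.EPOCA),
                                "normal"))
    reg.append(SensitivityParam("p_admit_after_ed.soc", params.p_admit_after_ed.soc,
                                0.64, 0.79, _arm_setter("p_admit_after_ed", Arm.SOC),
                                "beta"))
    reg.append(SensitivityParam("p_admit_after_ed.epoca",
                                params.p_admit_after_ed.epoca, 0.55, 0.83,
                                _arm_setter("p_admit_after_ed", Arm.EPOCA), "beta"))
    reg.append(SensitivityParam("mean_los.soc", params.mean_los.soc, 6.2, 9.2,
                                _arm_setter("mean_los", Arm.SOC), "normal"))
    reg.append(SensitivityParam("mean_los.epoca", params.mean_los.epoca, 5.8, 8.8,
                                _arm_setter("mean_los", Arm.EPOCA), "normal"))
    reg.append(SensitivityParam("mean_age", params.mean_age, 80.8, 95.0,
                                _field_setter("mean_age"), "normal",
                                level="inert"))
    reg.append(SensitivityParam("cost_hosp.epoca", params.cost_hosp.epoca,
                                832.0, 9557.0, _arm_setter("cost_hosp", Arm.EPOCA),
                                "lognormal", level="event"))
    reg.append(SensitivityParam("cost_hosp.soc", params.cost_hosp.soc,
                                1056.0, 8873.0, _arm_setter("cost_hosp", Arm.SOC),
                                "lognormal", level="event"))
    if params.use_post_ed_admission_cost:
        reg.append(SensitivityParam("cost_hosp_post_ed", params.cost_hosp_post_ed,
                                    395.0, 14057.0,
                                    _field_setter("cost_hosp_post_ed"),
                                    "lognormal", level="event"))
    reg.append(SensitivityParam("cost_ed_visit", params.cost_ed_visit_payer,
                                44.0, 61.0, _ed_cost_setter,
                                "lognormal", level="event"))
    reg.append(SensitivityParam("outpatient_annual.epoca",
                                params.outpatient_annual.epoca, 4656.0, 6984.0,
                                _arm_setter("outpatient_annual", Arm.EPOCA),
                                "gamma"))
    reg.append(SensitivityParam("outpatient_annual.soc",
                                params.outpatient_annual.soc, 4270.0, 6404.0,
                                _arm_setter("outpatient_annual", Arm.SOC),
                                "gamma"))
    reg.append(SensitivityParam("disutility_hosp_day", params.disutility_hosp_day,
                                0.0010, 0.0016,
                                _field_setter("disutility_hosp_day"), "beta"))
    # no printed CI -> deterministic ±20%, excluded from PSA
    reg.append(SensitivityParam("utility_baseline", params.utility_baseline,
                                params.utility_baseline * 0.8,
                                params.utility_baseline * 1.2,
                                _field_setter("utility_baseline")))
    reg.append(SensitivityParam("program_cost_annual", params.program_cost_annual,
                                params.program_cost_annual * 0.8,
                                params.program_cost_annual * 1.2,
                                _field_setter("program_cost_annual")))
    # joint variation of hospitalization unit costs (both arms move together)
    reg.append(SensitivityParam("cost_hosp.both_relative", 1.0,
                                1056.0 / params.cost_hosp.soc,
                                8873.0 / params.cost_hosp.soc,
                                _hosp_cost_both_setter))
    return reg


# ---------------------------------------------------------------------------
# batched evaluation

def _evaluate_batch(param_sets: Sequence[ParameterSet],
                    perspective: Perspective,
                    scenario: Scenario,
                    unit_cost_overrides: dict | None = None):
    """Run EPOCA and SOC for a batch of parameter sets; return outcomes."""
    stacked = stack_parameter_sets(list(param_sets))
    inputs = derive_model_inputs(stacked)
    traj_e = run_cohort(Arm.EPOCA, stacked, scenario=scenario, inputs=inputs)
    traj_s = run_cohort(Arm.SOC, stacked, scenario=BASE_SCENARIO, inputs=inputs)
    out_e = evaluate_arm(Arm.EPOCA, stacked, perspective, scenario,
                         traj=traj_e, unit_cost_overrides=unit_cost_overrides)
    out_s = evaluate_arm(Arm.SOC, stacked, perspective, BASE_SCENARIO,
                         traj=traj_s, unit_cost_overrides=unit_cost_overrides)
    return out_e, out_s, traj_e, traj_s


# ---------------------------------------------------------------------------
# deterministic sensitivity analysis

def run_dsa(params: ParameterSet, perspective: Perspective,
            scenario: Scenario = BASE_SCENARIO,
            metric: str = "delta_cost", wtp: float = 30_000.0,
            registry: list[SensitivityParam] | None = None) -> pd.DataFrame:
    """One-way sensitivity analysis over the registry.

    ``metric``: ``delta_cost`` (incremental discounted cost, EPOCA − SOC) or
    ``nmb`` (incremental net monetary benefit at *wtp* €/QALY).  Entries are
    returned in tornado order (largest output range first).
    """
    registry = build_registry(params) if registry is None else registry
    sets = [params]
    for e in registry:
        sets.append(e.setter(params, e.low))
        sets.append(e.setter(params, e.high))
    out_e, out_s, _, _ = _evaluate_batch(sets, perspective, scenario)
    dc = np.asarray(out_e.total_cost_disc - out_s.total_cost_disc)
    dq = np.asarray(out_e.qaly_disc - out_s.qaly_disc)
    vals = wtp * dq - dc if metric == "nmb" else dc
    if metric not in ("delta_cost", "nmb"):
        raise ValueError(f"unknown metric {metric!r}")
    rows = []
    for i, e in enumerate(registry):
        lo_v, hi_v = vals[1 + 2 * i], vals[2 + 2 * i]
        rows.append({
            "parameter": e.name, "input_low": e.low, "input_high": e.high,
            "outcome_low": float(lo_v), "outcome_high": float(hi_v),
            "outcome_base": float(vals[0]),
            "range": float(abs(hi_v - lo_v)),
        })
    df = pd.DataFrame(rows).sort_values("range", ascending=False,
                                        kind="stable").reset_index(drop=True)
    df.attrs["metric"] = metric
    return df


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

@dataclass
class PsaResult:
    """Incremental discounted cost and QALYs per draw, EPOCA − SOC."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    draws: pd.DataFrame
    n_resampled: int
    perspective: Perspective
    seed: int

    def prob_dominant(self) -> float:
        return float(np.mean((self.delta_cost < 0) & (self.delta_qaly > 0)))

    def prob_cost_effective(self, wtp: float = 30_000.0) -> float:
        return float(np.mean(wtp * self.delta_qaly - self.delta_cost > 0))

    def ceac(self, thresholds: np.ndarray | None = None) -> pd.DataFrame:
        return ceac(self.delta_cost, self.delta_qaly, thresholds)


def _joint_invalid(draws: dict[str, np.ndarray], params: ParameterSet) -> np.ndarray:
    """Rows whose sampled values violate model support (negative rates/LOS,
    direct-admission rate below zero, probabilities outside (0,1))."""
    def get(name, default):
        return draws.get(name, np.asarray(default))

    bad = np.zeros(len(next(iter(draws.values()))), dtype=bool)
    for arm, sfx in ((Arm.EPOCA, "epoca"), (Arm.SOC, "soc")):
        r_h = get(f"annual_hosp_rate.{sfx}", params.annual_hosp_rate.for_arm(arm))
        r_e = get(f"annual_ed_rate.{sfx}", params.annual_ed_rate.for_arm(arm))
        p_a = get(f"p_admit_after_ed.{sfx}", params.p_admit_after_ed.for_arm(arm))
        los = get(f"mean_los.{sfx}", params.mean_los.for_arm(arm))
        bad |= (r_h <= 0) | (r_e < 0) | (r_h - r_e * p_a < 0)
        bad |= (los < 1.0)
        bad |= (p_a <= 0) | (p_a >= 1)
    if "disutility_hosp_day" in draws:
        bad |= draws["disutility_hosp_day"] < 0
    return bad


def run_psa(params: ParameterSet, n_draws: int, seed: int,
            perspective: Perspective,
            scenario: Scenario = BASE_SCENARIO,
            fixed_at_mean: bool = False,
            registry: list[SensitivityParam] | None = None) -> PsaResult:
    """Monte-Carlo PSA: sample the registry, re-derive daily probabilities,
    run both arms per draw, and record discounted deltas.

    Mortality is held fixed (the published table does not vary it).  With
    ``fixed_at_mean`` every distribution collapses to its mean — a
    degenerate PSA that must reproduce the base case.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    registry = build_registry(params) if registry is None else registry
    param_entries = [e for e in registry
                     if e.family is not None and e.level in ("param", "inert")]
    event_entries = {e.name: e for e in registry
                     if e.family is not None and e.level == "event"}

    # --- parameter-level draws with joint-support resampling -------------
    samplers = {e.name: e.sampler() for e in param_entries}
    draws = {}
    for e in param_entries:
        if fixed_at_mean:
            draws[e.name] = np.full(n_draws, e.base)
        else:
            draws[e.name] = np.asarray(samplers[e.name].draw(rng, n_draws))
    n_resampled = 0
    for _ in range(100):
        bad = _joint_invalid(draws, params)
        if not bad.any():
            break
        n_resampled += int(bad.sum())
        for e in param_entries:
            if fixed_at_mean:
                continue
            draws[e.name][bad] = np.asarray(samplers[e.name].draw(rng, int(bad.sum())))
        if fixed_at_mean:
            break
    if n_resampled:
        log.info("PSA resampled %d invalid parameter vectors", n_resampled)

    # --- build the batched parameter set ---------------------------------
    sampled = params
    for e in param_entries:
        sampled = e.setter(sampled, draws[e.name])

    inputs = derive_model_inputs(sampled)
    traj_e = run_cohort(Arm.EPOCA, sampled, scenario=scenario, inputs=inputs)
    traj_s = run_cohort(Arm.SOC, sampled, scenario=BASE_SCENARIO, inputs=inputs)

    # --- event-level unit-cost draws (σ/√N on the log scale) --------------
    overrides: dict[str, np.ndarray] = {}

    def _event_cost_draw(entry: SensitivityParam, n_events: np.ndarray):
        m = entry.base
        if fixed_at_mean:
            return np.full(n_draws, m)
        sigma_e = (math.log(entry.high) - math.log(entry.low)) / 3.92
        cv_e2 = math.expm1(sigma_e**2)
        n_eff = np.maximum(np.asarray(n_events, dtype=float), 1e-9)
        sigma_n = np.sqrt(np.log1p(cv_e2 / n_eff))
        z = rng.standard_normal(n_draws)
        return m * np.exp(sigma_n * z - 0.5 * sigma_n**2)

    def _admissions(traj, p):
        t = traj.totals
        out = t["adm_direct"] + t["adm_post"]
        if p.count_entry_events:
            out = out + t["adm_entry"]
        return np.asarray(out)

    if "cost_hosp.epoca" in event_entries:
        n_e = np.asarray(traj_e.totals["adm_direct_fw"]) + \
            np.asarray(traj_e.totals["adm_post_fw"])
        overrides["cost_hosp_epoca"] = _event_cost_draw(
            event_entries["cost_hosp.epoca"], n_e)
        draws["cost_hosp.epoca"] = overrides["cost_hosp_epoca"]
    if "cost_hosp.soc" in event_entries:
        n_s = _admissions(traj_s, params)
        overrides["cost_hosp_soc"] = _event_cost_draw(
            event_entries["cost_hosp.soc"], n_s)
        draws["cost_hosp.soc"] = overrides["cost_hosp_soc"]
    if "cost_hosp_post_ed" in event_entries:
        n_p = np.asarray(traj_e.totals["adm_post"]) + \
            np.asarray(traj_s.totals["adm_post"])
        overrides["cost_hosp_post_ed"] = _event_cost_draw(
            event_entries["cost_hosp_post_ed"], n_p)
        draws["cost_hosp_post_ed"] = overrides["cost_hosp_post_ed"]
    if "cost_ed_visit" in event_entries:
        entry = event_entries["cost_ed_visit"]
        n_v = np.asarray(traj_s.totals["ed_visits"])
        cost_draw = _event_cost_draw(entry, n_v)
        overrides["cost_ed_visit"] = cost_draw / entry.base
        draws["cost_ed_visit"] = cost_draw

    out_e = evaluate_arm(Arm.EPOCA, sampled, perspective, scenario,
                         traj=traj_e, unit_cost_overrides=overrides)
    out_s = evaluate_arm(Arm.SOC, sampled, perspective, BASE_SCENARIO,
                         traj=traj_s, unit_cost_overrides=overrides)
    delta_cost = np.asarray(out_e.total_cost_disc - out_s.total_cost_disc)
    delta_qaly = np.asarray(out_e.qaly_disc - out_s.qaly_disc)
    frame = pd.DataFrame(draws)
    frame["delta_cost"] = delta_cost
    frame["delta_qaly"] = delta_qaly
    return PsaResult(delta_cost=delta_cost, delta_qaly=delta_qaly, draws=frame,
                     n_resampled=n_resampled, perspective=perspective, seed=seed)


def ceac(delta_cost: np.ndarray, delta_qaly: np.ndarray,
         thresholds: np.ndarray | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve:
    P(λ·ΔQALY − ΔCost > 0) over the willingness-to-pay grid."""
    thresholds = DEFAULT_WTP_GRID if thresholds is None else np.asarray(thresholds)
    dc = np.asarray(delta_cost)[None, :]
    dq = np.asarray(delta_qaly)[None, :]
    lam = np.asarray(thresholds, dtype=float)[:, None]
    prob = np.mean(lam * dq - dc > 0, axis=1)
    return pd.DataFrame({"threshold": thresholds, "prob_cost_effective": prob})
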