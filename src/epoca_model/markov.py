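"""Daily-cycle state-transition engine over HOME / ED / HOSPITAL / DEAD.

Two implementations of the same transition rules:

* :func:`run_cohort` — expected-value occupancy propagation (the model
  proper; deterministic, supports a leading batch axis so thousands of
  parameter sets run in one pass);
* :func:`run_microsim` — individual-level Monte-Carlo realization, used as
  an independent oracle for the cohort engine.

Transition rules per cycle (one day): death is resolved first with a
constant all-cause hazard; surviving HOME occupants may visit the ED or be
admitted directly; ED occupancy lasts exactly one cycle, after which the
patient is admitted (post-ED) or returns home; hospital stays are geometric
with daily discharge probability 1/mean LOS (optionally a fixed-length
tunnel); DEAD is absorbing.

Under waning scenarios the EPOCA arm's per-day probabilities are a mixture
of EPOCA and SOC values weighted by the fraction of the cohort still
benefiting; the engine also tracks benefit-weighted accumulators so the
economics layer can price admissions and outpatient days by origin.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .parameters import (
    Arm,
    ArmInputs,
    BASE_SCENARIO,
    DAYS_PER_YEAR,
    ModelInputs,
    ParameterError,
    ParameterSet,
    Scenario,
    _year_start_days,
    benefit_fraction_vector,
    derive_model_inputs,
)


class HealthState(enum.IntEnum):
    HOME = 0
    ED = 1
    HOSPITAL = 2
    DEAD = 3


@dataclass
class StepRates:
    """Per-day transition probabilities applied in one cycle."""

    p_death: Any
    p_ed: Any
    p_hosp_direct: Any
    p_admit: Any
    p_discharge: Any


@dataclass
class CohortState:
    """Occupancy over the four health states plus expected accumulators."""

    day_index: int
    occupancy: np.ndarray  # (..., 4), sums to 1
    cumulative_events: dict = field(default_factory=lambda: {
        "ed_visits": 0.0, "admissions_direct": 0.0, "admissions_post_ed": 0.0})
    cumulative_days: dict = field(default_factory=lambda: {
        "hospital_days": 0.0, "alive_days": 0.0})
    enrolled_fraction: float = 1.0


@dataclass
class TrajectoryResult:
    """Expected per-patient totals over the horizon (scalars, or arrays with
    a leading batch axis).  ``totals`` keys come in undiscounted /
    ``*_disc`` pairs; entry-day events are tracked separately so the
    analysis can include or exclude the enrolment visit."""

    arm: Arm
    scenario: Scenario
    n_days: int
    totals: dict[str, Any]
    alive_at_year_start: np.ndarray  # (..., n_years)
    per_day: pd.DataFrame | None = None
    se: dict[str, float] | None = None
    per_patient: dict[str, np.ndarray] | None = None

    def events_total(self, name: str, params: ParameterSet,
                     discounted: bool = False):
        """Event totals with the entry-day policy applied."""
        sfx = "_disc" if discounted else ""
        t = self.totals
        if name == "ed_visits":
            out = t["ed_visits" + sfx]
            if params.count_entry_events:
                out = out + t["ed_visits_entry" + sfx]
            return out
        if name == "hospitalizations":
            out = t["adm_direct" + sfx] + t["adm_post" + sfx]
            if params.count_entry_events:
                out = out + t["adm_entry" + sfx]
            return out
        raise KeyError(name)


def initial_state(arm: Arm, params: ParameterSet) -> CohortState:
    """Starting occupancy: the ED-entry fraction begins in the ED (eligible
    for admission next cycle), the rest at home; accumulators zero."""
    entry = np.asarray(params.ed_entry_fraction.for_arm(arm), dtype=float)
    occ = np.stack([1.0 - entry, entry, np.zeros_like(entry),
                    np.zeros_like(entry)], axis=-1)
    return CohortState(day_index=0, occupancy=occ)


def _step_flows(home, ed, hosp, dead, r: StepRates):
    """One cycle of expected flows.  Death first; survivors transition."""
    pd_, pe, ph, pa, pdis = (np.asarray(r.p_death), np.asarray(r.p_ed),
                             np.asarray(r.p_hosp_direct), np.asarray(r.p_admit),
                             np.asarray(r.p_discharge))
    if np.any(pe + ph > 1.0) or np.any((pd_ < 0) | (pd_ > 1)) \
            or np.any((pa < 0) | (pa > 1)) or np.any((pdis < 0) | (pdis > 1)):
        raise ParameterError("derived per-day probability outside [0, 1]")
    s = 1.0 - pd_
    home_s, ed_s, hosp_s = home * s, ed * s, hosp * s
    new_dead = dead + (home + ed + hosp) * pd_
    ed_new = home_s * pe
    adm_direct = home_s * ph
    adm_post = ed_s * pa
    ed_home = ed_s - adm_post
    discharge = hosp_s * pdis
    new_home = home_s - ed_new - adm_direct + ed_home + discharge
    new_ed = ed_new
    new_hosp = hosp_s - discharge + adm_direct + adm_post
    flows = {"ed_visits": ed_new, "adm_direct": adm_direct,
             "adm_post": adm_post, "ed_nonadmitted": ed_home}
    return new_home, new_ed, new_hosp, new_dead, flows


def step(state: CohortState, arm: Arm, params: ParameterSet,
         effective_rates: StepRates) -> CohortState:
    """Advance the cohort one day (public single-step contract; the run
    loop uses the same flow kernel)."""
    home, ed, hosp, dead = (state.occupancy[..., i] for i in range(4))
    nh, ne, nhp, nd, flows = _step_flows(home, ed, hosp, dead, effective_rates)
    ev = dict(state.cumulative_events)
    ev["ed_visits"] = ev["ed_visits"] + flows["ed_visits"]
    ev["admissions_direct"] = ev["admissions_direct"] + flows["adm_direct"]
    ev["admissions_post_ed"] = ev["admissions_post_ed"] + flows["adm_post"]
    days = dict(state.cumulative_days)
    days["hospital_days"] = days["hospital_days"] + hosp
    days["alive_days"] = days["alive_days"] + (1.0 - dead)
    return CohortState(
        day_index=state.day_index + 1,
        occupancy=np.stack([nh, ne, nhp, nd], axis=-1),
        cumulative_events=ev,
        cumulative_days=days,
        enrolled_fraction=state.enrolled_fraction,
    )


_TOTAL_KEYS = ("ed_visits", "adm_direct", "adm_post", "ed_nonadmitted",
               "adm_direct_fw", "adm_post_fw",
               "ed_visits_entry", "adm_entry", "adm_entry_fw",
               "ed_nonadmitted_entry",
               "hosp_days", "alive_days", "home_days", "alive_fw_days")


def _discount_vector(rate: float, n_days: int) -> np.ndarray:
    days = np.arange(n_days)
    return (1.0 + rate) ** (-days / DAYS_PER_YEAR)


def _scalar_rate(value, name: str) -> float:
    arr = np.asarray(value, dtype=float).ravel()
    if arr.size > 1 and not np.allclose(arr, arr[0]):
        raise ParameterError(f"{name} cannot vary within a batch")
    return float(arr[0])


def run_cohort(arm: Arm, params: ParameterSet,
               scenario: Scenario = BASE_SCENARIO,
               inputs: ModelInputs | None = None,
               inputs_override: tuple[float, ArmInputs] | None = None,
               record: bool = False,
               n_days: int | None = None) -> TrajectoryResult:
    """Propagate expected occupancy over the horizon.

    ``inputs`` carries calibrated mortality and corrected probabilities for
    both arms (derived from *params* if omitted).  ``inputs_override``
    short-circuits calibration with explicit ``(p_death, ArmInputs)`` — used
    by the calibration fixed point itself and by tests.
    """
    n_days = params.horizon_days if n_days is None else int(n_days)
    if inputs_override is not None:
        p_death, own = inputs_override
        other = own
        mixing = False
    else:
        if inputs is None:
            inputs = derive_model_inputs(params)
        p_death = inputs.p_death
        own = inputs.for_arm(arm)
        other = inputs.for_arm(Arm.SOC)
        mixing = (arm is Arm.EPOCA and scenario.waning_lag_days is not None)

    # benefit fraction: 1 for EPOCA under base case, 0 for SOC
    if arm is Arm.EPOCA:
        f_vec = benefit_fraction_vector(params, scenario, n_days)
    else:
        f_vec = np.zeros(n_days)

    r_disc = _scalar_rate(params.discount_rate_annual, "discount_rate_annual")
    v = _discount_vector(r_disc, n_days)

    entry = np.asarray(params.ed_entry_fraction.for_arm(arm), dtype=float)
    shape = np.broadcast_shapes(entry.shape, np.shape(own.p_ed),
                                np.shape(own.p_admit))
    scalar_run = shape == ()
    B = shape if shape else (1,)

    home = np.broadcast_to(1.0 - entry, B).astype(float).copy()
    ed = np.broadcast_to(entry, B).astype(float).copy()
    hosp = np.zeros(B)
    dead = np.zeros(B)

    tot = {k + sfx: np.zeros(B) for k in _TOTAL_KEYS for sfx in ("", "_disc")}
    year_starts = _year_start_days(params.horizon_years)
    year_starts = year_starts[year_starts < n_days]
    alive_at_ys = np.zeros(B + (len(year_starts),))
    ys_lookup = {int(d): i for i, d in enumerate(year_starts)}

    fixed_los = params.los_model == "fixed"
    if fixed_los:
        los_e = _scalar_rate(params.mean_los.for_arm(arm), "mean_los (fixed LOS mode)")
        L = max(int(round(los_e)), 1)
        tunnel = np.zeros((L,) + B)

    pe_o, ph_o, pa_o, pdis_o = (np.broadcast_to(x, B).astype(float) for x in
                                (own.p_ed, own.p_hosp_direct, own.p_admit,
                                 own.p_discharge))
    if mixing:
        pe_s, ph_s, pa_s, pdis_s = (np.broadcast_to(x, B).astype(float) for x in
                                    (other.p_ed, other.p_hosp_direct,
                                     other.p_admit, other.p_discharge))

    rec_rows = [] if record else None

    for t in range(n_days):
        alive = 1.0 - dead
        ft = f_vec[t]
        tot["alive_days"] += alive
        tot["alive_days_disc"] += alive * v[t]
        tot["hosp_days"] += hosp
        tot["hosp_days_disc"] += hosp * v[t]
        tot["home_days"] += home
        tot["home_days_disc"] += home * v[t]
        tot["alive_fw_days"] += alive * ft
        tot["alive_fw_days_disc"] += alive * ft * v[t]
        if t in ys_lookup:
            alive_at_ys[..., ys_lookup[t]] = alive
        if record:
            rec_rows.append((t, float(home.mean()), float(ed.mean()),
                             float(hosp.mean()), float(dead.mean())))

        if mixing and ft < 1.0:
            pe = ft * pe_o + (1 - ft) * pe_s
            ph = ft * ph_o + (1 - ft) * ph_s
            pa = ft * pa_o + (1 - ft) * pa_s
            pdis = ft * pdis_o + (1 - ft) * pdis_s
        else:
            pe, ph, pa, pdis = pe_o, ph_o, pa_o, pdis_o

        if fixed_los:
            # tunnel: death applies to every slot; slot 0 discharges
            s = 1.0 - p_death
            dead = dead + (home + ed + tunnel.sum(axis=0)) * p_death
            home_s, ed_s = home * s, ed * s
            tunnel *= s
            discharge = tunnel[0].copy()
            tunnel[:-1] = tunnel[1:]
            tunnel[-1] = 0.0
            ed_new = home_s * pe
            adm_direct = home_s * ph
            adm_post = ed_s * pa
            ed_home = ed_s - adm_post
            tunnel[-1] += adm_direct + adm_post
            home = home_s - ed_new - adm_direct + ed_home + discharge
            ed = ed_new
            hosp = tunnel.sum(axis=0)
            flows = {"ed_visits": ed_new, "adm_direct": adm_direct,
                     "adm_post": adm_post, "ed_nonadmitted": ed_home}
        else:
            home, ed, hosp, dead, flows = _step_flows(
                home, ed, hosp, dead,
                StepRates(p_death, pe, ph, pa, pdis))

        if t == 0:
            # flows out of the initial ED occupancy are enrolment-visit events
            tot["adm_entry"] += flows["adm_post"]
            tot["adm_entry_disc"] += flows["adm_post"] * v[t]
            tot["adm_entry_fw"] += flows["adm_post"] * ft
            tot["adm_entry_fw_disc"] += flows["adm_post"] * ft * v[t]
            tot["ed_nonadmitted_entry"] += flows["ed_nonadmitted"]
            tot["ed_nonadmitted_entry_disc"] += flows["ed_nonadmitted"] * v[t]
        else:
            tot["adm_post"] += flows["adm_post"]
            tot["adm_post_disc"] += flows["adm_post"] * v[t]
            tot["adm_post_fw"] += flows["adm_post"] * ft
            tot["adm_post_fw_disc"] += flows["adm_post"] * ft * v[t]
            tot["ed_nonadmitted"] += flows["ed_nonadmitted"]
            tot["ed_nonadmitted_disc"] += flows["ed_nonadmitted"] * v[t]
        tot["ed_visits"] += flows["ed_visits"]
        tot["ed_visits_disc"] += flows["ed_visits"] * v[t]
        tot["adm_direct"] += flows["adm_direct"]
        tot["adm_direct_disc"] += flows["adm_direct"] * v[t]
        tot["adm_direct_fw"] += flows["adm_direct"] * ft
        tot["adm_direct_fw_disc"] += flows["adm_direct"] * ft * v[t]

    # the day-0 ED occupancy itself is the enrolment visit
    tot["ed_visits_entry"] += np.broadcast_to(entry, B)
    tot["ed_visits_entry_disc"] += np.broadcast_to(entry, B)

    if scalar_run:
        tot = {k: float(x[0]) for k, x in tot.items()}
        alive_at_ys = alive_at_ys[0]

    per_day = None
    if record:
        per_day = pd.DataFrame(rec_rows,
                               columns=["day", "home", "ed", "hospital", "dead"])

    return TrajectoryResult(arm=arm, scenario=scenario, n_days=n_days,
                            totals=tot, alive_at_year_start=alive_at_ys,
                            per_day=per_day)


# ---------------------------------------------------------------------------
# microsimulation oracle

def run_microsim(arm: Arm, params: ParameterSet,
                 scenario: Scenario = BASE_SCENARIO,
                 n_patients: int = 10_000,
                 seed: int | None = None,
                 inputs: ModelInputs | None = None,
                 n_days: int | None = None) -> TrajectoryResult:
    """Individual-level Monte-Carlo realization of the same transition
    rules; returns sample means in ``totals`` (same keys as the cohort
    engine), Monte-Carlo standard errors in ``se``, and per-patient totals
    for distributional checks."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if inputs is None:
        inputs = derive_model_inputs(params)
    n_days = params.horizon_days if n_days is None else int(n_days)
    rng = np.random.default_rng(params.seed if seed is None else seed)

    p_death = inputs.p_death
    own = inputs.for_arm(arm)
    soc = inputs.for_arm(Arm.SOC)
    mixing = (arm is Arm.EPOCA and scenario.waning_lag_days is not None)
    f_vec = (benefit_fraction_vector(params, scenario, n_days)
             if arm is Arm.EPOCA else np.zeros(n_days))
    r_disc = _scalar_rate(params.discount_rate_annual, "discount_rate_annual")
    v = _discount_vector(r_disc, n_days)

    entry = float(np.asarray(params.ed_entry_fraction.for_arm(arm)))
    n = int(n_patients)
    state = np.zeros(n, dtype=np.int8)
    state[rng.random(n) < entry] = HealthState.ED
    fixed_los = params.los_model == "fixed"
    if fixed_los:
        L = max(int(round(float(np.asarray(params.mean_los.for_arm(arm))))), 1)
        rem = np.zeros(n, dtype=np.int32)

    acc = {k + sfx: np.zeros(n) for k in _TOTAL_KEYS for sfx in ("", "_disc")}
    year_starts = _year_start_days(params.horizon_years)
    year_starts = year_starts[year_starts < n_days]
    alive_at_ys = np.zeros((n, len(year_starts)))
    ys_lookup = {int(d): i for i, d in enumerate(year_starts)}

    def _mix(a, b, ft):
        return ft * float(np.asarray(a)) + (1 - ft) * float(np.asarray(b))

    acc["ed_visits_entry"] += (state == HealthState.ED)
    acc["ed_visits_entry_disc"] += (state == HealthState.ED)

    for t in range(n_days):
        alive = state != HealthState.DEAD
        at_home = state == HealthState.HOME
        in_ed = state == HealthState.ED
        in_hosp = state == HealthState.HOSPITAL
        ft = float(f_vec[t])
        acc["alive_days"] += alive
        acc["alive_days_disc"] += alive * v[t]
        acc["hosp_days"] += in_hosp
        acc["hosp_days_disc"] += in_hosp * v[t]
        acc["home_days"] += at_home
        acc["home_days_disc"] += at_home * v[t]
        acc["alive_fw_days"] += alive * ft
        acc["alive_fw_days_disc"] += alive * ft * v[t]
        if t in ys_lookup:
            alive_at_ys[:, ys_lookup[t]] = alive

        if mixing and ft < 1.0:
            pe = _mix(own.p_ed, soc.p_ed, ft)
            ph = _mix(own.p_hosp_direct, soc.p_hosp_direct, ft)
            pa = _mix(own.p_admit, soc.p_admit, ft)
            pdis = _mix(own.p_discharge, soc.p_discharge, ft)
        else:
            pe = float(np.asarray(own.p_ed))
            ph = float(np.asarray(own.p_hosp_direct))
            pa = float(np.asarray(own.p_admit))
            pdis = float(np.asarray(own.p_discharge))

        u_death = rng.random(n)
        u_move = rng.random(n)
        dies = alive & (u_death < p_death)
        state[dies] = HealthState.DEAD
        alive_now = state != HealthState.DEAD

        go_ed = at_home & alive_now & (u_move < pe)
        go_hosp_direct = at_home & alive_now & (u_move >= pe) & (u_move < pe + ph)
        admit = in_ed & alive_now & (u_move < pa)
        back_home_ed = in_ed & alive_now & ~admit
        if fixed_los:
            rem[in_hosp & alive_now] -= 1
            discharge = in_hosp & alive_now & (rem <= 0)
        else:
            discharge = in_hosp & alive_now & (u_move < pdis)

        key_post = "adm_entry" if t == 0 else "adm_post"
        key_nonadm = "ed_nonadmitted_entry" if t == 0 else "ed_nonadmitted"
        acc["ed_visits"] += go_ed
        acc["ed_visits_disc"] += go_ed * v[t]
        acc["adm_direct"] += go_hosp_direct
        acc["adm_direct_disc"] += go_hosp_direct * v[t]
        acc["adm_direct_fw"] += go_hosp_direct * ft
        acc["adm_direct_fw_disc"] += go_hosp_direct * ft * v[t]
        acc[key_post] += admit
        acc[key_post + "_disc"] += admit * v[t]
        acc[key_post + "_fw"] += admit * ft
        acc[key_post + "_fw_disc"] += admit * ft * v[t]
        acc[key_nonadm] += back_home_ed
        acc[key_nonadm + "_disc"] += back_home_ed * v[t]

        state[go_ed] = HealthState.ED
        new_adm = go_hosp_direct | admit
        state[new_adm] = HealthState.HOSPITAL
        state[back_home_ed] = HealthState.HOME
        state[discharge] = HealthState.HOME
        if fixed_los:
            rem[new_adm] = L

    totals = {}
    se = {}
    per_patient = {}
    for k, arr in acc.items():
        totals[k] = float(arr.mean())
        se[k] = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        per_patient[k] = arr
    return TrajectoryResult(arm=arm, scenario=scenario, n_days=n_days,
                            totals=totals,
                            alive_at_year_start=alive_at_ys.mean(axis=0),
                            se=se, per_patient=per_patient)


def export_trajectory(traj: TrajectoryResult, path) -> None:
    """Write the per-day occupancy table (requires ``record=True``)."""
    if traj.per_day is None:
        raise ValueError("trajectory was run without per-day recording")
    traj.per_day.to_csv(path, index=False)
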