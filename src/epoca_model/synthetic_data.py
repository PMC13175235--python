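"""Synthetic patient-level event histories with the structure of the pilot
study, and estimators that recover model inputs from them.

Each synthetic patient contributes a retrospective baseline window (six
months before inclusion, standard-of-care rates, no mortality — pilot
patients survived to enrolment) and a follow-up window (7.5 months on
average in the pilot) under intervention rates.  Events are daily Bernoulli
processes on at-home days; each ED visit may be followed by an admission
the next day; hospital stays are geometric; per-admission costs are
lognormal with the published patient-level moments; death acts through the
calibrated constant daily hazard during follow-up.

A per-patient gamma frailty multiplier (mean 1) on event hazards reproduces
the overdispersion of the published annualized counts (e.g. SD 5.1 around a
mean of 4.4); the at-home occupancy correction is computed under the
frailty distribution (E[g·home(g)] fixed point) so that realized
calendar-time event rates still equal the target rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import (
    Arm,
    ArmValue,
    DAYS_PER_YEAR,
    ParameterSet,
    calibrate_mortality,
)


@dataclass(frozen=True)
class Windows:
    """Observation windows in days around inclusion (day 0)."""

    baseline_days: int = 183   # six months pre-inclusion
    followup_days: int = 229   # 7.5 months of follow-up

    def __post_init__(self):
        if self.baseline_days <= 0 or self.followup_days <= 0:
            raise ValueError("window lengths must be positive")


@dataclass
class PatientHistory:
    """Event-level record for one synthetic patient.  Days are relative to
    inclusion (negative = baseline window)."""

    patient_id: int
    route: str                     # "ED" | "other"
    frailty: float
    death_day: float | None        # follow-up day of death, None if censored
    censor_day: int
    events: pd.DataFrame           # day, type, los_days, cost

    def validate(self) -> None:
        ev = self.events.sort_values("day")
        assert (ev["day"].diff().dropna() >= 0).all()
        end = self.death_day if self.death_day is not None else self.censor_day
        assert (ev["day"] <= end).all()
        adm = ev[ev["type"] == "admission_post_ed"]
        visits = set(ev.loc[ev["type"] == "ed_visit", "day"])
        assert all(d - 1 in visits for d in adm["day"])
        assert (ev.loc[ev["type"].str.startswith("admission"), "los_days"] >= 1).all()


@dataclass
class CohortSample:
    """A generated cohort: patient table + event table + provenance."""

    patients: pd.DataFrame
    events: pd.DataFrame
    params: ParameterSet
    windows: Windows
    seed: int
    frailty_shape: float | None

    def histories(self):
        for pid, row in self.patients.iterrows():
            ev = self.events[self.events["patient"] == pid]
            death = row["death_day"]
            yield PatientHistory(
                patient_id=int(pid), route=row["route"],
                frailty=float(row["frailty"]),
                death_day=None if np.isnan(death) else float(death),
                censor_day=int(row["censor_day"]),
                events=ev[["day", "type", "los_days", "cost"]].reset_index(drop=True),
            )

    def export(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(directory / "patients.csv", index_label="patient")
        self.events.to_csv(directory / "events.csv", index=False)


def load_cohort(directory: str | Path, params: ParameterSet,
                windows: Windows | None = None) -> CohortSample:
    directory = Path(directory)
    patients = pd.read_csv(directory / "patients.csv", index_col="patient")
    events = pd.read_csv(directory / "events.csv")
    return CohortSample(patients=patients, events=events, params=params,
                        windows=windows or Windows(), seed=-1,
                        frailty_shape=None)


# ---------------------------------------------------------------------------
# occupancy correction under frailty

def _frailty_nodes(shape: float | None, k: int = 512):
    if shape is None:
        return np.ones(1), np.ones(1)
    q = (np.arange(k) + 0.5) / k
    g = stats.gamma.ppf(q, a=shape, scale=1.0 / shape)
    w = np.full(k, 1.0 / k)
    return g, w


def _occupancy_correction(r_ed: float, r_hosp: float, p_admit: float,
                          mean_los: float, frailty_shape: float | None,
                          tol: float = 1e-10, max_rounds: int = 200) -> float:
    """Fixed point for c = E[g · home_frac(g)] so that calendar-time event
    rates equal the targets when daily hazards are rate/(365.25·c).

    In the generator an ED visit happens on an at-home day (no bed day);
    hospital stays remove ``mean_los`` at-home days per admission.
    """
    r_direct = r_hosp - r_ed * p_admit
    if r_direct < 0:
        raise ValueError("ED admissions exceed total hospitalization rate")
    g, w = _frailty_nodes(frailty_shape)
    c = 1.0
    for _ in range(max_rounds):
        h_adm = (r_ed * p_admit + r_direct) / (DAYS_PER_YEAR * c)
        home = 1.0 / (1.0 + g * h_adm * mean_los)
        c_new = float(np.sum(w * g * home))
        if abs(c_new - c) < tol:
            return c_new
        c = c_new
    return c


# ---------------------------------------------------------------------------
# generation

def generate_cohort(n_patients: int, params: ParameterSet,
                    windows: Windows | None = None,
                    seed: int | None = None,
                    frailty_shape: float | None = 1.0,
                    ed_route_fraction: float = 0.30) -> CohortSample:
    """Simulate per-patient event histories (baseline = SOC rates,
    follow-up = intervention rates); reproducible under ``seed``."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    windows = windows or Windows()
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = int(n_patients)

    g = (rng.gamma(frailty_shape, 1.0 / frailty_shape, size=n)
         if frailty_shape is not None else np.ones(n))
    route = np.where(rng.random(n) < ed_route_fraction, "ED", "other")
    p_death = calibrate_mortality(
        float(np.asarray(params.target_mean_survival_years)),
        float(np.asarray(params.horizon_years)))

    phase_cfg = {}
    for phase, arm in (("baseline", Arm.SOC), ("followup", Arm.EPOCA)):
        r_ed = float(np.asarray(params.annual_ed_rate.for_arm(arm)))
        r_hosp = float(np.asarray(params.annual_hosp_rate.for_arm(arm)))
        p_admit = float(np.asarray(params.p_admit_after_ed.for_arm(arm)))
        los = float(np.asarray(params.mean_los.for_arm(arm)))
        c = _occupancy_correction(r_ed, r_hosp, p_admit, los, frailty_shape)
        h_ed = r_ed / (DAYS_PER_YEAR * c)
        h_direct = (r_hosp - r_ed * p_admit) / (DAYS_PER_YEAR * c)
        cost_mean = float(np.asarray(params.cost_hosp.for_arm(arm)))
        cost_sd = {Arm.SOC: 2721.0, Arm.EPOCA: 3183.0}[arm]
        sigma = np.sqrt(np.log1p((cost_sd / cost_mean) ** 2))
        mu = np.log(cost_mean) - 0.5 * sigma**2
        phase_cfg[phase] = dict(h_ed=h_ed, h_direct=h_direct, p_admit=p_admit,
                                p_dis=1.0 / los, mu=mu, sigma=sigma)

    T_b, T_f = windows.baseline_days, windows.followup_days
    in_hosp = np.zeros(n, dtype=bool)
    rem_los = np.zeros(n, dtype=np.int64)
    pending = np.zeros(n, dtype=bool)   # ED visit yesterday, admission pending
    dead = np.zeros(n, dtype=bool)
    death_day = np.full(n, np.nan)

    ev_pat: list[np.ndarray] = []
    ev_day: list[np.ndarray] = []
    ev_type: list[str] = []
    ev_los: list[np.ndarray] = []
    ev_cost: list[np.ndarray] = []

    def _record(mask, day, etype, los=None, cost=None):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return
        ev_pat.append(idx)
        ev_day.append(np.full(idx.size, day))
        ev_type.extend([etype] * idx.size)
        ev_los.append(np.zeros(idx.size) if los is None else los)
        ev_cost.append(np.full(idx.size, 52.0) if cost is None else cost)

    ids_all = np.arange(n)
    for t in range(-T_b, T_f):
        if t == 0:
            # inclusion: reset everyone to home, clear pending admissions
            in_hosp[:] = False
            rem_los[:] = 0
            pending[:] = False
        cfg = phase_cfg["baseline" if t < 0 else "followup"]
        alive = ~dead
        if t >= 0:
            dies = alive & (rng.random(n) < p_death)
            death_day[dies] = t
            dead |= dies
            alive = ~dead
        # pending post-ED admissions resolve first
        u_adm = rng.random(n)
        admit = pending & alive & ~in_hosp & (u_adm < cfg["p_admit"])
        pending[:] = False
        # count down drawn stays; discharge when exhausted
        staying = in_hosp & alive
        rem_los[staying] -= 1
        disch = staying & (rem_los <= 0)
        in_hosp[disch] = False
        # new events on at-home days
        at_home = alive & ~in_hosp
        u = rng.random(n)
        h_e, h_d = cfg["h_ed"] * g, cfg["h_direct"] * g
        ed_visit = at_home & ~admit & (u < h_e)
        direct = at_home & ~admit & (u >= h_e) & (u < h_e + h_d)
        pending[ed_visit] = True

        _record(ed_visit, t, "ed_visit")
        for mask, etype in ((admit, "admission_post_ed"),
                            (direct, "admission_direct")):
            k = int(mask.sum())
            if k:
                los_draw = rng.geometric(cfg["p_dis"], size=k)
                cost_draw = np.exp(cfg["mu"] + cfg["sigma"] * rng.standard_normal(k))
                _record(mask, t, etype, los=los_draw.astype(float), cost=cost_draw)
                in_hosp |= mask
                rem_los[mask] = los_draw

    events = pd.DataFrame({
        "patient": np.concatenate(ev_pat) if ev_pat else np.array([], dtype=int),
        "day": np.concatenate(ev_day) if ev_day else np.array([], dtype=int),
        "type": pd.Series(ev_type, dtype="object"),
        "los_days": np.concatenate(ev_los) if ev_los else np.array([]),
        "cost": np.concatenate(ev_cost) if ev_cost else np.array([]),
    }).sort_values(["patient", "day"], kind="stable").reset_index(drop=True)

    patients = pd.DataFrame({
        "route": route,
        "frailty": g,
        "death_day": death_day,
        "censor_day": np.full(n, T_f),
        "baseline_days": np.full(n, T_b),
    }, index=pd.RangeIndex(n, name="patient"))

    return CohortSample(patients=patients, events=events, params=params,
                        windows=windows, seed=seed, frailty_shape=frailty_shape)


# ---------------------------------------------------------------------------
# estimation

class EstimationError(RuntimeError):
    pass


@dataclass
class PhaseEstimates:
    """Annualized rates (per calendar alive person-year by default),
    admission probability, LOS and cost moments for one phase, with SEs."""

    annual_hosp_rate: float
    annual_hosp_rate_se: float
    annual_ed_rate: float
    annual_ed_rate_se: float
    p_admit_after_ed: float
    p_admit_after_ed_se: float
    mean_los: float
    mean_los_se: float
    mean_cost_per_admission: float
    mean_cost_per_admission_se: float
    person_years: float
    n_patients: int


@dataclass
class ParameterEstimates:
    baseline: PhaseEstimates    # SOC phase
    followup: PhaseEstimates    # intervention phase
    exposure: str


def _ratio_rate(counts: np.ndarray, times_years: np.ndarray):
    """Rate = Σc/Σt with a cluster-robust (ratio-estimator) SE, valid under
    per-patient overdispersion."""
    T = times_years.sum()
    if T <= 0:
        raise EstimationError("zero person-time")
    r = counts.sum() / T
    n = len(counts)
    resid = counts - r * times_years
    se = np.sqrt((n / max(n - 1, 1)) * np.sum(resid**2)) / T
    return float(r), float(se)


def _phase_estimates(sample: CohortSample, phase: str,
                     exposure: str) -> PhaseEstimates:
    ev = sample.events
    pat = sample.patients
    n = len(pat)
    T_b = sample.windows.baseline_days
    T_f = sample.windows.followup_days
    if phase == "baseline":
        mask = ev["day"] < 0
        alive_days = np.full(n, float(T_b))
    else:
        mask = ev["day"] >= 0
        end = np.where(np.isnan(pat["death_day"]), T_f, pat["death_day"])
        alive_days = np.clip(end, 0, T_f).astype(float)
    sub = ev[mask]
    adm = sub[sub["type"].str.startswith("admission")]
    ed = sub[sub["type"] == "ed_visit"]

    if exposure == "at_home":
        hosp_days = adm.groupby("patient")["los_days"].sum()
        hd = np.zeros(n)
        hd[hosp_days.index.to_numpy()] = hosp_days.to_numpy()
        # stays can run past the censoring horizon; clip to alive time
        at_risk_days = np.maximum(alive_days - np.minimum(hd, alive_days), 1e-9)
    elif exposure == "calendar":
        at_risk_days = alive_days
    else:
        raise ValueError(f"unknown exposure {exposure!r}")
    t_years = at_risk_days / DAYS_PER_YEAR

    def per_patient_counts(df):
        c = df.groupby("patient").size()
        out = np.zeros(n)
        out[c.index.to_numpy()] = c.to_numpy()
        return out

    hosp_rate, hosp_se = _ratio_rate(per_patient_counts(adm), t_years)
    ed_rate, ed_se = _ratio_rate(per_patient_counts(ed), t_years)

    # admission probability over the risk set of ED visits whose next day
    # is observable (patient alive and inside the window)
    if phase == "baseline":
        resolved = ed["day"] <= -2
    else:
        dd = pat["death_day"].reindex(ed["patient"]).to_numpy()
        next_day = ed["day"].to_numpy() + 1
        resolved = (next_day < T_f) & (np.isnan(dd) | (next_day < dd))
    n_ed = int(np.sum(resolved))
    n_post = int((sub["type"] == "admission_post_ed").sum())
    if n_ed > 0:
        p_admit = n_post / n_ed
        p_admit_se = np.sqrt(max(p_admit * (1 - p_admit), 0.0) / n_ed)
    else:
        p_admit, p_admit_se = float("nan"), float("nan")

    if len(adm) > 0:
        mean_los = float(adm["los_days"].mean())
        mean_los_se = float(adm["los_days"].std(ddof=1) / np.sqrt(len(adm)))
        mean_cost = float(adm["cost"].mean())
        mean_cost_se = float(adm["cost"].std(ddof=1) / np.sqrt(len(adm)))
    else:
        mean_los = mean_los_se = mean_cost = mean_cost_se = float("nan")

    return PhaseEstimates(
        annual_hosp_rate=hosp_rate, annual_hosp_rate_se=hosp_se,
        annual_ed_rate=ed_rate, annual_ed_rate_se=ed_se,
        p_admit_after_ed=p_admit, p_admit_after_ed_se=p_admit_se,
        mean_los=mean_los, mean_los_se=mean_los_se,
        mean_cost_per_admission=mean_cost,
        mean_cost_per_admission_se=mean_cost_se,
        person_years=float(t_years.sum()), n_patients=n,
    )


def estimate_parameters(sample: CohortSample,
                        exposure: str = "calendar") -> ParameterEstimates:
    """Recover model inputs from a cohort sample.

    ``exposure='calendar'`` divides events by alive person-time (how the
    pilot rates were measured); ``'at_home'`` divides by out-of-hospital
    person-time (recovers the generating hazards directly).
    """
    return ParameterEstimates(
        baseline=_phase_estimates(sample, "baseline", exposure),
        followup=_phase_estimates(sample, "followup", exposure),
        exposure=exposure,
    )


def parameter_set_from_estimates(est: ParameterEstimates,
                                 base: ParameterSet) -> ParameterSet:
    """Feed estimated rates/LOS/admission probabilities back into a
    ParameterSet (baseline phase → SOC arm, follow-up → intervention arm)."""
    b, f = est.baseline, est.followup
    return base.replace(
        annual_hosp_rate=ArmValue(epoca=f.annual_hosp_rate, soc=b.annual_hosp_rate),
        annual_ed_rate=ArmValue(epoca=f.annual_ed_rate, soc=b.annual_ed_rate),
        p_admit_after_ed=ArmValue(epoca=f.p_admit_after_ed,
                                  soc=b.p_admit_after_ed),
        mean_los=ArmValue(epoca=f.mean_los, soc=b.mean_los),
        cost_hosp=ArmValue(epoca=f.mean_cost_per_admission,
                           soc=b.mean_cost_per_admission),
    )
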