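"""Model inputs: parameter container, rate→probability conversion, calibration,
and sampling distributions for probabilistic sensitivity analysis.

The model compares a tele-monitoring programme (EPOCA) against standard of
care (SOC) for frail, polypathological older adults.  All inputs are annual
event rates, unit costs (€2025), utilities and programme-participation
fractions; this module converts them into the per-cycle quantities the
daily-cycle Markov engine consumes:

* annual event rates → daily at-home event probabilities, inflated by an
  occupancy correction so that the *realized* number of events per alive
  person-year equals the observed rate (events can only fire on days spent
  at home, and pilot rates were measured per calendar time);
* a constant daily all-cause mortality hazard, calibrated so the cohort's
  undiscounted mean survival over the horizon matches the observed value;
* sampling distributions fitted to the published means and 95% CIs for the
  probabilistic sensitivity analysis.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy import optimize, stats

DAYS_PER_YEAR = 365.25
#: 10-year horizon in daily cycles.
HORIZON_DAYS = 3652

_DATA_DIR = Path(__file__).parent / "data"


class Arm(enum.Enum):
    """Strategy arm: tele-monitoring programme vs standard of care."""

    EPOCA = "epoca"
    SOC = "soc"


@dataclass(frozen=True)
class ArmValue:
    """A parameter with one value per arm."""

    epoca: float
    soc: float

    def for_arm(self, arm: Arm) -> float:
        return self.epoca if arm is Arm.EPOCA else self.soc

    def with_arm(self, arm: Arm, value: float) -> "ArmValue":
        if arm is Arm.EPOCA:
            return ArmValue(value, self.soc)
        return ArmValue(self.epoca, value)


class ParameterError(ValueError):
    """Invalid or inconsistent model parameter."""


class CalibrationError(RuntimeError):
    """Calibration target unattainable."""


@dataclass(frozen=True)
class ParameterSet:
    """Every model input, plus the structural switches of the analysis.

    Rates are events per person-year measured on calendar (alive) time;
    costs are €2025 per unit; proportions lie in [0, 1].  Fields whose
    value may legitimately differ between arms are :class:`ArmValue`.
    """

    # transition structure
    ed_entry_fraction: ArmValue = ArmValue(0.0, 0.22)
    annual_hosp_rate: ArmValue = ArmValue(2.4, 4.4)
    annual_ed_rate: ArmValue = ArmValue(1.6, 3.4)
    p_admit_after_ed: ArmValue = ArmValue(0.69, 0.71)
    mean_los: ArmValue = ArmValue(7.3, 7.7)
    mean_age: float = 87.9

    # costs (€2025)
    program_cost_annual: float = 2210.0
    cost_hosp: ArmValue = ArmValue(3714.0, 3773.0)
    cost_hosp_post_ed: float = 4249.0
    cost_ed_visit_payer: float = 52.0
    # back-derived so that collective ED spending matches published totals
    cost_ed_visit_collective: float = 165.25
    outpatient_annual: ArmValue = ArmValue(5820.0, 5337.0)
    tariff_ratio: float = 1.27
    outpatient_nhi_fraction: float = 0.65

    # utilities
    utility_baseline: float = 0.8
    disutility_hosp_day: float = 0.0013

    # time & discounting
    discount_rate_annual: float = 0.025
    horizon_years: float = 10.0
    target_mean_survival_years: float = 1.766

    # programme participation
    program_share_6m: float = 0.59
    program_share_12m: float = 0.41
    program_continuation_year2: float = 0.22

    # structural switches (see docs/methods.md for rationale)
    count_entry_events: bool = False
    use_post_ed_admission_cost: bool = False
    nhi_ed_nonadmitted_only: bool = False
    nhi_outpatient_fraction_applied: bool = False
    program_cost_mortality_adjusted: bool = True
    los_model: str = "geometric"  # "geometric" | "fixed"

    seed: int = 20250514

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def _all(x) -> np.ndarray:
            if isinstance(x, ArmValue):
                return np.concatenate([np.atleast_1d(x.epoca), np.atleast_1d(x.soc)])
            return np.atleast_1d(x)

        for name in ("ed_entry_fraction", "p_admit_after_ed",
                     "outpatient_nhi_fraction", "program_share_6m",
                     "program_share_12m", "program_continuation_year2"):
            v = _all(getattr(self, name))
            if np.any(v < 0) or np.any(v > 1):
                raise ParameterError(f"{name} must lie in [0, 1]")
        for name in ("annual_hosp_rate", "annual_ed_rate", "mean_los",
                     "cost_hosp", "cost_hosp_post_ed", "cost_ed_visit_payer",
                     "cost_ed_visit_collective", "outpatient_annual",
                     "tariff_ratio", "horizon_years",
                     "target_mean_survival_years"):
            v = _all(getattr(self, name))
            if np.any(v <= 0) and name not in ("annual_hosp_rate", "annual_ed_rate"):
                raise ParameterError(f"{name} must be strictly positive")
            if name in ("annual_hosp_rate", "annual_ed_rate") and np.any(v < 0):
                raise ParameterError(f"{name} must be non-negative")
        if np.any(_all(self.disutility_hosp_day) < 0):
            raise ParameterError("disutility_hosp_day must be >= 0")
        if self.los_model not in ("geometric", "fixed"):
            raise ParameterError(f"unknown los_model {self.los_model!r}")

    # -- convenience -------------------------------------------------------
    @property
    def horizon_days(self) -> int:
        h = np.asarray(self.horizon_years, dtype=float).ravel()
        if h.size > 1 and not np.allclose(h, h[0]):
            raise ParameterError("horizon_years cannot vary within a batch")
        return int(round(float(h[0]) * DAYS_PER_YEAR))

    def replace(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)

    def with_arm_value(self, name: str, arm: Arm, value: float) -> "ParameterSet":
        av: ArmValue = getattr(self, name)
        return replace(self, **{name: av.with_arm(arm, value)})


# ---------------------------------------------------------------------------
# configuration files

def _to_plain(params: ParameterSet) -> dict:
    out: dict = {}
    for f in fields(params):
        v = getattr(params, f.name)
        if isinstance(v, ArmValue):
            out[f.name] = {"epoca": v.epoca, "soc": v.soc}
        else:
            out[f.name] = v
    return out


def load_params(path: str | Path | None = None) -> ParameterSet:
    """Load a :class:`ParameterSet` from a YAML config (packaged default if
    *path* is None).  Keys are named exactly as the dataclass fields;
    arm-specific entries are ``{epoca: ..., soc: ...}`` mappings."""
    if path is None:
        path = _DATA_DIR / "default_params.yaml"
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name: f for f in fields(ParameterSet)}
    kwargs = {}
    for key, value in raw.items():
        if key not in known:
            raise ParameterError(f"unknown parameter {key!r} in {path}")
        if isinstance(value, dict):
            kwargs[key] = ArmValue(epoca=float(value["epoca"]), soc=float(value["soc"]))
        else:
            kwargs[key] = value
    return ParameterSet(**kwargs)


def save_params(params: ParameterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(params), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# scenarios (waning of the programme effect after exit)

@dataclass(frozen=True)
class Scenario:
    """Waning scenario: after programme exit (plus an optional lag) the
    disenrolled fraction's transition rates, unit costs and outpatient
    intensity revert to SOC values.  ``lag_days=None`` means benefits are
    retained for life (base case)."""

    name: str
    waning_lag_days: int | None = None


SCENARIOS: dict[str, Scenario] = {
    "base": Scenario("base", None),
    "waning_0m": Scenario("waning_0m", 0),
    "waning_3m": Scenario("waning_3m", 91),
    "waning_6m": Scenario("waning_6m", 183),
}
BASE_SCENARIO = SCENARIOS["base"]


def get_scenario(name: str) -> Scenario:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise ParameterError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        ) from None


# ---------------------------------------------------------------------------
# rate <-> probability

def daily_probability_from_annual_rate(rate, occupancy_correction=1.0):
    """Daily event probability on at-home days for an annual event rate.

    ``occupancy_correction`` is the fraction of alive time spent at home
    (events cannot fire from the ED or a hospital bed); the rate is divided
    by it so the realized events per alive person-year equal *rate*.
    """
    rate = np.asarray(rate, dtype=float)
    occ = np.asarray(occupancy_correction, dtype=float)
    if np.any(rate < 0):
        raise ParameterError("rate must be non-negative")
    if np.any(occ <= 0) or np.any(occ > 1):
        raise ParameterError("occupancy_correction must lie in (0, 1]")
    p = -np.expm1(-(rate / occ) / DAYS_PER_YEAR)
    return p if p.ndim else float(p)


def annual_rate_from_daily_probability(p, occupancy_correction=1.0):
    """Inverse of :func:`daily_probability_from_annual_rate`."""
    p = np.asarray(p, dtype=float)
    r = -DAYS_PER_YEAR * np.log1p(-p) * np.asarray(occupancy_correction, dtype=float)
    return r if r.ndim else float(r)


# ---------------------------------------------------------------------------
# mortality calibration

def mean_survival_years(p_death: float, n_days: int = HORIZON_DAYS) -> float:
    """Undiscounted mean survival (years) over the horizon for a constant
    daily death probability — the cohort engine's alive-day sum in closed
    form (death is state-independent, so occupancy does not enter)."""
    if p_death <= 0:
        return n_days / DAYS_PER_YEAR
    q = 1.0 - p_death
    return (1.0 - q ** n_days) / (p_death * DAYS_PER_YEAR)


def calibrate_mortality(target_mean_survival: float,
                        horizon_years: float = 10.0) -> float:
    """Constant daily death probability whose truncated mean survival over
    the horizon equals the target, found by root bracketing against the
    cohort engine's survival accumulation."""
    n_days = int(round(horizon_years * DAYS_PER_YEAR))
    if not 0 < target_mean_survival < horizon_years:
        raise CalibrationError(
            f"target survival {target_mean_survival} y not attainable within "
            f"a {horizon_years} y horizon")
    lo, hi = 1e-9, 0.5
    f = lambda p: mean_survival_years(p, n_days) - target_mean_survival
    if f(lo) < 0:
        raise CalibrationError("target survival exceeds horizon-limited maximum")
    return float(optimize.brentq(f, lo, hi, xtol=1e-14, rtol=1e-13))


# ---------------------------------------------------------------------------
# derived per-cycle inputs

@dataclass
class ArmInputs:
    """Per-cycle transition probabilities for one arm (scalar or batched)."""

    p_ed: np.ndarray
    p_hosp_direct: np.ndarray
    p_admit: np.ndarray
    p_discharge: np.ndarray
    occupancy_correction: np.ndarray


@dataclass
class ModelInputs:
    """Calibrated inputs consumed by the engine: constant daily mortality
    plus corrected transition probabilities for both arms."""

    p_death: float
    arms: dict[Arm, ArmInputs]
    params: ParameterSet

    def for_arm(self, arm: Arm) -> ArmInputs:
        return self.arms[arm]


def _arm_daily_inputs(params: ParameterSet, arm: Arm, p_death: float,
                      correction) -> ArmInputs:
    r_ed = np.asarray(params.annual_ed_rate.for_arm(arm), dtype=float)
    r_hosp = np.asarray(params.annual_hosp_rate.for_arm(arm), dtype=float)
    p_admit = np.asarray(params.p_admit_after_ed.for_arm(arm), dtype=float)
    los = np.asarray(params.mean_los.for_arm(arm), dtype=float)
    # post-ED admissions arrive via the ED state; the direct-admission rate
    # is the remainder of the total hospitalization rate
    r_direct = r_hosp - r_ed * p_admit
    if np.any(r_direct < 0):
        raise ParameterError(
            "annual_ed_rate * p_admit_after_ed exceeds annual_hosp_rate; "
            "direct admission rate would be negative")
    p_ed = daily_probability_from_annual_rate(r_ed, correction)
    p_direct = daily_probability_from_annual_rate(r_direct, correction)
    if np.any(np.asarray(p_ed) + np.asarray(p_direct) >= 1):
        raise ParameterError("combined daily event probability reaches 1")
    return ArmInputs(
        p_ed=np.asarray(p_ed, dtype=float),
        p_hosp_direct=np.asarray(p_direct, dtype=float),
        p_admit=p_admit,
        p_discharge=1.0 / los,
        occupancy_correction=np.asarray(correction, dtype=float),
    )


def derive_model_inputs(params: ParameterSet,
                        max_rounds: int = 30,
                        tol: float = 1e-10) -> ModelInputs:
    """Calibrate mortality and the per-arm occupancy corrections.

    The correction for each arm is found by fixed point against the cohort
    engine: run the arm, measure the realized recurrent events per alive
    person-year, and rescale until it equals the input rate.  Converges in
    ~5 rounds for realistic inputs.
    """
    from . import markov  # deferred: markov imports this module's types

    def _scalar(v, name):
        arr = np.asarray(v, dtype=float).ravel()
        if arr.size > 1 and not np.allclose(arr, arr[0]):
            raise ParameterError(f"{name} cannot vary within a batch")
        return float(arr[0])

    p_death = calibrate_mortality(
        _scalar(params.target_mean_survival_years, "target_mean_survival_years"),
        _scalar(params.horizon_years, "horizon_years"))
    arms: dict[Arm, ArmInputs] = {}
    for arm in Arm:
        target = np.asarray(params.annual_ed_rate.for_arm(arm), dtype=float)
        # seed the fixed point at the alive-time at-home fraction implied by
        # hospital occupancy in equilibrium
        r_hosp = np.asarray(params.annual_hosp_rate.for_arm(arm), dtype=float)
        los = np.asarray(params.mean_los.for_arm(arm), dtype=float)
        c = 1.0 / (1.0 + (r_hosp * los + target) / DAYS_PER_YEAR)
        c = np.asarray(c, dtype=float)
        for _ in range(max_rounds):
            arm_in = _arm_daily_inputs(params, arm, p_death, c)
            traj = markov.run_cohort(arm, params, inputs_override=(p_death, arm_in))
            alive_years = traj.totals["alive_days"] / DAYS_PER_YEAR
            realized_ed = traj.totals["ed_visits"] / alive_years
            ratio = np.where(target > 0, realized_ed / np.maximum(target, 1e-300), 1.0)
            c = c * ratio
            if np.all(np.abs(ratio - 1.0) < tol):
                break
        arms[arm] = _arm_daily_inputs(params, arm, p_death, c)
    return ModelInputs(p_death=p_death, arms=arms, params=params)


# ---------------------------------------------------------------------------
# programme participation schedule

def enrolled_fraction(day, params: ParameterSet):
    """Fraction of the (surviving) EPOCA cohort still enrolled on a given
    day: exits at 6 months (59%) and 12 months (41%), then geometric 22%/y
    continuation from the start of each subsequent year."""
    day = np.asarray(day)
    cont = params.program_continuation_year2
    year_starts = _year_start_days(params.horizon_years)
    # index of the programme year the day falls in (0-based)
    yr = np.searchsorted(year_starts, day, side="right") - 1
    frac = np.where(day < 183, 1.0,
                    np.where(day < year_starts[1] if len(year_starts) > 1 else 366,
                             params.program_share_12m,
                             cont ** np.maximum(yr, 1)))
    return frac if frac.ndim else float(frac)


def _year_start_days(horizon_years) -> np.ndarray:
    n = int(math.ceil(float(np.asarray(horizon_years, dtype=float).ravel()[0])))
    return np.array([int(y * DAYS_PER_YEAR + 0.5) for y in range(n)])


def benefit_fraction_vector(params: ParameterSet, scenario: Scenario,
                            n_days: int | None = None) -> np.ndarray:
    """Per-day fraction of the EPOCA cohort still experiencing EPOCA rates.

    Base case: 1 everywhere (benefits retained for life).  Waning scenarios:
    the fraction enrolled ``lag`` days ago (those who exited more than the
    lag ago have reverted to SOC)."""
    n_days = params.horizon_days if n_days is None else n_days
    days = np.arange(n_days)
    if scenario.waning_lag_days is None:
        return np.ones(n_days)
    lagged = days - scenario.waning_lag_days
    f = np.where(lagged < 0, 1.0, enrolled_fraction(np.maximum(lagged, 0), params))
    return np.asarray(f, dtype=float)


# ---------------------------------------------------------------------------
# PSA sampling distributions

class FittingError(ValueError):
    """Moment/CI matching infeasible for the requested family."""


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling family and moments for one uncertain parameter.

    ``sd`` is used directly for normal and for lognormal/gamma moment
    matching; when a 95% CI is given it takes precedence for the spread
    (CI width ≈ 3.92 sd on the natural scale; for the lognormal the CI is
    matched in log space with the mean anchored at ``mean``).
    """

    family: str  # normal | beta | gamma | lognormal | fixed
    mean: float
    sd: float | None = None
    ci95: tuple[float, float] | None = None

    def __post_init__(self):
        if self.family not in ("normal", "beta", "gamma", "lognormal", "fixed"):
            raise FittingError(f"unknown family {self.family!r}")

    def _spread_sd(self) -> float:
        if self.ci95 is not None:
            lo, hi = self.ci95
            if not hi > lo:
                raise FittingError("degenerate CI")
            return (hi - lo) / 3.92
        if self.sd is None:
            raise FittingError("need sd or ci95 for a non-fixed family")
        return float(self.sd)


class Sampler:
    """Deterministic-under-seed sampler for a fitted distribution."""

    def __init__(self, spec: DistributionSpec):
        self.spec = spec
        self._frozen = self._fit(spec)

    @staticmethod
    def _fit(spec: DistributionSpec):
        m = float(spec.mean)
        if spec.family == "fixed":
            return None
        s = spec._spread_sd()
        if s <= 0:
            raise FittingError("sd must be positive")
        if spec.family == "normal":
            return stats.norm(loc=m, scale=s)
        if spec.family == "beta":
            if not 0 < m < 1:
                raise FittingError("beta mean must lie in (0, 1)")
            nu = m * (1 - m) / s**2 - 1.0
            if nu <= 0:
                raise FittingError("beta sd too large for the given mean")
            return stats.beta(m * nu, (1 - m) * nu)
        if spec.family == "gamma":
            if m <= 0:
                raise FittingError("gamma mean must be positive")
            shape = (m / s) ** 2
            return stats.gamma(shape, scale=s**2 / m)
        # lognormal
        if m <= 0:
            raise FittingError("lognormal mean must be positive")
        if spec.ci95 is not None:
            lo, hi = spec.ci95
            if lo <= 0:
                raise FittingError("lognormal CI must be positive")
            sigma = (math.log(hi) - math.log(lo)) / 3.92
        else:
            sigma = math.sqrt(math.log1p((s / m) ** 2))
        mu = math.log(m) - 0.5 * sigma**2
        return stats.lognorm(sigma, scale=math.exp(mu))

    def draw(self, rng: np.random.Generator, size=None):
        if self._frozen is None:
            if size is None:
                return float(self.spec.mean)
            return np.full(size, float(self.spec.mean))
        out = self._frozen.rvs(size=size, random_state=rng)
        return out

    def mean(self) -> float:
        if self._frozen is None:
            return float(self.spec.mean)
        return float(self._frozen.mean())


def fit_distribution(spec: DistributionSpec) -> Sampler:
    """Fit a PSA sampling distribution; see :class:`DistributionSpec`."""
    return Sampler(spec)


# ---------------------------------------------------------------------------
# batching helpers (PSA/DSA evaluate many parameter sets in one engine pass)

def stack_parameter_sets(sets: Sequence[ParameterSet]) -> ParameterSet:
    """Stack scalar parameter sets into one set whose numeric fields are
    arrays (leading batch axis); structural switches must agree."""
    base = sets[0]
    kwargs = {}
    for f in fields(ParameterSet):
        values = [getattr(s, f.name) for s in sets]
        v0 = values[0]
        if isinstance(v0, ArmValue):
            kwargs[f.name] = ArmValue(
                epoca=np.array([v.epoca for v in values], dtype=float),
                soc=np.array([v.soc for v in values], dtype=float),
            )
        elif isinstance(v0, (bool, str, int)) and f.name != "mean_age":
            if any(v != v0 for v in values):
                raise ParameterError(f"cannot batch differing switch {f.name!r}")
            kwargs[f.name] = v0
        else:
            kwargs[f.name] = np.array(values, dtype=float)
    return ParameterSet(**kwargs)
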