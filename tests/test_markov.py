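"""Cohort engine and microsimulation oracle."""

import numpy as np
import pytest

from epoca_model import (
    Arm,
    DAYS_PER_YEAR,
    get_scenario,
    initial_state,
    run_cohort,
    run_microsim,
    step,
)
from epoca_model.markov import StepRates
from epoca_model.parameters import ArmInputs, benefit_fraction_vector


def _zero_rates(p_death=0.0):
    return (p_death, ArmInputs(p_ed=np.float64(0.0), p_hosp_direct=np.float64(0.0),
                               p_admit=np.float64(0.0), p_discharge=np.float64(0.1),
                               occupancy_correction=np.float64(1.0)))


class TestInitialState:
    def test_epoca_starts_home(self, params):
        s = initial_state(Arm.EPOCA, params)
        assert np.allclose(s.occupancy, [1.0, 0.0, 0.0, 0.0])

    def test_soc_starts_with_ed_entry(self, params):
        s = initial_state(Arm.SOC, params)
        assert np.allclose(s.occupancy, [0.78, 0.22, 0.0, 0.0])

    def test_accumulators_zero(self, params):
        s = initial_state(Arm.SOC, params)
        assert all(v == 0 for v in s.cumulative_events.values())
        assert all(v == 0 for v in s.cumulative_days.values())


class TestStep:
    def test_certain_death(self, params):
        s = initial_state(Arm.SOC, params)
        r = StepRates(1.0, 0.01, 0.01, 0.7, 0.13)
        out = step(s, Arm.SOC, params, r)
        assert np.allclose(out.occupancy, [0, 0, 0, 1])

    def test_no_event_identity(self, params):
        s = initial_state(Arm.EPOCA, params)
        r = StepRates(0.0, 0.0, 0.0, 0.0, 0.1)
        out = step(s, Arm.EPOCA, params, r)
        assert np.allclose(out.occupancy, s.occupancy)

    def test_soc_entry_admissions(self, params, inputs):
        """One step from the SOC initial state: expected post-ED admissions
        gain is 0.22 · (1 − p_death) · 0.71."""
        s = initial_state(Arm.SOC, params)
        ai = inputs.for_arm(Arm.SOC)
        r = StepRates(inputs.p_death, ai.p_ed, ai.p_hosp_direct,
                      ai.p_admit, ai.p_discharge)
        out = step(s, Arm.SOC, params, r)
        expected = 0.22 * (1 - inputs.p_death) * 0.71
        assert out.cumulative_events["admissions_post_ed"] == pytest.approx(
            expected, rel=1e-12)

    def test_invalid_probability_raises(self, params):
        from epoca_model.parameters import ParameterError
        s = initial_state(Arm.SOC, params)
        with pytest.raises(ParameterError):
            step(s, Arm.SOC, params, StepRates(0.0, 0.7, 0.7, 0.5, 0.1))


class TestCohortRun:
    def test_occupancy_conservation(self, params, inputs):
        for arm in Arm:
            traj = run_cohort(arm, params, inputs=inputs, record=True)
            occ = traj.per_day[["home", "ed", "hospital", "dead"]].to_numpy()
            assert np.all(np.abs(occ.sum(axis=1) - 1.0) < 1e-12)
            assert np.all(occ >= -1e-15)

    def test_dead_fraction_monotone(self, params, inputs):
        traj = run_cohort(Arm.SOC, params, inputs=inputs, record=True)
        dead = traj.per_day["dead"].to_numpy()
        assert np.all(np.diff(dead) >= -1e-15)

    def test_zero_mortality_zero_events(self, params):
        traj = run_cohort(Arm.EPOCA, params.replace(
            ed_entry_fraction=type(params.ed_entry_fraction)(0.0, 0.0)),
            inputs_override=_zero_rates())
        assert traj.totals["alive_days"] == pytest.approx(3652)
        assert traj.totals["ed_visits"] == 0
        assert traj.totals["adm_direct"] == 0
        assert traj.totals["adm_post"] == 0

    def test_effect_direction(self, params, inputs):
        te = run_cohort(Arm.EPOCA, params, inputs=inputs)
        ts = run_cohort(Arm.SOC, params, inputs=inputs)
        assert te.events_total("ed_visits", params) < ts.events_total(
            "ed_visits", params)
        assert te.events_total("hospitalizations", params) < ts.events_total(
            "hospitalizations", params)
        assert te.totals["hosp_days"] < ts.totals["hosp_days"]

    def test_realized_soc_ed_rate(self, params, inputs):
        """The occupancy correction keeps the realized recurrent ED rate per
        alive person-year at the pilot value (3.4) within 1%."""
        traj = run_cohort(Arm.SOC, params, inputs=inputs)
        realized = traj.totals["ed_visits"] / (traj.totals["alive_days"]
                                               / DAYS_PER_YEAR)
        assert realized == pytest.approx(3.4, rel=0.01)

    def test_realized_hosp_rate(self, params, inputs):
        traj = run_cohort(Arm.SOC, params, inputs=inputs)
        hosp = traj.totals["adm_direct"] + traj.totals["adm_post"]
        realized = hosp / (traj.totals["alive_days"] / DAYS_PER_YEAR)
        assert realized == pytest.approx(4.4, rel=0.01)

    def test_fixed_los_tunnel_variant(self, params):
        """With a fixed-length stay the mean realized stay equals the tunnel
        length (up to death truncation)."""
        p = params.replace(los_model="fixed")
        from epoca_model import derive_model_inputs
        traj = run_cohort(Arm.EPOCA, p, inputs=derive_model_inputs(p))
        adm = traj.totals["adm_direct"] + traj.totals["adm_post"]
        stay = traj.totals["hosp_days"] / adm
        assert stay == pytest.approx(7.0, abs=0.15)  # round(7.3) with truncation


class TestWaning:
    def test_base_fraction_is_one(self, params):
        f = benefit_fraction_vector(params, get_scenario("base"))
        assert np.all(f == 1.0)

    def test_waning_fraction_schedule(self, params):
        f0 = benefit_fraction_vector(params, get_scenario("waning_0m"))
        assert f0[0] == 1.0 and f0[182] == 1.0
        assert f0[183] == pytest.approx(0.41)
        assert f0[365] == pytest.approx(0.22)
        assert f0[731] == pytest.approx(0.22**2)
        f3 = benefit_fraction_vector(params, get_scenario("waning_3m"))
        assert np.all(f3 >= f0)
        f6 = benefit_fraction_vector(params, get_scenario("waning_6m"))
        assert np.all(f6 >= f3)

    def test_waning_increases_epoca_events(self, params, inputs):
        base = run_cohort(Arm.EPOCA, params, inputs=inputs)
        waned = run_cohort(Arm.EPOCA, params, get_scenario("waning_0m"),
                           inputs=inputs)
        assert waned.events_total("ed_visits", params) > base.events_total(
            "ed_visits", params)
        assert waned.totals["hosp_days"] > base.totals["hosp_days"]


class TestMicrosim:
    def test_determinism_under_seed(self, params, inputs):
        a = run_microsim(Arm.SOC, params, n_patients=300, seed=11, inputs=inputs)
        b = run_microsim(Arm.SOC, params, n_patients=300, seed=11, inputs=inputs)
        assert a.totals == b.totals

    def test_zero_mortality_full_survival(self, params):
        p = params.replace(ed_entry_fraction=type(params.ed_entry_fraction)(0.0, 0.0))
        traj = run_microsim(Arm.EPOCA, p, n_patients=50, seed=5,
                            inputs=_wrap_inputs(p, _zero_rates()))
        assert np.all(traj.per_patient["alive_days"] == 3652)

    def test_agrees_with_cohort_engine(self, params, inputs):
        """Sample means match cohort expectations within 3 Monte-Carlo SEs
        (moderate n here; the acceptance suite uses n = 50,000)."""
        for arm in Arm:
            ms = run_microsim(arm, params, n_patients=20_000, seed=77,
                              inputs=inputs)
            coh = run_cohort(arm, params, inputs=inputs)
            for key in ("ed_visits", "adm_direct", "adm_post",
                        "hosp_days", "alive_days"):
                z = (ms.totals[key] - coh.totals[key]) / ms.se[key]
                assert abs(z) < 3.0, (arm, key, z)

    def test_bad_n_raises(self, params, inputs):
        with pytest.raises(ValueError):
            run_microsim(Arm.SOC, params, n_patients=0, inputs=inputs)


def _wrap_inputs(params, override):
    """Build a ModelInputs carrying the same override for both arms."""
    from epoca_model.parameters import ModelInputs
    p_death, ai = override
    return ModelInputs(p_death=p_death, arms={Arm.EPOCA: ai, Arm.SOC: ai},
                       params=params)
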