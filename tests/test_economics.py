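"""Cost accrual, QALYs, discounting and incremental results."""

import numpy as np
import pytest

from epoca_model import (
    Arm,
    DAYS_PER_YEAR,
    Perspective,
    accrue_costs,
    accrue_qalys,
    discount_factor,
    evaluate_strategies,
    get_scenario,
    incremental,
    results_table,
    run_cohort,
)
from epoca_model.economics import ArmOutcome, COST_CATEGORIES
from epoca_model.markov import TrajectoryResult, _TOTAL_KEYS
from epoca_model.parameters import ArmInputs, BASE_SCENARIO, derive_model_inputs


def _traj(arm, n_days=3652, n_years=10, **totals):
    """Hand-built trajectory with explicit totals (discounted twins default
    to the undiscounted values — i.e. events at day 0)."""
    t = {k + sfx: 0.0 for k in _TOTAL_KEYS for sfx in ("", "_disc")}
    for k, v in totals.items():
        t[k] = v
        if k + "_disc" not in totals:
            t[k + "_disc"] = v
    return TrajectoryResult(arm=arm, scenario=BASE_SCENARIO, n_days=n_days,
                            totals=t, alive_at_year_start=np.zeros(n_years))


class TestDiscounting:
    def test_day_zero(self):
        assert discount_factor(0) == 1.0

    def test_one_year(self):
        assert discount_factor(365.25) == pytest.approx(1 / 1.025, rel=1e-12)

    def test_monotone_decreasing(self):
        days = np.arange(0, 4000, 50)
        f = discount_factor(days)
        assert np.all(np.diff(f) < 0)


class TestCostRules:
    def test_outpatient_only_one_alive_year(self, params):
        """Zero-event SOC cohort alive for a year accrues only outpatient
        costs: €5,337/year (collective, undiscounted)."""
        zero = ArmInputs(p_ed=np.float64(0), p_hosp_direct=np.float64(0),
                         p_admit=np.float64(0), p_discharge=np.float64(0.2),
                         occupancy_correction=np.float64(1.0))
        p = params.replace(ed_entry_fraction=type(params.ed_entry_fraction)(0.0, 0.0))
        traj = run_cohort(Arm.SOC, p, inputs_override=(0.0, zero), n_days=365)
        costs_u, _ = accrue_costs(traj, Arm.SOC, p, Perspective.COLLECTIVE)
        expected = 5337.0 * 365 / DAYS_PER_YEAR
        assert costs_u["outpatient"] == pytest.approx(expected, rel=1e-9)
        assert costs_u["outpatient"] == pytest.approx(5337.0, rel=1e-2)
        for cat in ("program", "ed_visits", "hospitalization"):
            assert costs_u[cat] == 0.0

    def test_nhi_admission_tariff(self, params):
        """One direct EPOCA admission costs 3714/1.27 ≈ 2924 for the payer."""
        traj = _traj(Arm.EPOCA, adm_direct=1.0, adm_direct_fw=1.0)
        costs_u, _ = accrue_costs(traj, Arm.EPOCA, params, Perspective.NHI)
        assert costs_u["hospitalization"] == pytest.approx(3714 / 1.27, rel=1e-12)

    def test_post_ed_cost_switch(self, params):
        p = params.replace(use_post_ed_admission_cost=True)
        traj = _traj(Arm.EPOCA, adm_post=1.0, adm_post_fw=1.0)
        costs_u, _ = accrue_costs(traj, Arm.EPOCA, p, Perspective.COLLECTIVE)
        assert costs_u["hospitalization"] == pytest.approx(4249.0)

    def test_ed_visit_pricing_by_perspective(self, params):
        traj = _traj(Arm.SOC, ed_visits=2.0, ed_nonadmitted=1.0)
        cu_coll, _ = accrue_costs(traj, Arm.SOC, params, Perspective.COLLECTIVE)
        cu_nhi, _ = accrue_costs(traj, Arm.SOC, params, Perspective.NHI)
        assert cu_coll["ed_visits"] == pytest.approx(2 * 165.25)
        assert cu_nhi["ed_visits"] == pytest.approx(2 * 52.0)
        p2 = params.replace(nhi_ed_nonadmitted_only=True)
        cu_nhi2, _ = accrue_costs(traj, Arm.SOC, p2, Perspective.NHI)
        assert cu_nhi2["ed_visits"] == pytest.approx(1 * 52.0)

    def test_total_is_sum_of_categories(self, params, inputs):
        for arm in Arm:
            traj = run_cohort(arm, params, inputs=inputs)
            for persp in Perspective:
                cu, cd = accrue_costs(traj, arm, params, persp)
                assert cu["total"] == pytest.approx(
                    sum(cu[c] for c in COST_CATEGORIES), abs=1e-6)
                assert cd["total"] == pytest.approx(
                    sum(cd[c] for c in COST_CATEGORIES), abs=1e-6)

    def test_program_cost_schedule(self, params, inputs):
        """Programme cost = annual payment × enrolled fraction × surviving
        fraction at each year start; without mortality adjustment it equals
        the geometric-continuation closed form (≈ €2,833)."""
        traj = run_cohort(Arm.EPOCA, params, inputs=inputs)
        cu, _ = accrue_costs(traj, Arm.EPOCA, params, Perspective.COLLECTIVE)
        expected = 2210.0 * (1.0 + sum(
            0.22**y * traj.alive_at_year_start[y] for y in range(1, 10)))
        assert cu["program"] == pytest.approx(expected, rel=1e-9)
        p2 = params.replace(program_cost_mortality_adjusted=False)
        cu2, _ = accrue_costs(traj, Arm.EPOCA, p2, Perspective.COLLECTIVE)
        closed_form = 2210.0 * sum(0.22**y for y in range(10))
        assert cu2["program"] == pytest.approx(closed_form, rel=1e-9)


class TestQalys:
    def test_one_healthy_year(self, params):
        traj = _traj(Arm.EPOCA, alive_days=DAYS_PER_YEAR)
        q_u, _ = accrue_qalys(traj, params)
        assert q_u == pytest.approx(0.8)

    def test_hospital_day_disutility(self, params):
        """25 extra hospital days at equal survival cost 25 × 0.0013 =
        0.0325 QALYs undiscounted."""
        base = _traj(Arm.SOC, alive_days=2 * DAYS_PER_YEAR, hosp_days=10.0)
        worse = _traj(Arm.SOC, alive_days=2 * DAYS_PER_YEAR, hosp_days=35.0)
        q1, _ = accrue_qalys(base, params)
        q2, _ = accrue_qalys(worse, params)
        assert q1 - q2 == pytest.approx(0.0325, rel=1e-9)

    def test_zero_alive_days(self, params):
        q_u, q_d = accrue_qalys(_traj(Arm.SOC), params)
        assert q_u == 0.0 and q_d == 0.0

    def test_perspective_independent(self, params, inputs):
        e_c, s_c, _ = evaluate_strategies(params, Perspective.COLLECTIVE,
                                          inputs=inputs)
        e_n, s_n, _ = evaluate_strategies(params, Perspective.NHI,
                                          inputs=inputs)
        assert float(e_c.qaly_disc) == float(e_n.qaly_disc)
        assert float(s_c.qaly_disc) == float(s_n.qaly_disc)


class TestIncremental:
    def _outcome(self, cost, qaly):
        return ArmOutcome(arm=Arm.EPOCA, perspective=Perspective.NHI,
                          events={}, costs={"total": cost},
                          costs_disc={"total": cost}, qaly=qaly,
                          qaly_disc=qaly, life_years=1.0, life_years_disc=1.0)

    def test_dominant(self):
        inc = incremental(self._outcome(20_000, 1.30), self._outcome(27_108, 1.26))
        assert inc.status == "dominant"
        assert inc.delta_cost == pytest.approx(-7108)

    def test_equivalent(self):
        inc = incremental(self._outcome(100.0, 1.0), self._outcome(100.0, 1.0))
        assert inc.status == "equivalent"

    def test_icer_arithmetic(self):
        inc = incremental(self._outcome(1_000, 1.05), self._outcome(0.0, 1.0))
        assert inc.status == "icer"
        assert inc.icer == pytest.approx(20_000)

    def test_dominated(self):
        inc = incremental(self._outcome(1_000, 0.9), self._outcome(0.0, 1.0))
        assert inc.status == "dominated"


class TestInvariants:
    def test_collective_at_least_nhi(self, params, inputs):
        """Production costs ≥ tariffs and collective ED price ≥ payer price,
        so collective totals dominate payer totals in every run."""
        scenarios = [get_scenario(s) for s in
                     ("base", "waning_0m", "waning_3m", "waning_6m")]
        for scen in scenarios:
            for arm in Arm:
                traj = run_cohort(arm, params, scen if arm is Arm.EPOCA
                                  else BASE_SCENARIO, inputs=inputs)
                cu_c, _ = accrue_costs(traj, arm, params, Perspective.COLLECTIVE)
                cu_n, _ = accrue_costs(traj, arm, params, Perspective.NHI)
                assert cu_c["total"] >= cu_n["total"]

    def test_zero_discount_identity(self, params):
        p = params.replace(discount_rate_annual=0.0)
        inp = derive_model_inputs(p)
        for arm in Arm:
            traj = run_cohort(arm, p, inputs=inp)
            for k in ("ed_visits", "hosp_days", "alive_days", "adm_direct"):
                assert traj.totals[k] == pytest.approx(traj.totals[k + "_disc"],
                                                       rel=1e-9)
            cu, cd = accrue_costs(traj, arm, p, Perspective.COLLECTIVE)
            assert cu["total"] == pytest.approx(cd["total"], rel=1e-9)

    def test_discounted_below_undiscounted(self, params, inputs):
        for arm in Arm:
            traj = run_cohort(arm, params, inputs=inputs)
            cu, cd = accrue_costs(traj, arm, params, Perspective.COLLECTIVE)
            for cat in COST_CATEGORIES:
                assert cd[cat] <= cu[cat] + 1e-12

    def test_qaly_bounded_by_life_years(self, params, inputs):
        for arm in Arm:
            traj = run_cohort(arm, params, inputs=inputs)
            q_u, _ = accrue_qalys(traj, params)
            assert q_u <= 0.8 * traj.totals["alive_days"] / DAYS_PER_YEAR + 1e-12

    def test_results_table_shape(self, params, inputs):
        df = results_table(params, inputs=inputs)
        assert {"section", "category", "epoca", "soc", "difference"} <= set(df.columns)
        assert (df[df.category == "total"].shape[0] == 4)  # 2 persp × disc/undisc
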