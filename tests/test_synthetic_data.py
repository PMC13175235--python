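"""Synthetic pilot-cohort generator and parameter estimators."""

import numpy as np
import pytest

from epoca_model import (
    Windows,
    estimate_parameters,
    generate_cohort,
    parameter_set_from_estimates,
)
from epoca_model.parameters import ArmValue
from epoca_model.synthetic_data import EstimationError, load_cohort


class TestGeneration:
    def test_zero_rates_give_empty_histories(self, params):
        p = params.replace(annual_hosp_rate=ArmValue(0.0, 0.0),
                           annual_ed_rate=ArmValue(0.0, 0.0))
        sample = generate_cohort(200, p, seed=1)
        assert len(sample.events) == 0

    def test_seed_reproducibility(self, params):
        a = generate_cohort(300, params, seed=42)
        b = generate_cohort(300, params, seed=42)
        assert a.events.equals(b.events)
        assert a.patients.equals(b.patients)

    def test_history_invariants(self, params):
        sample = generate_cohort(120, params, seed=3)
        for h in sample.histories():
            h.validate()

    def test_no_baseline_mortality(self, params):
        sample = generate_cohort(400, params, seed=8)
        # deaths only during follow-up (pilot patients survived to inclusion)
        dd = sample.patients["death_day"].dropna()
        assert (dd >= 0).all()

    def test_ed_route_fraction(self, params):
        sample = generate_cohort(4000, params, seed=9)
        frac = (sample.patients["route"] == "ED").mean()
        assert frac == pytest.approx(0.30, abs=0.03)


class TestEstimation:
    def test_parameter_recovery_within_3se(self, params):
        """Rates, admission probability, LOS and costs estimated from a
        generated cohort recover the generating values within 3 SEs."""
        sample = generate_cohort(4000, params, seed=101)
        est = estimate_parameters(sample)
        checks = [
            (est.baseline.annual_hosp_rate, est.baseline.annual_hosp_rate_se, 4.4),
            (est.baseline.annual_ed_rate, est.baseline.annual_ed_rate_se, 3.4),
            (est.followup.annual_hosp_rate, est.followup.annual_hosp_rate_se, 2.4),
            (est.followup.annual_ed_rate, est.followup.annual_ed_rate_se, 1.6),
            (est.baseline.p_admit_after_ed, est.baseline.p_admit_after_ed_se, 0.71),
            (est.followup.p_admit_after_ed, est.followup.p_admit_after_ed_se, 0.69),
            (est.baseline.mean_los, est.baseline.mean_los_se, 7.7),
            (est.followup.mean_los, est.followup.mean_los_se, 7.3),
            (est.baseline.mean_cost_per_admission,
             est.baseline.mean_cost_per_admission_se, 3773.0),
            (est.followup.mean_cost_per_admission,
             est.followup.mean_cost_per_admission_se, 3714.0),
        ]
        for value, se, target in checks:
            assert abs(value - target) < 3 * se, (value, se, target)

    def test_every_ed_visit_admitted(self, params):
        p = params.replace(p_admit_after_ed=ArmValue(1.0, 1.0))
        sample = generate_cohort(500, p, seed=5)
        est = estimate_parameters(sample)
        assert est.baseline.p_admit_after_ed == 1.0
        assert est.followup.p_admit_after_ed == 1.0

    def test_se_shrinks_as_sqrt_n(self, params):
        ses = []
        for n in (500, 2000, 8000):
            sample = generate_cohort(n, params, seed=7)
            ses.append(estimate_parameters(sample).baseline.annual_hosp_rate_se)
        assert ses[0] > ses[1] > ses[2]
        ratio = ses[0] / ses[2]   # expected √16 = 4
        assert 2.5 < ratio < 6.0

    def test_pooled_rate_between_strata(self, params):
        a = generate_cohort(800, params, seed=21)
        b = generate_cohort(800, params, seed=22)
        ra = estimate_parameters(a).baseline.annual_ed_rate
        rb = estimate_parameters(b).baseline.annual_ed_rate
        ev = len(a.events[(a.events.day < 0) & (a.events.type == "ed_visit")]) \
            + len(b.events[(b.events.day < 0) & (b.events.type == "ed_visit")])
        pt = estimate_parameters(a).baseline.person_years \
            + estimate_parameters(b).baseline.person_years
        pooled = ev / pt
        assert min(ra, rb) <= pooled <= max(ra, rb)

    def test_zero_person_time_errors(self, params):
        sample = generate_cohort(5, params, windows=Windows(1, 1), seed=1)
        sample.patients["death_day"] = 0.0  # everyone dies at inclusion
        with pytest.raises(EstimationError):
            estimate_parameters(sample)

    def test_at_home_exposure_rate_higher(self, params):
        """Out-of-hospital exposure is shorter than calendar exposure, so
        at-home rates exceed calendar rates."""
        sample = generate_cohort(1500, params, seed=13)
        cal = estimate_parameters(sample, exposure="calendar")
        home = estimate_parameters(sample, exposure="at_home")
        assert home.baseline.annual_hosp_rate > cal.baseline.annual_hosp_rate


class TestRoundTrips:
    def test_csv_round_trip(self, params, tmp_path):
        sample = generate_cohort(150, params, seed=31)
        sample.export(tmp_path)
        loaded = load_cohort(tmp_path, params)
        e1 = estimate_parameters(sample)
        e2 = estimate_parameters(loaded)
        assert e1.baseline.annual_hosp_rate == pytest.approx(
            e2.baseline.annual_hosp_rate)
        assert e1.followup.mean_los == pytest.approx(e2.followup.mean_los)

    def test_estimates_feed_back_into_parameter_set(self, params):
        sample = generate_cohort(1000, params, seed=77)
        est = estimate_parameters(sample)
        p2 = parameter_set_from_estimates(est, params)
        assert p2.annual_hosp_rate.soc == pytest.approx(
            est.baseline.annual_hosp_rate)
        assert p2.mean_los.epoca == pytest.approx(est.followup.mean_los)
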