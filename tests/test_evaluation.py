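import numpy as np
import pytest

from hccsurv.evaluation import (
    budget_sweep,
    compare_schedules,
    delay_for_patient,
    delay_in_days,
    evaluate_schedule,
    paired_delay_tests,
)
from hccsurv.hazard import MonthlyRiskProfile, km_profile
from hccsurv.scheduling import Schedule, fixed_schedule
from hccsurv.synthetic import default_generator_config, generate_cohort

from .conftest import make_cohort


class TestPatientDelay:
    def test_day_unit_worked_example(self):
        """Progression on day 200 with the next visit on day 240 -> 40 days."""
        sched = fixed_schedule([4, 8, 12], horizon=36)  # visit at month 8 = day 240
        assert delay_in_days(200.0, sched) == pytest.approx(40.0)

    def test_zero_delay_at_visit_month(self):
        assert delay_for_patient(9.0, fixed_schedule("recommended7")) == 0.0

    def test_horizon_boundary_after_last_visit(self):
        # last visit of the 7-visit recommendation is month 30; horizon 36
        assert delay_for_patient(31.0, fixed_schedule("recommended7")) == pytest.approx(5.0)

    def test_beyond_horizon_excluded(self):
        assert delay_for_patient(37.0, fixed_schedule("ecio")) is None

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            delay_for_patient(0.0, fixed_schedule("ecio"))


class TestEvaluateSchedule:
    def test_hand_enumerated_delays(self):
        c = make_cohort([2.0, 9.0, 20.0], [True, True, True])
        ev = evaluate_schedule(c, fixed_schedule("uniform6"))
        assert sorted(ev.per_patient_delay.values()) == [3.0, 4.0, 4.0]
        assert ev.total_delay == pytest.approx(11.0)
        assert ev.n_evaluated == 3

    def test_visits_coinciding_with_events_give_zero_total(self):
        c = make_cohort([6.0, 12.0, 24.0], [True, True, True])
        ev = evaluate_schedule(c, fixed_schedule("uniform6"))
        assert ev.total_delay == 0.0

    def test_censored_patients_excluded(self):
        c = make_cohort([2.0, 9.0], [True, False])
        ev = evaluate_schedule(c, fixed_schedule("uniform6"))
        assert ev.n_evaluated == 1

    def test_no_evaluable_patients_rejected(self):
        c = make_cohort([5.0, 6.0], [False, False])
        with pytest.raises(ValueError, match="evaluable"):
            evaluate_schedule(c, fixed_schedule("uniform6"))

    def test_superset_of_visits_never_increases_delays(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            times = rng.uniform(0.5, 36.0, size=30)
            c = make_cohort(times, [True] * 30, seed=int(rng.integers(1000)))
            base = sorted(rng.choice(np.arange(1, 37), size=5, replace=False))
            extra = sorted(set(base) | {int(rng.integers(1, 37))})
            ev_a = evaluate_schedule(c, Schedule(tuple(base), horizon=36))
            ev_b = evaluate_schedule(c, Schedule(tuple(extra), horizon=36))
            for pid, d in ev_b.per_patient_delay.items():
                assert d <= ev_a.per_patient_delay[pid] + 1e-12


class TestComparison:
    def test_identical_schedules_degenerate(self):
        c = make_cohort([2.0, 9.0, 20.0], [True] * 3)
        cmp = compare_schedules(c, fixed_schedule("uniform6"), fixed_schedule("uniform6"))
        assert cmp.degenerate
        assert cmp.mean_difference == 0.0
        assert cmp.paired_t_p == 1.0

    def test_constant_shift_mean_difference(self):
        cmp = paired_delay_tests(np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0]))
        assert cmp.mean_difference == pytest.approx(-1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_delay_tests(np.array([1.0]), np.array([2.0]))

    def test_paired_t_type_one_error_calibrated(self):
        """Under no true schedule difference the paired t rejects ~5% of the time."""
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            base = rng.exponential(2.0, size=50)
            da = base + rng.normal(0, 0.3, size=50)
            db = base + rng.normal(0, 0.3, size=50)
            if paired_delay_tests(da, db).paired_t_p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07


@pytest.fixture(scope="module")
def big_cohort():
    # ~5,000 progressors for the empirical delay-vs-budget trend
    return generate_cohort(default_generator_config(n=9000, seed=19))


class TestBudgetSweep:
    def test_row_count_and_empirical_trend(self, big_cohort):
        prof = km_profile(big_cohort, 36)
        sweep = budget_sweep(big_cohort, prof, budgets=(6, 7, 8, 9, 10, 11),
                             controls=("ecio", "uniform6"))
        assert len(sweep) == 6 + 2
        totals = sweep[sweep["name"].str.contains("_k")]["total_delay_months"].to_numpy()
        # nonincreasing in budget, 1% Monte-Carlo slack
        assert all(a >= b - 0.01 * a for a, b in zip(totals, totals[1:]))

    def test_expected_delay_column_monotone(self, big_cohort):
        prof = km_profile(big_cohort, 36)
        sweep = budget_sweep(big_cohort, prof, budgets=(6, 7, 8, 9, 10, 11))
        exp = sweep[sweep["name"].str.contains("_k")]["expected_delay_months"].to_numpy()
        assert all(a >= b - 1e-12 for a, b in zip(exp, exp[1:]))

    def test_empty_budgets_rejected(self, big_cohort):
        prof = km_profile(big_cohort, 36)
        with pytest.raises(ValueError):
            budget_sweep(big_cohort, prof, budgets=())


def test_empirical_mean_delay_converges_to_expected_delay():
    """Sampling 100,000 event times from a profile reproduces expected_delay."""
    rng = np.random.default_rng(77)
    mass = rng.random(36)
    mass *= 0.7 / mass.sum()
    prof = MonthlyRiskProfile.from_mass(mass, source="true_generator")
    sched = fixed_schedule("ecio")
    months = rng.choice(36, size=100_000, p=mass / mass.sum()) + 1
    mc = np.mean([sched.next_visit(m) - m for m in months]) * mass.sum()
    from hccsurv.scheduling import expected_delay

    assert mc == pytest.approx(expected_delay(prof, sched), rel=0.02)
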