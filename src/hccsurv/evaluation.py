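"""Delayed-detection evaluation and schedule comparison.

The delayed-detection time for a progressed patient is the interval from the
progression time to the next scheduled visit at or after it (for example, a
patient progressing on day 200 whose next scheduled visit falls on day 240
has a 40-day delay).  Totals are accumulated over progressed patients only;
censored patients contribute nothing, and progressions beyond the horizon
fall outside the surveillance window and are excluded.

Schedules are compared on paired per-patient delays with a two-sided paired
t-test and rank tests.  The design is paired, so the Wilcoxon signed-rank
test is the primary rank test; a Kruskal-Wallis test on the two delay
samples (which ignores the pairing) is reported alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .hazard import MonthlyRiskProfile
from .scheduling import (
    Schedule,
    expected_delay,
    fixed_schedule,
    min_expected_delay_schedule,
    top_mass_schedule,
)

DAYS_PER_MONTH = 30.0  # display-unit conversion only; never used internally


def delay_for_patient(t: float, schedule: Schedule, horizon: int | None = None) -> float | None:
    """Months from progression at time t to the next visit at or after t.

    Returns None when t lies beyond the horizon (outside the surveillance
    window; the patient is excluded, not an error).  A progression exactly at
    a visit month has zero delay; progressions after the last visit are
    detected at the horizon boundary.
    """
    H = horizon if horizon is not None else schedule.horizon
    if t <= 0:
        raise ValueError("progression time must be positive")
    if t > H:
        return None
    return schedule.next_visit(t) - t


def delay_in_days(t_days: float, schedule: Schedule, horizon: int | None = None) -> float | None:
    """Day-unit convenience wrapper: converts at 30 days per month for display."""
    d = delay_for_patient(t_days / DAYS_PER_MONTH, schedule, horizon)
    return None if d is None else d * DAYS_PER_MONTH


@dataclass
class DelayEvaluation:
    schedule: Schedule
    per_patient_delay: dict[str, float]
    n_excluded_beyond_horizon: int = 0

    @property
    def n_evaluated(self) -> int:
        return len(self.per_patient_delay)

    @property
    def total_delay(self) -> float:
        return float(sum(self.per_patient_delay.values()))

    @property
    def mean_delay(self) -> float:
        return self.total_delay / self.n_evaluated

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": list(self.per_patient_delay),
                "delay_months": list(self.per_patient_delay.values()),
            }
        )

    def summary(self) -> dict:
        return {
            "schedule": list(self.schedule.visit_months),
            "method": self.schedule.method,
            "budget": self.schedule.budget,
            "n_evaluated": self.n_evaluated,
            "n_excluded_beyond_horizon": self.n_excluded_beyond_horizon,
            "total_delay_months": self.total_delay,
            "mean_delay_months": self.mean_delay,
        }


def evaluate_schedule(cohort: Cohort, schedule: Schedule) -> DelayEvaluation:
    """Per-patient delayed-detection months over all evaluable progressors."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    H = schedule.horizon
    delays: dict[str, float] = {}
    excluded = 0
    prog = cohort.data[cohort.data["event"]]
    for pid, t in zip(prog["patient_id"], prog["pfs_months"]):
        d = delay_for_patient(float(t), schedule, H)
        if d is None:
            excluded += 1
        else:
            delays[str(pid)] = d
    if not delays:
        raise ValueError("no evaluable progressed patients within the horizon")
    return DelayEvaluation(schedule, delays, n_excluded_beyond_horizon=excluded)


@dataclass
class ScheduleComparison:
    """Paired comparison of two schedules on the same progressed patients."""

    delta_per_patient: np.ndarray  # schedule A delay - schedule B delay
    mean_difference: float
    paired_t_p: float
    rank_test_p: float  # Wilcoxon signed-rank (primary, paired)
    kruskal_p: float  # Kruskal-Wallis on the two samples (unpaired)
    degenerate: bool = False  # all paired differences exactly zero

    def summary(self) -> dict:
        return {
            "n_pairs": int(len(self.delta_per_patient)),
            "mean_difference_months": self.mean_difference,
            "paired_t_p": self.paired_t_p,
            "wilcoxon_p": self.rank_test_p,
            "kruskal_wallis_p": self.kruskal_p,
            "degenerate": self.degenerate,
        }


def paired_delay_tests(da: np.ndarray, db: np.ndarray) -> ScheduleComparison:
    """Two-sided paired t, Wilcoxon signed-rank and Kruskal-Wallis on delay pairs.

    All-zero differences (identical schedules) are a degenerate case flagged
    with p-values of 1.
    """
    da = np.asarray(da, float)
    db = np.asarray(db, float)
    if len(da) != len(db) or len(da) < 2:
        raise ValueError("need at least two equal-length delay pairs")
    delta = da - db
    if np.all(delta == 0.0):
        return ScheduleComparison(delta, 0.0, 1.0, 1.0, 1.0, degenerate=True)
    t_p = float(stats.ttest_rel(da, db).pvalue)
    w_p = float(stats.wilcoxon(da, db, zero_method="wilcox").pvalue)
    k_p = float(stats.kruskal(da, db).pvalue)
    return ScheduleComparison(delta, float(delta.mean()), t_p, w_p, k_p)


def compare_schedules(cohort: Cohort, a: Schedule, b: Schedule) -> ScheduleComparison:
    """Two-sided paired tests of per-patient delays under schedules a and b."""
    if a.horizon != b.horizon:
        raise ValueError("schedules must share a horizon")
    ev_a = evaluate_schedule(cohort, a)
    ev_b = evaluate_schedule(cohort, b)
    ids = sorted(ev_a.per_patient_delay)  # same evaluable set by construction
    da = np.array([ev_a.per_patient_delay[i] for i in ids])
    db = np.array([ev_b.per_patient_delay[i] for i in ids])
    return paired_delay_tests(da, db)


def budget_sweep(
    cohort: Cohort,
    profile: MonthlyRiskProfile,
    budgets: tuple[int, ...] = (6, 7, 8, 9, 10, 11),
    method: str = "min_expected_delay",
    controls: tuple[str, ...] = ("ecio",),
) -> pd.DataFrame:
    """Risk-based schedules across visit budgets plus named controls.

    One row per budget (allocation from the profile by the configured
    method) and one per control, with the analytic expected delay and the
    empirical total/mean delay on the cohort's progressors.
    """
    if not budgets:
        raise ValueError("budgets must be nonempty")
    allocate = {
        "min_expected_delay": min_expected_delay_schedule,
        "top_mass": top_mass_schedule,
    }[method]
    rows = []
    for k in budgets:
        sched = allocate(profile, k)
        ev = evaluate_schedule(cohort, sched)
        rows.append(
            {
                "name": f"{method}_k{k}",
                "budget": k,
                "visit_months": sched.visit_months,
                "expected_delay_months": expected_delay(profile, sched),
                "total_delay_months": ev.total_delay,
                "mean_delay_months": ev.mean_delay,
                "n_evaluated": ev.n_evaluated,
            }
        )
    for name in controls:
        sched = fixed_schedule(name, horizon=profile.horizon)
        ev = evaluate_schedule(cohort, sched)
        rows.append(
            {
                "name": name,
                "budget": sched.budget,
                "visit_months": sched.visit_months,
                "expected_delay_months": expected_delay(profile, sched),
                "total_delay_months": ev.total_delay,
                "mean_delay_months": ev.mean_delay,
                "n_evaluated": ev.n_evaluated,
            }
        )
    return pd.DataFrame(rows)
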