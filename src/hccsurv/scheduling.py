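"""Follow-up visit allocation under a fixed budget.

A schedule is a strictly increasing set of visit months within the horizon,
at most one visit per month.  Two allocation rules are provided:

* ``top_mass_schedule`` — visit the k months with the largest monthly
  progression-probability mass (ties to the earlier month);
* ``min_expected_delay_schedule`` — the size-k visit set minimizing the
  expected delay between progression and the next visit, found exactly by
  dynamic programming over (last visit, visits used).

Progression after the final visit is charged delay up to the horizon
boundary H: an implicit end-of-surveillance assessment closes the window.
A visit at month v detects any progression with t <= v, so delay at a visit
month is zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .hazard import MonthlyRiskProfile

#: Built-in control schedules over the 36-month horizon.
#: ``ecio`` is the ECIO/ESOI consensus follow-up grid; ``uniform6`` and
#: ``uniform11`` are the even comparators (every 6 months; every 3 months
#: from month 4); ``recommended7`` is the published risk-based 7-visit grid.
NAMED_SCHEDULES: dict[str, tuple[int, ...]] = {
    "ecio": (1, 3, 6, 9, 12, 18, 24, 30, 36),
    "uniform6": (6, 12, 18, 24, 30, 36),
    "uniform11": (4, 7, 10, 13, 16, 19, 22, 25, 28, 31, 34),
    "recommended7": (5, 7, 9, 11, 17, 23, 30),
}


@dataclass(frozen=True)
class Schedule:
    visit_months: tuple[int, ...]
    horizon: int = 36
    method: str = "fixed"  # {"top_mass", "min_expected_delay", "fixed"}

    def __post_init__(self) -> None:
        v = self.visit_months
        if len(v) == 0:
            raise ValueError("schedule needs at least one visit")
        if any(int(m) != m for m in v):
            raise ValueError("visit months must be integers")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("visit months must be strictly increasing")
        if v[0] < 1 or v[-1] > self.horizon:
            raise ValueError(f"visit months must lie in [1, {self.horizon}]")
        object.__setattr__(self, "visit_months", tuple(int(m) for m in v))

    @property
    def budget(self) -> int:
        return len(self.visit_months)

    def next_visit(self, t: float) -> float:
        """Earliest visit at or after time t; the horizon if none remains."""
        for v in self.visit_months:
            if v >= t:
                return float(v)
        return float(self.horizon)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "method": self.method,
                "horizon": self.horizon,
                "budget": self.budget,
                "visit_months": list(self.visit_months),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "Schedule":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        obj = json.loads(text)
        return cls(
            tuple(obj["visit_months"]),
            horizon=int(obj["horizon"]),
            method=obj.get("method", "fixed"),
        )


def fixed_schedule(
    name_or_months: str | Iterable[int], horizon: int = 36
) -> Schedule:
    """A named control schedule or an arbitrary custom visit list."""
    if isinstance(name_or_months, str):
        try:
            months = NAMED_SCHEDULES[name_or_months]
        except KeyError:
            raise KeyError(
                f"unknown schedule {name_or_months!r}; "
                f"known: {sorted(NAMED_SCHEDULES)}"
            ) from None
    else:
        months = tuple(name_or_months)
    return Schedule(months, horizon=horizon, method="fixed")


def top_mass_schedule(profile: MonthlyRiskProfile, k: int) -> Schedule:
    """Visit the k months with the largest progression mass (ties: earlier month)."""
    H = profile.horizon
    if not 1 <= k <= H:
        raise ValueError(f"budget k={k} must lie in [1, {H}]")
    # quantize so reconstruction round-off cannot break exact ties,
    # then stable sort -> earlier month wins a tie
    mass = np.round(profile.mass, 12)
    order = np.argsort(-mass, kind="stable")
    months = tuple(sorted(int(m) + 1 for m in order[:k]))
    return Schedule(months, horizon=H, method="top_mass")


def expected_delay(profile: MonthlyRiskProfile, schedule: Schedule) -> float:
    """Expected months from progression to the next visit, over the profile.

    sum_m p_m (next(m) - m), where next(m) is the first visit at or after
    month m, or the horizon boundary when none remains.
    """
    H = profile.horizon
    if schedule.visit_months[-1] > H:
        raise ValueError("schedule extends beyond the profile horizon")
    total = 0.0
    for m, p in enumerate(profile.mass, start=1):
        total += p * (schedule.next_visit(m) - m)
    return float(total)


def _prefix_sums(mass: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    months = np.arange(1, len(mass) + 1, dtype=float)
    P = np.concatenate([[0.0], np.cumsum(mass)])
    W = np.concatenate([[0.0], np.cumsum(mass * months)])
    return P, W


def min_expected_delay_schedule(profile: MonthlyRiskProfile, k: int) -> Schedule:
    """The size-k visit set minimizing expected delay (exact DP, O(H^2 k)).

    State: (months remaining after last visit u, visits left j); transition
    places the next visit at v > u, charging sum_{u<m<=v} p_m (v - m).  Mass
    after the final visit is charged to the horizon boundary.  Ties are
    broken toward the lexicographically earliest visit set.
    """
    H = profile.horizon
    if not 1 <= k <= H:
        raise ValueError(f"budget k={k} must lie in [1, {H}]")
    mass = profile.mass
    P, W = _prefix_sums(mass)

    def seg(u: int, v: int) -> float:
        # cost of months u+1..v when the next visit is at v
        return v * (P[v] - P[u]) - (W[v] - W[u])

    def tail(u: int) -> float:
        # months after the last visit u detected at the horizon boundary
        return H * (P[H] - P[u]) - (W[H] - W[u])

    # g[j][u]: minimal cost of months > u given j visits remain
    g = np.empty((k + 1, H + 1))
    g[0] = [tail(u) for u in range(H + 1)]
    for j in range(1, k + 1):
        for u in range(H + 1):
            if H - u < j:  # not enough months left to place j visits
                g[j][u] = np.inf
                continue
            g[j][u] = min(seg(u, v) + g[j - 1][v] for v in range(u + 1, H + 1))

    # reconstruct, preferring the earliest feasible visit on (near-)ties
    visits: list[int] = []
    u = 0
    for j in range(k, 0, -1):
        best = g[j][u]
        tol = 1e-12 * max(1.0, abs(best))
        for v in range(u + 1, H + 1):
            if seg(u, v) + g[j - 1][v] <= best + tol:
                visits.append(v)
                u = v
                break
    return Schedule(tuple(visits), horizon=H, method="min_expected_delay")
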