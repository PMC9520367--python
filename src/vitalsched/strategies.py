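"""Rule-based charting strategies and the variable-schedule grid search.

Five strategies are compared in this framework:

* ``actual`` — the nurse charting recorded in the visit;
* ``equal_spacing`` — the same number of events spread evenly over the visit
  (retrospective: it knows the visit duration and event count);
* ``fixed_schedule`` — charting at rooming then at a fixed per-ESI interval
  (prospective; defaults ESI 1: 13, 2: 45, 3: 71, 4: 65 minutes);
* ``variable_schedule`` — prospective two-speed rule: recheck after a large
  step while observations stay within the coverage bounds of the previous
  observation, after a small step otherwise (the selected policy is the
  80/40-minute rule);
* ``optimized`` — coverage-maximising placement (see :mod:`.optimizer`).

The grid search evaluates all (large, small) step combinations on a cohort
and selects the pair whose mean events/visit is closest to, but not
exceeding, the actual charting budget.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coverage import coverage
from .types import COVERAGE_BOUNDS, MODALITIES, ChartEvent, Visit

logger = logging.getLogger(__name__)

#: Default per-ESI charting intervals (minutes): the median interval between
#: actual charting events for visits triaged at each ESI level.
FIXED_SCHEDULE_INTERVALS: dict[int, int] = {1: 13, 2: 45, 3: 71, 4: 65}

#: Default grid-search ranges (minutes).
DEFAULT_LARGE_GRID: tuple[int, ...] = tuple(range(20, 121, 10))
DEFAULT_SMALL_GRID: tuple[int, ...] = tuple(range(10, 91, 10))

STRATEGY_KINDS = ("actual", "equal_spacing", "fixed_schedule", "variable_schedule", "optimized")


def equal_spacing_times(visit: Visit, k: int) -> list[int]:
    """``k`` charting times evenly spanning [0, duration-1], endpoints anchored.

    For k >= 2, time_i = round(i (D-1)/(k-1)); duplicates arising on very
    short visits are collapsed.  k = 0 gives no events.
    """
    if k < 0:
        raise ValueError("k must be nonnegative")
    if k == 0:
        return []
    duration = visit.duration_min
    if k == 1:
        return [0]
    times = [int(round(i * (duration - 1) / (k - 1))) for i in range(k)]
    return sorted(set(times))


def fixed_schedule_times(
    visit: Visit,
    esi_intervals: Optional[dict[int, int]] = None,
    fallback_interval: int = 65,
) -> list[int]:
    """Charting at rooming then every ESI-specific interval until departure."""
    intervals = esi_intervals if esi_intervals is not None else FIXED_SCHEDULE_INTERVALS
    interval = intervals.get(visit.esi)
    if interval is None:
        logger.warning(
            "fixed_schedule: no interval for ESI %d, using fallback %d min",
            visit.esi,
            fallback_interval,
        )
        interval = fallback_interval
    if interval < 1:
        raise ValueError("charting interval must be at least 1 minute")
    return list(range(0, visit.duration_min, interval))


def _defined_count(visit: Visit, minute: int) -> int:
    return sum(
        1
        for trace in visit.traces.values()
        if 0 <= minute < trace.duration and trace.defined_mask[minute]
    )


def _observe(visit: Visit, minute: int) -> dict[str, float]:
    obs = {}
    for mod, trace in visit.traces.items():
        v = trace.value_at(minute)
        if v is not None:
            obs[mod] = v
    return obs


def variable_schedule_times(
    visit: Visit,
    large_step: int,
    small_step: int,
    bounds: Optional[dict[str, float]] = None,
) -> list[int]:
    """Online two-speed schedule.

    The first observation happens at the first minute where at least two
    modalities are defined.  At each observation the current monitor values
    are compared with the previous observation (the triage vitals for the
    first in-room observation): if every modality present in both lies
    within its coverage bound the patient is deemed stable and the next
    observation follows after ``large_step`` minutes, otherwise after
    ``small_step``.  A missing triage makes the first check count as
    unstable.  MAP participates only at minutes where a cuff-derived value
    exists.
    """
    if large_step < 1 or small_step < 1:
        raise ValueError("steps must be at least 1 minute")
    if bounds is None:
        bounds = COVERAGE_BOUNDS
    duration = visit.duration_min
    start = next((m for m in range(duration) if _defined_count(visit, m) >= 2), None)
    if start is None:
        logger.warning("variable_schedule: visit %s never has 2 defined modalities", visit.visit_id)
        return []
    prev: Optional[dict[str, float]] = (
        dict(visit.triage.recorded) if visit.triage is not None else None
    )
    times: list[int] = []
    t = start
    while t < duration:
        times.append(t)
        cur = _observe(visit, t)
        if prev is None:
            stable = False  # no triage reference: treat the first check as unstable
        else:
            common = [m for m in cur if m in prev]
            stable = all(abs(cur[m] - prev[m]) <= bounds[m] for m in common)
        prev = cur
        t += large_step if stable else small_step
    return times


def realize_charting(visit: Visit, times: Sequence[int]) -> list[ChartEvent]:
    """Turn a list of charting minutes into events recording monitor values.

    Each event records, for every modality defined at that minute, the
    monitor 1-minute value (the carried-forward cuff value for MAP).  Times
    at which no modality is defined are dropped.
    """
    events = []
    for t in sorted(set(int(t) for t in times)):
        if not 0 <= t < visit.duration_min:
            raise ValueError(f"charting time {t} outside the visit")
        recorded = _observe(visit, t)
        if not recorded:
            logger.warning("realize_charting: no defined modality at minute %d, dropping", t)
            continue
        events.append(ChartEvent(minute=t, recorded=recorded))
    return events


def strategy_times(
    visit: Visit,
    kind: str,
    *,
    large_step: int = 80,
    small_step: int = 40,
    esi_intervals: Optional[dict[int, int]] = None,
    bounds: Optional[dict[str, float]] = None,
) -> list[int]:
    """Charting minutes for one of the rule-based strategies."""
    if kind == "actual":
        return [e.minute for e in visit.actual_charting]
    if kind == "equal_spacing":
        return equal_spacing_times(visit, len(visit.actual_charting))
    if kind == "fixed_schedule":
        return fixed_schedule_times(visit, esi_intervals)
    if kind == "variable_schedule":
        return variable_schedule_times(visit, large_step, small_step, bounds)
    raise ValueError(f"unknown strategy kind {kind!r}")


# ---------------------------------------------------------------------------
# Grid search over variable-schedule steps
# ---------------------------------------------------------------------------


@dataclass
class GridSearchResult:
    """Outcome of the (large, small) step grid search on a cohort."""

    table: pd.DataFrame  # columns: large_step, small_step, mean_coverage, mean_events
    selected: tuple[int, int]
    reference_budget: float
    feasible: bool
    flags: list[str] = field(default_factory=list)


def actual_events_per_visit(cohort: Sequence[Visit]) -> float:
    return float(np.mean([len(v.actual_charting) for v in cohort]))


def grid_search(
    cohort: Sequence[Visit],
    large_grid: Sequence[int] = DEFAULT_LARGE_GRID,
    small_grid: Sequence[int] = DEFAULT_SMALL_GRID,
    bounds: Optional[dict[str, float]] = None,
    reference_budget: Optional[float] = None,
) -> GridSearchResult:
    """Evaluate every (large, small) pair on the cohort and select a policy.

    For each pair, every visit is charted by the online variable schedule;
    the cell records the modality-averaged mean coverage and the mean number
    of events per visit.  The selected pair is the one with mean events
    closest to, but not above, the reference budget (mean actual events per
    visit by default); ties prefer higher coverage, then a smaller small
    step.  If no pair fits the budget, the pair with fewest events is
    returned and flagged.
    """
    if not len(cohort):
        raise ValueError("cohort must be nonempty")
    if not len(large_grid) or not len(small_grid):
        raise ValueError("grids must be nonempty")
    if reference_budget is None:
        reference_budget = actual_events_per_visit(cohort)
    if reference_budget <= 0:
        raise ValueError("reference budget must be positive")
    rows = []
    for large in large_grid:
        for small in small_grid:
            covs = []
            n_events = []
            for visit in cohort:
                times = variable_schedule_times(visit, large, small, bounds)
                events = realize_charting(visit, times)
                res = coverage(visit, events, bounds)
                covs.append(res.mean_fraction(list(visit.traces)))
                n_events.append(len(events))
            rows.append((large, small, float(np.mean(covs)), float(np.mean(n_events))))
    table = pd.DataFrame(rows, columns=["large_step", "small_step", "mean_coverage", "mean_events"])
    feasible = table[table["mean_events"] <= reference_budget]
    flags = []
    if len(feasible):
        ranked = feasible.sort_values(
            by=["mean_events", "mean_coverage", "small_step"],
            ascending=[False, False, True],
            kind="mergesort",
        )
        best = ranked.iloc[0]
        selected = (int(best["large_step"]), int(best["small_step"]))
        ok = True
    else:
        flags.append("no_feasible_pair")
        logger.warning("grid_search: no (large, small) pair fits budget %.2f", reference_budget)
        ranked = table.sort_values(
            by=["mean_events", "mean_coverage", "small_step"],
            ascending=[True, False, True],
            kind="mergesort",
        )
        best = ranked.iloc[0]
        selected = (int(best["large_step"]), int(best["small_step"]))
        ok = False
    return GridSearchResult(table, selected, float(reference_budget), ok, flags)


def event_decile_distribution(
    cohort: Sequence[Visit], events_by_visit: dict[str, Sequence[int]]
) -> pd.DataFrame:
    """Proportion of charting events falling in each tenth of the visit."""
    counts = np.zeros(10, dtype=int)
    for visit in cohort:
        for t in events_by_visit.get(visit.visit_id, ()):  # triage excluded
            decile = min(int(10 * t / visit.duration_min), 9)
            counts[decile] += 1
    total = counts.sum()
    props = counts / total if total else np.zeros(10)
    return pd.DataFrame(
        {"decile": np.arange(1, 11), "n_events": counts, "proportion": props}
    )
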