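"""Coverage-maximising placement of charting events (the optimized strategy).

Given full knowledge of a visit, place at most K charting events so that the
weighted number of covered monitor minutes, summed over modalities, is
maximal.  Because the coverage reference is always the most recent event,
the objective decomposes over the segments between consecutive events: the
minutes in [e_i, e_{i+1}) are scored against the values charted at e_i, and
the minutes before the first event against the triage observation (or not at
all if triage is absent).  That additivity admits an exact dynamic program
over (last event minute, events used), validated here against exhaustive
enumeration on small instances.

The optimum is an upper bound on what any charting policy — actual nursing
practice or the rule-based strategies — can achieve with the same number of
events; it is retrospective by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .coverage import coverage
from .strategies import realize_charting
from .types import COVERAGE_BOUNDS, ChartEvent, Visit

_EPS = 1e-6  # tie tolerance for float objectives (exact for integer weights)


@dataclass
class PlacementProblem:
    """A budgeted placement instance: visit, budget K, bounds and weights."""

    visit: Visit
    budget: Optional[int] = None  # default: number of actual charting events
    bounds: dict[str, float] = field(default_factory=lambda: dict(COVERAGE_BOUNDS))
    modality_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.budget is None:
            self.budget = len(self.visit.actual_charting)
        if self.budget < 0:
            raise ValueError("budget must be nonnegative")
        for mod in self.visit.traces:
            self.modality_weights.setdefault(mod, 1.0)
        if any(w < 0 for w in self.modality_weights.values()):
            raise ValueError("modality weights must be nonnegative")


@dataclass
class PlacementSolution:
    """Chosen event minutes, realized per-modality coverage, and objective."""

    minutes: list[int]
    coverage_fractions: dict[str, float]
    objective: float


def interval_gain(
    visit: Visit,
    ref_minute: int,
    from_minute: int,
    to_minute: int,
    bounds: Optional[dict[str, float]] = None,
    weights: Optional[dict[str, float]] = None,
) -> float:
    """Weighted count of minutes in [from, to) covered by the ``ref_minute`` values.

    Modalities undefined at the reference minute contribute nothing (their
    reference would not have been charted).
    """
    if not 0 <= ref_minute <= from_minute <= to_minute <= visit.duration_min:
        raise ValueError("require 0 <= ref <= from <= to <= duration")
    if bounds is None:
        bounds = COVERAGE_BOUNDS
    total = 0.0
    for mod, trace in visit.traces.items():
        w = 1.0 if weights is None else weights.get(mod, 1.0)
        if w == 0 or not trace.defined_mask[ref_minute]:
            continue
        ref = trace.values[ref_minute]
        seg_vals = trace.values[from_minute:to_minute]
        seg_def = trace.defined_mask[from_minute:to_minute]
        with np.errstate(invalid="ignore"):
            within = np.abs(seg_vals - ref) <= bounds[mod]
        total += w * float(np.sum(within & seg_def))
    return total


def _prefix_matrices(problem: PlacementProblem) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative gain tables for the DP.

    ``P[ref, t]`` is the weighted covered count of minutes [0, t) scored
    against minute ``ref``; ``P0[t]`` the same against the triage
    observation (zero if absent).
    """
    visit = problem.visit
    duration = visit.duration_min
    gain = np.zeros((duration, duration))
    gain0 = np.zeros(duration)
    for mod, trace in visit.traces.items():
        w = problem.modality_weights.get(mod, 1.0)
        if w == 0:
            continue
        b = problem.bounds[mod]
        vals = np.where(trace.defined_mask, trace.values, np.inf)
        with np.errstate(invalid="ignore"):
            within = np.abs(vals[None, :] - vals[:, None]) <= b
        gain += w * within
        if visit.triage is not None and mod in visit.triage.recorded:
            tri = visit.triage.recorded[mod]
            gain0 += w * (np.abs(vals - tri) <= b)
    P = np.zeros((duration, duration + 1))
    np.cumsum(gain, axis=1, out=P[:, 1:])
    P0 = np.concatenate(([0.0], np.cumsum(gain0)))
    return P, P0


def optimal_placement(problem: PlacementProblem) -> PlacementSolution:
    """Exact coverage-maximal placement of at most K events, by dynamic programming.

    Among equal-objective solutions the lexicographically earliest minute
    sequence is returned (fewer events win ties, then earlier minutes).
    Runtime is O(K * duration^2) plus an O(duration^2 * modalities) table
    build.
    """
    visit = problem.visit
    duration = visit.duration_min
    K = int(problem.budget)
    P, P0 = _prefix_matrices(problem)
    no_event_objective = float(P0[duration])
    if K == 0 or duration == 0:
        events = realize_charting(visit, [])
        cov = coverage(visit, events, problem.bounds)
        return PlacementSolution([], cov.fractions, no_event_objective)

    # suf[l] = best score of minutes [l, duration) with an event at l and up
    # to j further events after it; built level by level for j = 0 .. K-1.
    idx = np.arange(duration)
    suf_levels = []
    suf = P[idx, duration] - P[idx, idx]  # j = 0: segment [l, D) vs ref l
    suf_levels.append(suf.copy())
    for _ in range(1, K):
        prev = suf_levels[-1]
        nxt = prev.copy()
        for l in range(duration - 1):
            cand = P[l, l + 1 : duration] - P[l, l] + prev[l + 1 :]
            best = cand.max()
            if best > nxt[l]:
                nxt[l] = best
        suf_levels.append(nxt)

    with_first = P0[:duration] + suf_levels[K - 1]
    best_obj = float(max(no_event_objective, with_first.max()))

    minutes: list[int] = []
    if no_event_objective < best_obj - _EPS:
        first = int(np.flatnonzero(with_first >= best_obj - _EPS)[0])
        minutes.append(first)
        l, j = first, K - 1
        while j > 0:
            target = suf_levels[j][l]
            if suf_levels[0][l] >= target - _EPS:
                break  # stopping here already attains the optimum
            cand = P[l, l + 1 : duration] - P[l, l] + suf_levels[j - 1][l + 1 :]
            m = int(l + 1 + np.flatnonzero(cand >= target - _EPS)[0])
            minutes.append(m)
            l, j = m, j - 1

    events = realize_charting(visit, minutes)
    cov = coverage(visit, events, problem.bounds)
    return PlacementSolution(minutes, cov.fractions, best_obj)


def optimal_objectives_by_budget(problem: PlacementProblem) -> list[float]:
    """Optimal objective for every budget 0..K (one DP sweep).

    Useful for dominance checks where each compared strategy uses a
    different number of events on the same visit.
    """
    visit = problem.visit
    duration = visit.duration_min
    K = int(problem.budget)
    P, P0 = _prefix_matrices(problem)
    out = [float(P0[duration])]
    if K == 0 or duration == 0:
        return out
    # once every defined minute is covered, larger budgets change nothing
    saturation = float(
        sum(
            problem.modality_weights.get(mod, 1.0) * trace.defined_mask.sum()
            for mod, trace in visit.traces.items()
        )
    )
    idx = np.arange(duration)
    suf = P[idx, duration] - P[idx, idx]
    out.append(float(max(out[0], (P0[:duration] + suf).max())))
    for _ in range(2, K + 1):
        if out[-1] >= saturation - _EPS:
            out.append(out[-1])
            continue
        nxt = suf.copy()
        for l in range(duration - 1):
            cand = P[l, l + 1 : duration] - P[l, l] + suf[l + 1 :]
            best = cand.max()
            if best > nxt[l]:
                nxt[l] = best
        suf = nxt
        out.append(float(max(out[-1], (P0[:duration] + suf).max())))
    return out


def placement_objective(problem: PlacementProblem, minutes: Sequence[int]) -> float:
    """Objective value of an arbitrary placement, via the segment decomposition."""
    visit = problem.visit
    duration = visit.duration_min
    ms = sorted(int(m) for m in minutes)
    if any(b <= a for a, b in zip(ms, ms[1:])):
        raise ValueError("event minutes must be distinct")
    if ms and (ms[0] < 0 or ms[-1] >= duration):
        raise ValueError("event minutes must lie in [0, duration)")
    P, P0 = _prefix_matrices(problem)
    if not ms:
        return float(P0[duration])
    total = float(P0[ms[0]])
    for a, b in zip(ms, ms[1:] + [duration]):
        total += float(P[a, b] - P[a, a])
    return total


def brute_force_placement(problem: PlacementProblem, cap: int = 10**6) -> PlacementSolution:
    """Exhaustive maximiser over all sets of at most K event minutes.

    Only intended for small instances (the number of candidate placements
    must stay below ``cap``); serves as the independent oracle for the DP.
    """
    visit = problem.visit
    duration = visit.duration_min
    K = int(problem.budget)
    n_configs = sum(math.comb(duration, j) for j in range(min(K, duration) + 1))
    if n_configs > cap:
        raise ValueError(f"{n_configs} placements exceed the enumeration cap {cap}")
    P, P0 = _prefix_matrices(problem)

    def objective(ms: tuple[int, ...]) -> float:
        if not ms:
            return float(P0[duration])
        total = float(P0[ms[0]])
        for i, a in enumerate(ms):
            b = ms[i + 1] if i + 1 < len(ms) else duration
            total += float(P[a, b] - P[a, a])
        return total

    best_obj = -np.inf
    best_ms: tuple[int, ...] = ()
    for j in range(min(K, duration) + 1):
        for ms in combinations(range(duration), j):
            obj = objective(ms)
            if obj > best_obj + _EPS or (
                obj > best_obj - _EPS and tuple(ms) < best_ms
            ):
                best_obj = obj
                best_ms = tuple(ms)
    events = realize_charting(visit, list(best_ms))
    cov = coverage(visit, events, problem.bounds)
    return PlacementSolution(list(best_ms), cov.fractions, float(best_obj))
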