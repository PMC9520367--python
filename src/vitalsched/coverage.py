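"""Coverage of monitored vital-sign trends by charted observations.

A monitored minute is *covered* when the monitor value lies within the
modality's symmetric bound of the most recently charted value of that
modality ("bounds carried forward until the next observation").  Coverage is
the covered fraction of defined monitor minutes over the visit.
*Informativeness* of a single charting event is the drop in coverage when
that event is removed — it may be negative, since removing an event changes
the reference for all downstream minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import COVERAGE_BOUNDS, ChartEvent, Visit


@dataclass
class CoverageResult:
    """Per-modality coverage fractions and covered-minute masks for one visit."""

    fractions: dict[str, float]
    covered_masks: dict[str, np.ndarray]
    n_defined: dict[str, int]
    n_events: int
    flags: list[str] = field(default_factory=list)

    def mean_fraction(self, modalities: Optional[Sequence[str]] = None) -> float:
        mods = list(modalities) if modalities is not None else list(self.fractions)
        return float(np.mean([self.fractions[m] for m in mods]))


def reference_series(
    visit: Visit,
    charting: Sequence[ChartEvent],
    modality: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Carried-forward charted reference for one modality.

    ``ref[m]`` is the value of the most recent event at minute <= m that
    recorded the modality; the triage observation (minute <= 0) seeds the
    reference before the first in-room event.  ``has_ref[m]`` is False before
    any reference exists.
    """
    duration = visit.duration_min
    ref = np.full(duration, np.nan)
    has_ref = np.zeros(duration, dtype=bool)
    events: list[ChartEvent] = []
    if visit.triage is not None and modality in visit.triage.recorded:
        events.append(visit.triage)
    events.extend(e for e in charting if modality in e.recorded)
    events.sort(key=lambda e: e.minute)
    for ev in events:
        start = max(ev.minute, 0)
        if start >= duration:
            continue
        ref[start:] = ev.recorded[modality]
        has_ref[start:] = True
    return ref, has_ref


def coverage(
    visit: Visit,
    charting: Sequence[ChartEvent],
    bounds: Optional[dict[str, float]] = None,
    include_leading_minutes: bool = True,
) -> CoverageResult:
    """Coverage of each monitored modality by a set of charting events.

    Comparison is inclusive (|monitor - reference| <= bound).  The
    denominator is the number of defined monitor minutes from rooming to
    departure; with ``include_leading_minutes=False`` minutes before the
    first reference are excluded from the denominator instead of counting as
    uncovered.
    """
    if bounds is None:
        bounds = COVERAGE_BOUNDS
    minutes = [e.minute for e in charting]
    if any(b <= a for a, b in zip(minutes, minutes[1:])):
        raise ValueError("charting events must be sorted and strictly increasing")
    flags = []
    if not charting and visit.triage is None:
        flags.append("no_reference")
    fractions: dict[str, float] = {}
    masks: dict[str, np.ndarray] = {}
    n_defined: dict[str, int] = {}
    for mod, trace in visit.traces.items():
        if mod not in bounds:
            raise ValueError(f"no coverage bound for modality {mod!r}")
        ref, has_ref = reference_series(visit, charting, mod)
        defined = trace.defined_mask.copy()
        with np.errstate(invalid="ignore"):
            within = np.abs(trace.values - ref) <= bounds[mod]
        covered = defined & has_ref & within
        denom_mask = defined if include_leading_minutes else (defined & has_ref)
        denom = int(denom_mask.sum())
        num = int((covered & denom_mask).sum())
        fractions[mod] = num / denom if denom else 0.0
        masks[mod] = covered
        n_defined[mod] = denom
    return CoverageResult(fractions, masks, n_defined, n_events=len(charting), flags=flags)


def informativeness(
    visit: Visit,
    charting: Sequence[ChartEvent],
    bounds: Optional[dict[str, float]] = None,
    event_index: int = 0,
    modality: str = "HR",
) -> float:
    """Coverage reduction for ``modality`` if one charting event is removed.

    Defined as coverage(with the event) - coverage(without it); can be
    negative because the removed event's reference also shaped downstream
    minutes.  No clamping is applied.
    """
    if not 0 <= event_index < len(charting):
        raise IndexError("event_index out of range")
    full = coverage(visit, charting, bounds)
    reduced_events = [e for i, e in enumerate(charting) if i != event_index]
    reduced = coverage(visit, reduced_events, bounds)
    return full.fractions[modality] - reduced.fractions[modality]


def per_event_informativeness(
    visit: Visit,
    charting: Sequence[ChartEvent],
    bounds: Optional[dict[str, float]] = None,
) -> dict[tuple[int, str], float]:
    """Informativeness of every (event, modality) pair for one visit."""
    out = {}
    for i, ev in enumerate(charting):
        for mod in visit.traces:
            if mod in ev.recorded:
                out[(i, mod)] = informativeness(visit, charting, bounds, i, mod)
    return out
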