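"""Detection and charting capture of vital-sign abnormalities.

An abnormality *event* is a threshold crossing (tachycardia HR > 100,
bradycardia HR < 60, hypotension MAP < 65, hypoxia SpO2 < 95; all strict)
that arises after the first 5 minutes of monitoring of that modality — at
most one event per type per visit, anchored at its first qualifying minute.
An event is *captured* when a later charting entry records a value of the
same modality meeting the same threshold; the capture lag is the minutes
from monitor onset to that first capturing chart entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    ABNORMALITY_THRESHOLDS,
    ABNORMALITY_TYPES,
    ChartEvent,
    Visit,
    threshold_crossed,
)

#: Number of initial monitored minutes during which an abnormality counts as
#: "present at baseline" rather than as a new event.
WARM_IN_MINUTES = 5


@dataclass
class AbnormalityEvent:
    """One new abnormality on the monitor, and whether charting captured it."""

    visit_id: str
    abnormality_type: str
    onset_minute: int
    captured: bool = False
    lag_minutes: Optional[int] = None


def detect_events(
    visit: Visit,
    thresholds: Optional[dict[str, tuple[str, str, float]]] = None,
) -> list[AbnormalityEvent]:
    """Find new abnormality events on the visit's monitor traces.

    For each abnormality type there is at most one event: it exists iff the
    threshold is not met during the first 5 defined minutes of the modality's
    trace (the warm-in window, counted from monitoring initiation) but is met
    at some later defined minute; the onset is the first such minute.
    Modalities with no defined minutes are not evaluable.
    """
    if thresholds is None:
        thresholds = ABNORMALITY_THRESHOLDS
    events = []
    for abn, (mod, direction, thr) in thresholds.items():
        trace = visit.traces.get(mod)
        if trace is None or not trace.defined_mask.any():
            continue
        defined_minutes = np.flatnonzero(trace.defined_mask)
        abnormal = threshold_crossed(trace.values[defined_minutes], abn)
        warm_in = abnormal[:WARM_IN_MINUTES]
        if warm_in.any():
            continue  # present at baseline, not a new event
        later = np.flatnonzero(abnormal[WARM_IN_MINUTES:])
        if later.size == 0:
            continue
        onset = int(defined_minutes[WARM_IN_MINUTES + later[0]])
        events.append(AbnormalityEvent(visit.visit_id, abn, onset))
    return events


def capture(
    events: Sequence[AbnormalityEvent],
    charting: Sequence[ChartEvent],
    thresholds: Optional[dict[str, tuple[str, str, float]]] = None,
    horizon_minutes: Optional[int] = None,
) -> list[AbnormalityEvent]:
    """Mark each event captured if charting subsequently notes the abnormality.

    A charting event at minute >= onset captures the event when its recorded
    value for the relevant modality meets the same strict threshold; the lag
    is minutes from onset to the first such entry.  ``horizon_minutes``
    optionally limits how late a capture may occur (no limit by default).
    """
    if thresholds is None:
        thresholds = ABNORMALITY_THRESHOLDS
    minutes = [e.minute for e in charting]
    if any(b <= a for a, b in zip(minutes, minutes[1:])):
        raise ValueError("charting events must be sorted and strictly increasing")
    out = []
    for ev in events:
        mod, _, _ = thresholds[ev.abnormality_type]
        captured = False
        lag: Optional[int] = None
        for ce in charting:
            if ce.minute < ev.onset_minute or mod not in ce.recorded:
                continue
            if horizon_minutes is not None and ce.minute - ev.onset_minute > horizon_minutes:
                break
            if threshold_crossed(np.array([ce.recorded[mod]]), ev.abnormality_type)[0]:
                captured = True
                lag = ce.minute - ev.onset_minute
                break
        out.append(
            AbnormalityEvent(ev.visit_id, ev.abnormality_type, ev.onset_minute, captured, lag)
        )
    return out


def events_table(events: Sequence[AbnormalityEvent], strategy: str = "") -> pd.DataFrame:
    rows = [
        (e.visit_id, e.abnormality_type, e.onset_minute, e.captured, e.lag_minutes, strategy)
        for e in events
    ]
    df = pd.DataFrame(
        rows, columns=["visit_id", "type", "onset", "captured", "lag", "strategy"]
    )
    df["lag"] = df["lag"].astype(float)
    df["captured"] = df["captured"].astype(bool)
    return df


def cohort_capture_summary(
    cohort: Sequence[Visit],
    charting_by_visit: dict[str, Sequence[ChartEvent]],
    thresholds: Optional[dict[str, tuple[str, str, float]]] = None,
) -> pd.DataFrame:
    """Per-abnormality capture summary over a cohort for one charting scheme.

    Proportions are over evaluable events; median and IQR of the lag are over
    captured events only (emitted as NaN when there are none).
    """
    if not len(cohort):
        raise ValueError("cohort must be nonempty")
    all_events: list[AbnormalityEvent] = []
    for visit in cohort:
        evs = detect_events(visit, thresholds)
        charted = capture(evs, charting_by_visit.get(visit.visit_id, []), thresholds)
        all_events.extend(charted)
    return summarize_events(all_events)


def summarize_events(events: Sequence[AbnormalityEvent]) -> pd.DataFrame:
    """Aggregate a flat event list into the per-type capture summary."""
    rows = []
    for abn in ABNORMALITY_TYPES:
        evs = [e for e in events if e.abnormality_type == abn]
        n = len(evs)
        captured = [e for e in evs if e.captured]
        n_cap = len(captured)
        lags = np.array([e.lag_minutes for e in captured], dtype=float)
        rows.append(
            (
                abn,
                n,
                n_cap,
                (n_cap / n) if n else np.nan,
                float(np.median(lags)) if n_cap else np.nan,
                float(np.percentile(lags, 25)) if n_cap else np.nan,
                float(np.percentile(lags, 75)) if n_cap else np.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["type", "n_events", "n_captured", "proportion", "median_lag", "lag_q1", "lag_q3"],
    )
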