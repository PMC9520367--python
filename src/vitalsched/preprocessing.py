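"""Alignment of raw monitor samples and charted observations to 1-minute bins.

Time origin is the rooming minute; per-minute bins are half-open intervals
[m, m+1) in minutes from rooming.  Missing minutes are filled by carrying the
last observation forward (LOCF); minutes before the first defined value stay
undefined.  Blood pressure is summarised as mean arterial pressure,
MAP = (1/3) SBP + (2/3) DBP.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import MODALITIES, ChartEvent, VitalTrace, Visit

logger = logging.getLogger(__name__)

ArrayLike = Union[float, Sequence[float], np.ndarray]


def minute_means(
    raw_samples: Iterable[tuple[float, float]],
    modality: str,
    duration_min: Optional[int] = None,
) -> VitalTrace:
    """Bin raw (timestamp, value) samples into 1-minute means.

    Timestamps are minutes from rooming (fractions allowed); sample ``(t, v)``
    lands in bin ``floor(t)``.  Minutes with no samples are left undefined
    (to be filled downstream by :func:`carry_forward`).  Non-finite sample
    values are dropped and counted.
    """
    samples = [(float(t), float(v)) for t, v in raw_samples]
    n_bad = sum(1 for _, v in samples if not np.isfinite(v))
    if n_bad:
        logger.warning("minute_means: dropped %d non-finite %s samples", n_bad, modality)
        samples = [(t, v) for t, v in samples if np.isfinite(v)]
    if samples and min(t for t, _ in samples) < 0:
        raise ValueError("sample timestamps must be within the visit (minute >= 0)")
    if duration_min is None:
        duration_min = int(max(t for t, _ in samples)) + 1 if samples else 0
    if duration_min < 1:
        raise ValueError("duration must be at least 1 minute")
    sums = np.zeros(duration_min)
    counts = np.zeros(duration_min)
    for t, v in samples:
        m = int(np.floor(t))
        if m >= duration_min:
            raise ValueError("sample timestamp beyond the visit duration")
        sums[m] += v
        counts[m] += 1
    mask = counts > 0
    values = np.full(duration_min, np.nan)
    values[mask] = sums[mask] / counts[mask]
    return VitalTrace(modality, values, mask)


def carry_forward(trace: VitalTrace) -> VitalTrace:
    """Fill undefined minutes with the last observation carried forward.

    Minutes before the first defined value remain undefined.  Idempotent and
    never alters a defined minute.  An all-undefined trace is returned
    unchanged (with a warning).
    """
    mask = trace.defined_mask
    if not mask.any():
        logger.warning("carry_forward: %s trace has no defined minutes", trace.modality)
        return VitalTrace(trace.modality, trace.values.copy(), mask.copy(), trace.n_clipped)
    idx = np.where(mask, np.arange(trace.duration), -1)
    np.maximum.accumulate(idx, out=idx)
    values = np.full(trace.duration, np.nan)
    filled = idx >= 0
    values[filled] = trace.values[idx[filled]]
    return VitalTrace(trace.modality, values, filled, trace.n_clipped)


def mean_arterial_pressure(sbp: ArrayLike, dbp: ArrayLike) -> Union[float, np.ndarray]:
    """MAP = (1/3) SBP + (2/3) DBP, elementwise; requires SBP >= DBP > 0."""
    sbp_arr = np.asarray(sbp, dtype=float)
    dbp_arr = np.asarray(dbp, dtype=float)
    if np.any(dbp_arr <= 0):
        raise ValueError("diastolic pressure must be positive")
    if np.any(sbp_arr < dbp_arr):
        raise ValueError("systolic pressure must be >= diastolic pressure")
    out = sbp_arr / 3.0 + 2.0 * dbp_arr / 3.0
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Long-format CSV interchange
# ---------------------------------------------------------------------------

LONG_COLUMNS = ["visit_id", "minute", "modality", "value", "source"]
VISIT_COLUMNS = ["visit_id", "esi", "duration_min", "disposition"]


def cohort_to_long(cohort: Sequence[Visit]) -> pd.DataFrame:
    """Flatten a cohort into long format: one row per (visit, minute, modality)."""
    rows = []
    for visit in cohort:
        for mod, trace in visit.traces.items():
            for m in np.flatnonzero(trace.defined_mask):
                rows.append((visit.visit_id, int(m), mod, float(trace.values[m]), "monitor"))
        if visit.triage is not None:
            for mod, v in visit.triage.recorded.items():
                rows.append((visit.visit_id, visit.triage.minute, mod, v, "triage"))
        for ev in visit.actual_charting:
            for mod, v in ev.recorded.items():
                rows.append((visit.visit_id, ev.minute, mod, v, "chart"))
    return pd.DataFrame(rows, columns=LONG_COLUMNS)


def cohort_to_visit_table(cohort: Sequence[Visit]) -> pd.DataFrame:
    rows = [(v.visit_id, v.esi, v.duration_min, "") for v in cohort]
    return pd.DataFrame(rows, columns=VISIT_COLUMNS)


def write_cohort_csv(cohort: Sequence[Visit], long_path, visits_path) -> None:
    cohort_to_long(cohort).to_csv(long_path, index=False)
    cohort_to_visit_table(cohort).to_csv(visits_path, index=False)


def _events_from_rows(rows: pd.DataFrame) -> list[ChartEvent]:
    events = []
    for minute, grp in rows.groupby("minute", sort=True):
        recorded = {str(r.modality): float(r.value) for r in grp.itertuples()}
        events.append(ChartEvent(minute=int(minute), recorded=recorded))
    return events


def read_cohort_csv(long_path, visits_path) -> list[Visit]:
    """Reconstruct a cohort from the long-format CSV pair.

    Monitor rows define the per-minute traces (absent minutes are undefined);
    chart rows are grouped by minute into charting events; triage rows (one
    per modality) form the triage observation.
    """
    long_df = pd.read_csv(long_path)
    visits_df = pd.read_csv(visits_path)
    missing = set(LONG_COLUMNS) - set(long_df.columns)
    if missing:
        raise ValueError(f"long CSV missing columns: {sorted(missing)}")
    cohort = []
    by_visit = dict(tuple(long_df.groupby("visit_id", sort=False)))
    for rec in visits_df.itertuples():
        vid = rec.visit_id
        duration = int(rec.duration_min)
        rows = by_visit.get(vid, pd.DataFrame(columns=LONG_COLUMNS))
        traces = {}
        monitor = rows[rows["source"] == "monitor"]
        for mod in MODALITIES:
            sub = monitor[monitor["modality"] == mod]
            values = np.full(duration, np.nan)
            mask = np.zeros(duration, dtype=bool)
            for r in sub.itertuples():
                m = int(r.minute)
                if not 0 <= m < duration:
                    raise ValueError(f"visit {vid}: monitor minute {m} out of range")
                values[m] = float(r.value)
                mask[m] = True
            if mask.any():
                traces[mod] = VitalTrace(mod, values, mask)
        triage_rows = rows[rows["source"] == "triage"]
        triage = None
        if len(triage_rows):
            minute = int(triage_rows["minute"].iloc[0])
            triage = ChartEvent(
                minute=minute,
                recorded={
                    str(r.modality): float(r.value) for r in triage_rows.itertuples()
                },
            )
        chart_rows = rows[rows["source"] == "chart"]
        charting = _events_from_rows(chart_rows) if len(chart_rows) else []
        cohort.append(
            Visit(
                visit_id=str(vid),
                esi=int(rec.esi),
                duration_min=duration,
                traces=traces,
                triage=triage,
                actual_charting=charting,
            )
        )
    return cohort


def minute_matrix(cohort: Sequence[Visit]) -> pd.DataFrame:
    """Aligned per-minute matrix: one row per visit-minute, modality columns."""
    frames = []
    for visit in cohort:
        data = {"visit_id": visit.visit_id, "minute": np.arange(visit.duration_min)}
        for mod in MODALITIES:
            trace = visit.traces.get(mod)
            if trace is None:
                data[mod] = np.full(visit.duration_min, np.nan)
            else:
                col = np.where(trace.defined_mask, trace.values, np.nan)
                data[mod] = col
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["visit_id", "minute", *MODALITIES]
    )
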