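"""Core domain types and clinical constants.

The package analyses monitored emergency-department (ED) visits at 1-minute
resolution.  A visit carries one :class:`VitalTrace` per modality (heart rate,
respiratory rate, pulse-oximetry saturation, mean arterial pressure), an
optional triage observation, and the list of nurse charting events actually
recorded during the visit.  Minute 0 is the rooming time; triage observations
may carry a negative minute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

# ---------------------------------------------------------------------------
# Modalities and clinical constants
# ---------------------------------------------------------------------------

HR = "HR"
RR = "RR"
SPO2 = "SPO2"
MAP = "MAP"

MODALITIES: tuple[str, ...] = (HR, MAP, RR, SPO2)

#: Symmetric coverage half-widths per modality (units of the modality).
#: A monitored minute is "covered" when it lies within the half-width of the
#: most recently charted value of the same modality.
COVERAGE_BOUNDS: dict[str, float] = {HR: 5.0, RR: 3.0, SPO2: 2.0, MAP: 6.0}

#: Physiologic guard rails used to clip simulated traces, (low, high).
GUARD_RAILS: dict[str, tuple[float, float]] = {
    HR: (20.0, 250.0),
    RR: (2.0, 60.0),
    SPO2: (50.0, 100.0),
    MAP: (20.0, 200.0),
}

TACHYCARDIA = "tachycardia"
BRADYCARDIA = "bradycardia"
HYPOTENSION = "hypotension"
HYPOXIA = "hypoxia"

ABNORMALITY_TYPES: tuple[str, ...] = (TACHYCARDIA, BRADYCARDIA, HYPOTENSION, HYPOXIA)

#: Abnormality definitions: modality, direction ('above'/'below') and the
#: strict threshold.  Tachycardia is HR > 100/min; bradycardia HR < 60/min;
#: hypotension MAP < 65 mm Hg; hypoxia SpO2 < 95%.  All strict inequalities.
ABNORMALITY_THRESHOLDS: dict[str, tuple[str, str, float]] = {
    TACHYCARDIA: (HR, "above", 100.0),
    BRADYCARDIA: (HR, "below", 60.0),
    HYPOTENSION: (MAP, "below", 65.0),
    HYPOXIA: (SPO2, "below", 95.0),
}


def threshold_crossed(values: np.ndarray, abnormality: str) -> np.ndarray:
    """Boolean mask of minutes where ``values`` meet the abnormality threshold."""
    _, direction, thr = ABNORMALITY_THRESHOLDS[abnormality]
    values = np.asarray(values, dtype=float)
    if direction == "above":
        return values > thr
    return values < thr


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class VitalTrace:
    """One modality's per-minute series over a visit.

    ``values[m]`` is the 1-minute mean at minute ``m`` (from rooming);
    ``defined_mask[m]`` is False where the monitor produced no value (e.g.
    before the first blood-pressure cuff reading).  Values at undefined
    minutes are NaN.
    """

    modality: str
    values: np.ndarray
    defined_mask: np.ndarray
    n_clipped: int = 0  # minutes clipped to physiologic guard rails (synthetic)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.defined_mask = np.asarray(self.defined_mask, dtype=bool)
        if self.values.shape != self.defined_mask.shape:
            raise ValueError("values and defined_mask must have equal length")
        if not np.all(np.isfinite(self.values[self.defined_mask])):
            raise ValueError("defined minutes must hold finite values")

    @property
    def duration(self) -> int:
        return int(self.values.shape[0])

    def value_at(self, minute: int) -> Optional[float]:
        """Value at ``minute`` or None if out of range / undefined."""
        if minute < 0 or minute >= self.duration or not self.defined_mask[minute]:
            return None
        return float(self.values[minute])


@dataclass
class ChartEvent:
    """A timestamped observation recording one value per available modality.

    ``minute`` is the offset from rooming and may be negative for triage
    observations.  ``recorded`` maps modality name to the charted value; a
    subset of modalities is allowed but at least one must be present.
    """

    minute: int
    recorded: dict[str, float]

    def __post_init__(self) -> None:
        if not self.recorded:
            raise ValueError("a charting event must record at least one modality")


@dataclass
class EpisodeSpec:
    """An injected abnormality episode for the synthetic generator.

    The episode shifts the affected modality's process mean by ``magnitude``
    (signed, units of the modality) over ``[onset, onset + duration)``, with
    ``ramp``-minute linear on/off ramps inside the episode so onsets are
    gradual rather than instantaneous.
    """

    abnormality_type: str
    onset: int
    duration: int
    magnitude: float
    ramp: int = 3

    def __post_init__(self) -> None:
        if self.abnormality_type not in ABNORMALITY_THRESHOLDS:
            raise ValueError(f"unknown abnormality type {self.abnormality_type!r}")
        if self.onset < 6:
            raise ValueError("episode onset must be at minute 6 or later")
        if self.duration < 1:
            raise ValueError("episode duration must be at least 1 minute")
        if self.ramp < 0:
            raise ValueError("ramp must be nonnegative")

    @property
    def modality(self) -> str:
        return ABNORMALITY_THRESHOLDS[self.abnormality_type][0]

    @property
    def end(self) -> int:
        return self.onset + self.duration


@dataclass
class Visit:
    """A monitored ED visit: traces, triage vitals and actual nurse charting."""

    visit_id: str
    esi: int
    duration_min: int
    traces: dict[str, VitalTrace]
    triage: Optional[ChartEvent] = None
    actual_charting: list[ChartEvent] = field(default_factory=list)
    injected_episodes: list[EpisodeSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= self.esi <= 5:
            raise ValueError("ESI must be between 1 and 5")
        for trace in self.traces.values():
            if trace.duration != self.duration_min:
                raise ValueError("all traces must share the visit duration")
        minutes = [e.minute for e in self.actual_charting]
        if any(b <= a for a, b in zip(minutes, minutes[1:])):
            raise ValueError("charting events must be strictly increasing in minute")
        if any(e.minute >= self.duration_min for e in self.actual_charting):
            raise ValueError("charting events must fall before departure")
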