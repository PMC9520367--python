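import numpy as np
import pytest

from vitalsched.types import HR, MAP, RR, SPO2, ChartEvent, VitalTrace, Visit


def make_trace(modality, values, mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isfinite(values)
    return VitalTrace(modality, values, np.asarray(mask, dtype=bool))


def make_visit(
    traces,
    visit_id="T0",
    esi=3,
    triage=None,
    charting=(),
    duration=None,
):
    """Build a visit from {modality: values} with NaN marking undefined minutes."""
    built = {mod: make_trace(mod, vals) for mod, vals in traces.items()}
    if duration is None:
        duration = next(iter(built.values())).duration
    return Visit(
        visit_id=visit_id,
        esi=esi,
        duration_min=duration,
        traces=built,
        triage=triage,
        actual_charting=list(charting),
    )


def random_visit(rng, duration=None, modalities=(HR, MAP, RR, SPO2), undefined_frac=0.0):
    """A random multi-modality visit for property and oracle tests."""
    if duration is None:
        duration = int(rng.integers(5, 60))
    baselines = {HR: (80, 6), MAP: (85, 6), RR: (16, 2), SPO2: (97, 1)}
    traces = {}
    for mod in modalities:
        mean, sd = baselines[mod]
        vals = mean + sd * rng.standard_normal(duration)
        if undefined_frac > 0:
            vals = np.where(rng.random(duration) < undefined_frac, np.nan, vals)
        traces[mod] = vals
    triage = None
    if rng.random() < 0.5:
        rec = {}
        for mod in modalities:
            v = traces[mod][0]
            if np.isfinite(v):
                rec[mod] = float(v + rng.normal(0, 2))
        if rec:
            triage = ChartEvent(minute=-3, recorded=rec)
    return make_visit(traces, triage=triage)


def random_charting(rng, visit, max_events=6):
    """Random strictly increasing charting events recording monitor values."""
    k = int(rng.integers(0, max_events + 1))
    minutes = sorted(rng.choice(visit.duration_min, size=min(k, visit.duration_min), replace=False))
    events = []
    for m in minutes:
        rec = {}
        for mod, trace in visit.traces.items():
            if trace.defined_mask[m] and rng.random() < 0.9:
                rec[mod] = float(trace.values[m] + rng.normal(0, 3))
        if rec:
            events.append(ChartEvent(minute=int(m), recorded=rec))
    return events


@pytest.fixture(scope="session")
def small_cohort():
    from vitalsched.synthetic import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n_visits=30, seed=123))
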