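"""Synthetic cohorts of monitored ED visits.

The study population this generator emulates is a continuously monitored
emergency-department cohort: 1-minute heart-rate, respiratory-rate and
pulse-oximetry traces, intermittent cuff-derived mean arterial pressure
carried forward between measurements, a triage observation before rooming,
hourly-ish nurse charting, and episodic vital-sign abnormalities
(tachycardia, bradycardia, hypotension, hypoxia).

Each modality follows a discrete-time mean-reverting (AR(1)) process around
a configurable baseline; abnormality episodes shift the process mean
additively with short linear on/off ramps so that onsets are gradual.
SpO2 is simulated on a logit-like bounded scale and clipped at 100% to
reproduce its ceiling effect.  All randomness flows through numpy
Generators seeded from a single cohort seed, so cohorts are exactly
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import expit, logit

from .types import (
    ABNORMALITY_THRESHOLDS,
    ABNORMALITY_TYPES,
    BRADYCARDIA,
    COVERAGE_BOUNDS,
    GUARD_RAILS,
    HR,
    HYPOTENSION,
    HYPOXIA,
    MAP,
    MODALITIES,
    RR,
    SPO2,
    TACHYCARDIA,
    ChartEvent,
    EpisodeSpec,
    VitalTrace,
    Visit,
    threshold_crossed,
)

RngLike = Union[int, np.random.Generator]


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class BaselineParams:
    """Stationary AR(1) parameters for one modality.

    ``mean`` and ``sd`` are the stationary mean and SD in the modality's
    units; ``reversion`` is the per-minute pull toward the mean (AR
    coefficient ``phi = 1 - reversion``).
    """

    mean: float
    sd: float
    reversion: float = 0.1

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if not 0 < self.reversion <= 1:
            raise ValueError("reversion must be in (0, 1]")


@dataclass
class NursePolicy:
    """Stylised nurse charting behaviour.

    Scheduled charting at jittered multiples of ``cadence_min``; with
    probability ``reactive_prob`` an extra charting event follows the minute
    after an abnormality first appears on the monitor.
    """

    cadence_min: float = 100.0
    jitter_sd: float = 15.0
    reactive_prob: float = 0.25

    def __post_init__(self) -> None:
        if self.cadence_min < 1:
            raise ValueError("cadence must be at least 1 minute")
        if self.jitter_sd < 0:
            raise ValueError("jitter SD must be nonnegative")
        if not 0 <= self.reactive_prob <= 1:
            raise ValueError("reactive probability must be in [0, 1]")


def _default_baselines() -> dict[str, BaselineParams]:
    # Means sit >= 3 stationary SDs from the abnormality thresholds so that
    # threshold crossings are driven by injected episodes, not baseline noise.
    return {
        HR: BaselineParams(mean=80.0, sd=5.5, reversion=0.05),
        RR: BaselineParams(mean=16.0, sd=2.2, reversion=0.05),
        SPO2: BaselineParams(mean=97.5, sd=0.6, reversion=0.05),
        MAP: BaselineParams(mean=85.0, sd=6.0, reversion=0.03),
    }


def _default_prevalence() -> dict[str, float]:
    # Per-visit probability of injecting each abnormality episode.
    return {TACHYCARDIA: 0.151, BRADYCARDIA: 0.124, HYPOTENSION: 0.055, HYPOXIA: 0.402}


@dataclass
class CohortConfig:
    """Full description of a synthetic cohort.

    Visit durations are lognormal with the given median (minutes) and
    log-scale SD; the defaults give a median of 324 minutes with quartiles
    near 236/445 minutes.  ``esi_probs`` is the case mix over ESI 1-4
    (most- to least-urgent levels seen in monitored beds).
    """

    n_visits: int = 500
    seed: int = 0
    duration_median: float = 324.0
    duration_log_sd: float = 0.47
    min_duration: int = 20
    esi_probs: tuple[float, float, float, float] = (0.020, 0.353, 0.615, 0.012)
    episode_prevalence: dict[str, float] = field(default_factory=_default_prevalence)
    baseline_params: dict[str, BaselineParams] = field(default_factory=_default_baselines)
    cuff_interval: int = 30
    nurse_policy: NursePolicy = field(default_factory=NursePolicy)

    def __post_init__(self) -> None:
        if self.n_visits < 0:
            raise ValueError("n_visits must be nonnegative")
        if abs(sum(self.esi_probs) - 1.0) > 1e-9:
            raise ValueError("esi_probs must sum to 1")
        if any(p < 0 or p > 1 for p in self.esi_probs):
            raise ValueError("esi_probs must lie in [0, 1]")
        for t, p in self.episode_prevalence.items():
            if t not in ABNORMALITY_THRESHOLDS:
                raise ValueError(f"unknown abnormality type {t!r}")
            if not 0 <= p <= 1:
                raise ValueError("episode prevalence must lie in [0, 1]")
        if self.duration_median <= 0 or self.duration_log_sd < 0:
            raise ValueError("duration parameters must be positive")
        if self.cuff_interval < 1:
            raise ValueError("cuff_interval must be at least 1 minute")


# ---------------------------------------------------------------------------
# Trace simulation
# ---------------------------------------------------------------------------


def _episode_shift(duration: int, episodes: Sequence[EpisodeSpec]) -> np.ndarray:
    """Additive mean-shift profile over the visit.

    Within an episode the shift ramps linearly up over the first ``ramp``
    minutes and down over the last ``ramp`` minutes, holding the full
    magnitude on the plateau in between; outside the episode it is zero.
    """
    shift = np.zeros(duration)
    for ep in episodes:
        n = ep.duration
        r = min(ep.ramp, max((n - 1) // 2, 0))
        i = np.arange(n, dtype=float)
        frac = np.minimum(1.0, np.minimum((i + 1) / (r + 1), (n - i) / (r + 1)))
        shift[ep.onset : ep.end] += ep.magnitude * frac
    return shift


def _check_episodes(modality: str, duration: int, episodes: Sequence[EpisodeSpec]) -> None:
    for ep in episodes:
        if ep.modality != modality:
            raise ValueError(
                f"episode {ep.abnormality_type!r} affects {ep.modality}, not {modality}"
            )
        if ep.end > duration:
            raise ValueError("episode extends beyond the visit")
    spans = sorted((ep.onset, ep.end) for ep in episodes)
    for (_, e1), (s2, _) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping {modality} episodes")


def _ar1(duration: int, mean: float, sd: float, reversion: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series: x_{t+1} = mean + phi (x_t - mean) + eps."""
    phi = 1.0 - reversion
    x = np.empty(duration)
    x[0] = mean + sd * rng.standard_normal()
    if duration > 1:
        innov_sd = sd * math.sqrt(max(1.0 - phi * phi, 0.0))
        eps = innov_sd * rng.standard_normal(duration - 1)
        for t in range(1, duration):
            x[t] = mean + phi * (x[t - 1] - mean) + eps[t - 1]
    return x


def _spo2_latent_params(params: BaselineParams) -> tuple[float, float]:
    """Map SpO2 mean/SD (percent) onto the latent logit scale.

    SpO2 lives on (50, 100]; the latent variable is logit((x - 50) / 50) and
    the latent SD is matched to the raw-scale SD by the delta method.
    """
    p = np.clip((params.mean - 50.0) / 50.0, 1e-6, 1 - 1e-6)
    lmean = float(logit(p))
    deriv = 50.0 * p * (1.0 - p)  # d(raw)/d(latent) at the mean
    lsd = params.sd / deriv
    return lmean, lsd


def _spo2_from_latent(latent: np.ndarray) -> np.ndarray:
    return 50.0 + 50.0 * expit(latent)


def _simulate_process(
    modality: str,
    duration: int,
    params: BaselineParams,
    episodes: Sequence[EpisodeSpec],
    rng: np.random.Generator,
) -> np.ndarray:
    """Continuous per-minute process for one modality, before any sampling."""
    shift = _episode_shift(duration, episodes)
    if modality == SPO2:
        lmean, lsd = _spo2_latent_params(params)
        latent = _ar1(duration, lmean, lsd, params.reversion, rng)
        # translate the raw-scale mean shift into a latent shift
        target_raw = np.clip(params.mean + shift, 50.0 + 1e-6, 100.0 - 1e-6)
        latent_shift = logit((target_raw - 50.0) / 50.0) - lmean
        values = _spo2_from_latent(latent + latent_shift)
    else:
        values = _ar1(duration, params.mean, params.sd, params.reversion, rng) + shift
    return values


def _clip_and_enforce(
    modality: str,
    values: np.ndarray,
    params: BaselineParams,
    episodes: Sequence[EpisodeSpec],
) -> tuple[np.ndarray, int]:
    """Clip to guard rails and force each episode to cross its threshold.

    Noise can occasionally revert an episode back across its threshold for
    the whole window; in that case the plateau midpoint is pinned at the
    shifted mean so every injected episode is detectable on the monitor.
    """
    low, high = GUARD_RAILS[modality]
    clipped = np.clip(values, low, high)
    n_clipped = int(np.sum((values < low) | (values > high)))
    for ep in episodes:
        window = clipped[ep.onset : ep.end]
        if not threshold_crossed(window, ep.abnormality_type).any():
            mid = ep.onset + ep.duration // 2
            clipped[mid] = float(np.clip(params.mean + ep.magnitude, low, high))
    return clipped, n_clipped


def generate_trace(
    modality: str,
    duration_minutes: int,
    baseline_params: BaselineParams,
    episodes: Sequence[EpisodeSpec] = (),
    seed: RngLike = 0,
) -> VitalTrace:
    """Simulate a continuously monitored modality at 1-minute resolution.

    Returns a fully defined trace: a stationary mean-reverting process around
    the configured baseline, plus additive episode shifts, clipped to
    physiologic guard rails.  Deterministic given the seed.
    """
    if duration_minutes < 1:
        raise ValueError("duration must be at least 1 minute")
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    _check_episodes(modality, duration_minutes, episodes)
    rng = _as_rng(seed)
    values = _simulate_process(modality, duration_minutes, baseline_params, episodes, rng)
    values, n_clipped = _clip_and_enforce(modality, values, baseline_params, episodes)
    mask = np.ones(duration_minutes, dtype=bool)
    return VitalTrace(modality, values, mask, n_clipped=n_clipped)


def generate_map_trace(
    duration_minutes: int,
    baseline_params: BaselineParams,
    episodes: Sequence[EpisodeSpec] = (),
    cuff_interval: int = 30,
    seed: RngLike = 0,
    return_underlying: bool = False,
):
    """Simulate intermittent cuff-derived MAP.

    The underlying arterial-pressure process runs continuously (episodes act
    on it), but the monitor only reports it at cuff minutes 0, c, 2c, ...;
    between cuff readings the last measurement is carried forward.  Short
    hypotensive dips can therefore be invisible on the recorded trace, as
    with real sphygmomanometry.
    """
    if duration_minutes < 1:
        raise ValueError("duration must be at least 1 minute")
    if cuff_interval < 1:
        raise ValueError("cuff_interval must be at least 1 minute")
    _check_episodes(MAP, duration_minutes, episodes)
    rng = _as_rng(seed)
    underlying = _simulate_process(MAP, duration_minutes, baseline_params, episodes, rng)
    underlying, n_clipped = _clip_and_enforce(MAP, underlying, baseline_params, episodes)
    cuff_minutes = np.arange(0, duration_minutes, cuff_interval)
    values = np.full(duration_minutes, np.nan)
    for i, m in enumerate(cuff_minutes):
        end = cuff_minutes[i + 1] if i + 1 < len(cuff_minutes) else duration_minutes
        values[m:end] = underlying[m]
    mask = ~np.isnan(values)
    trace = VitalTrace(MAP, values, mask, n_clipped=n_clipped)
    if return_underlying:
        return trace, underlying
    return trace


# ---------------------------------------------------------------------------
# Nurse charting
# ---------------------------------------------------------------------------


def _record_at(visit: Visit, minute: int) -> Optional[ChartEvent]:
    """Chart the monitor values at ``minute`` for every defined modality."""
    recorded = {}
    for mod in MODALITIES:
        trace = visit.traces.get(mod)
        if trace is None:
            continue
        v = trace.value_at(minute)
        if v is not None:
            recorded[mod] = v
    if not recorded:
        return None
    return ChartEvent(minute=minute, recorded=recorded)


def _abnormality_onset_minutes(visit: Visit) -> list[int]:
    """Minutes at which any abnormality first appears (rising edges)."""
    onsets: set[int] = set()
    for abn, (mod, _, _) in ABNORMALITY_THRESHOLDS.items():
        trace = visit.traces.get(mod)
        if trace is None:
            continue
        mask = threshold_crossed(trace.values, abn) & trace.defined_mask
        edges = np.flatnonzero(mask & ~np.concatenate(([False], mask[:-1])))
        onsets.update(int(m) for m in edges)
    return sorted(onsets)


def simulate_nurse_charting(
    visit: Visit, nurse_policy: NursePolicy, seed: RngLike = 0
) -> list[ChartEvent]:
    """Simulate actual nurse charting for a visit.

    Scheduled events fall at jittered multiples of the target cadence within
    [0, duration); with probability ``reactive_prob`` an extra event is
    charted the minute after any abnormality first crosses its threshold on
    the monitor.  Events record the monitor value for every defined modality.
    """
    rng = _as_rng(seed)
    duration = visit.duration_min
    cadence = nurse_policy.cadence_min
    times: set[int] = set()
    k = 0
    while k * cadence < duration + 5.0 * nurse_policy.jitter_sd:
        t = int(round(k * cadence + rng.normal(0.0, nurse_policy.jitter_sd)))
        t = max(t, 0)  # the rooming observation cannot precede rooming
        if t < duration:
            times.add(t)
        k += 1
    if nurse_policy.reactive_prob > 0:
        for onset in _abnormality_onset_minutes(visit):
            if rng.random() < nurse_policy.reactive_prob and onset + 1 < duration:
                times.add(onset + 1)
    events = []
    for t in sorted(times):
        ev = _record_at(visit, t)
        if ev is not None:
            events.append(ev)
    return events


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

_EPISODE_DURATION_RANGE = (15, 90)  # minutes, inclusive


def _draw_magnitude(abn: str, baselines: dict[str, BaselineParams], rng: np.random.Generator) -> float:
    """Episode magnitude: enough to cross the threshold plus a random excess."""
    mod, direction, thr = ABNORMALITY_THRESHOLDS[abn]
    mean = baselines[mod].mean
    if abn == TACHYCARDIA:
        excess = rng.uniform(10.0, 30.0)
    elif abn == BRADYCARDIA:
        excess = rng.uniform(5.0, 20.0)
    elif abn == HYPOTENSION:
        excess = rng.uniform(5.0, 15.0)
    else:  # hypoxia
        excess = rng.uniform(2.0, 8.0)
    gap = abs(thr - mean)
    return (gap + excess) if direction == "above" else -(gap + excess)


def _draw_episodes(
    duration: int,
    prevalence: dict[str, float],
    baselines: dict[str, BaselineParams],
    rng: np.random.Generator,
) -> list[EpisodeSpec]:
    episodes: list[EpisodeSpec] = []
    for abn in ABNORMALITY_TYPES:
        p = prevalence.get(abn, 0.0)
        if rng.random() >= p:
            continue
        lo, hi = _EPISODE_DURATION_RANGE
        max_len = duration - 7  # onset >= 6 and end <= duration
        if max_len < max(lo, 1):
            continue  # visit too short to host an episode
        ep_len = int(rng.integers(lo, min(hi, max_len) + 1))
        spec = None
        for _ in range(20):
            onset = int(rng.integers(6, duration - ep_len + 1))
            cand = EpisodeSpec(abn, onset, ep_len, _draw_magnitude(abn, baselines, rng))
            overlap = any(
                e.modality == cand.modality and cand.onset < e.end and e.onset < cand.end
                for e in episodes
            )
            if not overlap:
                spec = cand
                break
        if spec is not None:
            episodes.append(spec)
    return episodes


def _make_triage(visit: Visit, rng: np.random.Generator, minute: int = -5) -> ChartEvent:
    """Triage vitals: minute-0 monitor values plus small observation noise."""
    recorded = {}
    for mod in MODALITIES:
        trace = visit.traces.get(mod)
        if trace is None:
            continue
        v = trace.value_at(0)
        if v is None:
            continue
        noisy = v + rng.normal(0.0, COVERAGE_BOUNDS[mod] / 2.0)
        low, high = GUARD_RAILS[mod]
        recorded[mod] = float(np.clip(noisy, low, high))
    return ChartEvent(minute=minute, recorded=recorded)


def generate_visit(config: CohortConfig, visit_id: str, seed: RngLike) -> Visit:
    """Generate one synthetic visit (traces, episodes, triage, charting)."""
    rng = _as_rng(seed)
    mu = math.log(config.duration_median)
    duration = int(round(math.exp(mu + config.duration_log_sd * rng.standard_normal())))
    duration = max(duration, config.min_duration)
    esi = int(rng.choice([1, 2, 3, 4], p=list(config.esi_probs)))
    episodes = _draw_episodes(duration, config.episode_prevalence, config.baseline_params, rng)
    by_mod: dict[str, list[EpisodeSpec]] = {m: [] for m in MODALITIES}
    for ep in episodes:
        by_mod[ep.modality].append(ep)
    traces = {
        HR: generate_trace(HR, duration, config.baseline_params[HR], by_mod[HR], rng),
        RR: generate_trace(RR, duration, config.baseline_params[RR], by_mod[RR], rng),
        SPO2: generate_trace(SPO2, duration, config.baseline_params[SPO2], by_mod[SPO2], rng),
        MAP: generate_map_trace(
            duration, config.baseline_params[MAP], by_mod[MAP], config.cuff_interval, rng
        ),
    }
    visit = Visit(
        visit_id=visit_id,
        esi=esi,
        duration_min=duration,
        traces=traces,
        injected_episodes=episodes,
    )
    visit.triage = _make_triage(visit, rng)
    visit.actual_charting = simulate_nurse_charting(visit, config.nurse_policy, rng)
    return visit


def generate_cohort(config: CohortConfig) -> list[Visit]:
    """Generate a reproducible cohort of ``config.n_visits`` synthetic visits."""
    children = np.random.SeedSequence(config.seed).spawn(config.n_visits)
    return [
        generate_visit(config, visit_id=f"V{i:05d}", seed=np.random.default_rng(child))
        for i, child in enumerate(children)
    ]
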