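# Methods

## The data model

A visit runs from rooming (minute 0) to departure, on a 1-minute grid.
Raw monitor samples are averaged within half-open bins `[m, m+1)`; missing
minutes are filled by last observation carried forward (LOCF), and minutes
before the first defined value stay undefined.  Blood pressure is summarised
as mean arterial pressure, MAP = (1/3)·SBP + (2/3)·DBP, and — because cuff
measurements are intermittent — the MAP trace is piecewise constant between
cuff readings.  Charting events carry one value per recorded modality;
triage observations are charting events at non-positive minutes and never
enter the coverage denominator.

## Coverage and informativeness

Minute `m` of modality `X` is covered when `|x(m) − ref(m)| ≤ δ_X`, where
`ref(m)` is the value of the most recent event at minute ≤ m that recorded
`X` (triage included), and the half-widths are δ = 5 (HR, /min), 3 (RR,
/min), 2 (SpO2, %), 6 (MAP, mm Hg).  Conventions, each chosen once:

* comparison is inclusive (`≤ δ`), matching bounds quoted as ±δ;
* an event's own minute already uses the new reference;
* an event that omits a modality leaves the previous reference standing;
* the denominator is all defined monitor minutes; minutes before any
  reference exist count as uncovered.  Whether such lead-in minutes belong
  in the denominator is a genuine modelling choice, so
  `coverage(..., include_leading_minutes=False)` exposes the alternative.

Informativeness of event `i` for modality `X` is
`coverage(all events) − coverage(all events except i)`, computed by two full
coverage passes; no clamping, so values can be negative (an event recording
a transient value can misdirect the downstream reference).

## Abnormality capture

Thresholds are strict: HR > 100 (tachycardia), HR < 60 (bradycardia),
MAP < 65 (hypotension), SpO2 < 95 (hypoxia).  An event of a type exists when
no minute of the first 5 *defined* minutes of that modality's trace meets
the threshold (warm-in, counted from monitoring initiation of the modality,
not the visit) but a later defined minute does; the first such minute is the
onset, and one event per type per visit is kept.  Capture requires a chart
entry at minute ≥ onset whose *recorded* value meets the threshold — an
entry made during an episode but recording a normal value does not capture
it.  No upper time limit is imposed by default (`horizon_minutes` exposes
one).  Whether capture should be required before the episode resolves is
unknowable from charted data alone; we deliberately do not require it.

## Charting strategies

* *Equal spacing*: `k` events at `round(i·(D−1)/(k−1))`, anchored at both
  endpoints — "evenly across the visit" is otherwise underdetermined.
* *Fixed schedule*: events at 0, I, 2I, … with I per triage ESI
  (1→13, 2→45, 3→71, 4→65 minutes; configurable, with a flagged fallback
  for ESI 5).
* *Variable schedule*: online; first event at the first minute with ≥ 2
  defined modalities; at each event, if every modality present in both the
  current and the previous observation lies within its coverage bound the
  next event follows after the large step, else after the small step.  The
  first in-room check compares against triage; a missing triage counts as
  unstable.  MAP joins the check only where a cuff-derived value exists.
* *Grid search*: all (large, small) pairs over large ∈ {20,…,120},
  small ∈ {10,…,90} (step 10; 11×9 grid by default, fully configurable
  since step pairs with small > large are mechanically valid but
  semantically inverted).  Selection: among pairs with mean events/visit ≤
  budget (mean actual events by default), the pair closest to the budget;
  ties prefer higher mean coverage, then a smaller small step.  If nothing
  is feasible the cheapest pair is returned, flagged.

## Optimal placement

Because the reference for every minute is the single most recent event,
the coverage objective decomposes over segments between consecutive events.
`interval_gain(ref, a, b)` is the weighted covered-minute count of `[a, b)`
scored against the values at `ref` (modalities undefined at `ref` are
skipped).  The optimizer maximizes

    G0(e1) + Σ_i gain(e_i, e_i, e_{i+1}) + gain(e_K, e_K, D)

over all sets of ≤ K event minutes, where G0 scores the pre-first-event
segment against triage (zero without triage).  A suffix dynamic program over
(event minute, remaining budget) solves this exactly in O(K·D²) time after
an O(D²·modalities) table build; a 480-minute visit with K = 8 solves in
well under a second.  Ties are broken toward the lexicographically earliest
minute sequence (fewer events first, then earlier minutes); equality
comparisons use a 1e-6 tolerance, exact for integer weights.  Events may sit
at any minute, not only at actual charting minutes, and the solver may use
fewer than K events when extra events add nothing.  `brute_force_placement`
enumerates all C(D, ≤K) configurations (capped) and is the validation
oracle.  One caveat: the segment decomposition assumes the reference for a
modality comes from the segment's own event; if an event records no value
for a modality (undefined at that minute), true coverage could fall back to
an older reference and exceed the segment score.  Generated cohorts define
every modality at every minute from rooming, so the decomposition is exact
there.

Modality weights default to 1 each ("overall coverage across all
modalities"); equal weighting is clinically debatable, hence configurable.

## Statistical procedures

All tests two-sided, α = 0.05, no multiplicity adjustment.

* Coverage comparisons: Welch two-sample t (pooled-variance switch
  available), and a Fieller-type CI for the ratio of means under unequal
  variances — the CI is the set of ratios R with
  `(m_a − R·m_b)² ≤ t²(v_a/n_a + R²·v_b/n_b)` (Welch df); when the
  denominator mean is not significantly positive the interval is unbounded
  and flagged.
* Capture comparisons: Yates continuity-corrected χ² on the 2×2 table
  (p = 1 with a zero margin, flagged), and a skewness-corrected score CI for
  the ratio of proportions: with constrained MLEs p̃1 = φ·p̃2 (closed form),
  score u(φ) = (p̂1 − φ·p̂2)/√(p̃1q̃1/n1 + φ²p̃2q̃2/n2) and estimated
  skewness γ(φ) of the numerator, the limits solve
  u(φ) = ±z + γ(φ)(z² − 1)/6.  The correction is applied at the target
  quantile (z² form) rather than the u² form, which is first-order
  equivalent but keeps the equation monotone in φ and therefore
  bracketable far from the estimate; roots are found by bisection
  (`brentq`, xtol 1e-12) with decade-stepped bracket expansion.  Zero
  numerator gives a lower limit of 0; zero denominator an infinite upper
  limit.
* Lag comparisons: Wilcoxon signed-rank on events captured by both
  strategies, paired by (visit, abnormality type) — the natural pairing
  unit, since each visit contributes at most one event per type.  Zero
  differences are dropped; the exact conditional distribution is used for
  n ≤ 25 (ties permitted), the tie-corrected normal approximation with
  continuity correction above.  Median-difference CIs come from a
  percentile bootstrap (default 10 000 replicates, seeded and exactly
  reproducible); groups are resampled independently because the two
  strategies' captured-event sets need not coincide, with a paired variant
  available.  The accompanying p is the bootstrap achieved significance
  level, not an exact test.

## Synthetic cohorts

The generator emulates a monitored adult ED population; every default is a
fixed study condition:

| parameter | default | rationale |
|---|---|---|
| visit duration | lognormal, median 324 min, log-SD 0.47, floor 20 min | median/IQR of monitored ED stays (implied quartiles ≈ 236/445 min) |
| ESI mix (1–4) | 2.0 / 35.3 / 61.5 / 1.2 % | triage mix of monitored beds |
| episode prevalence | tachy 15.1, brady 12.4, hypotension 5.5, hypoxia 40.2 % per visit | observed per-visit rates of new abnormalities |
| HR baseline | mean 80 /min, SD 5.5, reversion 0.05/min | normocardic adult; thresholds ≥ 3 SD away so crossings are episode-driven |
| RR baseline | mean 16 /min, SD 2.2, reversion 0.05/min | typical adult RR |
| SpO2 baseline | mean 97.5 %, SD 0.6, reversion 0.05/min | simulated on a logit scale over (50, 100] for the ceiling effect |
| MAP baseline | mean 85 mm Hg, SD 6, reversion 0.03/min | normotensive adult; slower drift |
| cuff interval | 30 min | routine non-invasive BP cycling |
| nurse cadence | 100 min, jitter SD 15, reactive prob 0.25 | yields ≈ 4.4 events/visit (median 4), matching observed charting density |

Traces are stationary AR(1) processes (φ = 1 − reversion; innovation SD
matched to the stationary SD), clipped to physiologic guard rails (HR
20–250, RR 2–60, SpO2 50–100, MAP 20–200; clipped minutes are counted on
the trace).  Episodes shift the process mean additively with 3-minute
linear on/off ramps inside the episode window (onsets are gradual, as real
deteriorations are); magnitudes are drawn to overshoot the threshold by a
type-specific margin, and if noise still reverts the whole window the
plateau midpoint is pinned so every injected episode is realised on the
monitor.  MAP episodes act on the underlying continuous pressure; cuff
sampling may legitimately miss short dips.  Nurse charting combines
jittered multiples of the cadence (the rooming observation clamped to
minute 0) with optional reactive events the minute after an abnormality
first appears; charted values equal monitor values.  Triage vitals are the
minute-0 monitor values plus Gaussian noise with SD half the coverage bound.

What the generator does *not* emulate: transcription error and value
rounding in nurse charting, charting clustered around interventions, missing
modalities, monitor artifacts and false alarms, inter-visit correlation, or
case-mix drift.  Simulated nurses are therefore more diligent than real
ones — synthetic actual-practice coverage (≈ 71 % modality-averaged) and
capture rates (≈ 60–70 %) are far better than observed in real EDs, and the
prospective strategies consequently show little or no improvement over
synthetic actual practice.  Passing tests demonstrate the internal
correctness of the metrics, strategies, optimizer and statistics — not
real-world effect sizes or directions.

## Problem sizes and numerical checks

The test-suite validates the optimizer against exhaustive enumeration on
110 random visits (duration ≤ 30 min, K ≤ 3), checks optimizer dominance
visit-by-visit on a 500-visit cohort, the coverage metric against a literal
per-minute scan on 1 000 random instances, generator calibration at 2 000
visits, and CI calibration by simulation (2 000 replicates; ratio of
proportions at n = 200 per group, bootstrap median difference at n = 501
per group with 1 000 inner replicates — the percentile bootstrap for a
median is mildly conservative at smaller n).  The acceptance script runs
the full pipeline at 500 visits.  All randomness flows through seeded numpy
Generators; reruns with the same configuration are byte-identical.

## Known limitations

* The additive-segment optimizer is retrospective by design; it bounds
  achievable coverage but is not a deployable policy.
* Coverage treats all minutes equally; no severity weighting.
* The 1-minute mean is the only artifact filter, so a real deployment would
  see residual false alarms, particularly for SpO2.
* The exact variant of the heterogeneous-variance ratio-of-means CI and the
  skewness-corrected score CI exist in several published forms; the forms
  implemented here are stated above and validated by parametric-bootstrap
  agreement and empirical-coverage simulation rather than against a single
  canonical reference.
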