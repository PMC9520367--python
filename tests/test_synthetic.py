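"""Tests for the synthetic cohort generator."""

import numpy as np
import pytest
from scipy.stats import norm

from vitalsched.synthetic import (
    BaselineParams,
    CohortConfig,
    NursePolicy,
    generate_cohort,
    generate_map_trace,
    generate_trace,
    generate_visit,
    simulate_nurse_charting,
)
from vitalsched.types import (
    GUARD_RAILS,
    HR,
    MAP,
    EpisodeSpec,
    threshold_crossed,
)

from conftest import make_visit


class TestGenerateTrace:
    def test_zero_noise_is_constant_baseline(self):
        trace = generate_trace(HR, 10, BaselineParams(mean=70, sd=0), seed=5)
        assert np.allclose(trace.values, 70.0)
        assert trace.defined_mask.all()

    def test_zero_noise_episode_plateau_and_baseline(self):
        """With no noise, the episode plateau sits at mean+magnitude and all
        minutes outside the episode stay at the baseline."""
        ep = EpisodeSpec("tachycardia", onset=30, duration=10, magnitude=40)
        trace = generate_trace(HR, 60, BaselineParams(mean=70, sd=0), [ep], seed=1)
        # 3-minute linear ramps inside the episode: full shift on the plateau
        assert np.allclose(trace.values[33:37], 110.0)
        assert (trace.values[30:40] > 70).all()
        outside = np.r_[trace.values[:30], trace.values[40:]]
        assert np.allclose(outside, 70.0)

    def test_stationary_moments(self):
        """Long-run sample mean and SD match the configured stationary values."""
        trace = generate_trace(HR, 40_000, BaselineParams(mean=70, sd=8, reversion=0.1), seed=2)
        assert abs(trace.values.mean() - 70) < 0.5
        assert abs(trace.values.std(ddof=1) - 8) < 1.0

    def test_overlapping_episodes_rejected(self):
        eps = [
            EpisodeSpec("tachycardia", onset=10, duration=20, magnitude=40),
            EpisodeSpec("bradycardia", onset=25, duration=10, magnitude=-30),
        ]
        with pytest.raises(ValueError, match="overlap"):
            generate_trace(HR, 60, BaselineParams(mean=75, sd=5), eps, seed=0)

    def test_episode_beyond_visit_rejected(self):
        ep = EpisodeSpec("tachycardia", onset=50, duration=20, magnitude=40)
        with pytest.raises(ValueError, match="beyond"):
            generate_trace(HR, 60, BaselineParams(mean=75, sd=5), [ep], seed=0)

    def test_deterministic_given_seed(self):
        a = generate_trace(HR, 200, BaselineParams(mean=75, sd=6), seed=42)
        b = generate_trace(HR, 200, BaselineParams(mean=75, sd=6), seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    @pytest.mark.parametrize("modality", list(GUARD_RAILS))
    def test_guard_rails(self, modality):
        params = BaselineParams(mean=sum(GUARD_RAILS[modality]) / 2, sd=50, reversion=0.5)
        trace = generate_trace(modality, 500, params, seed=3)
        low, high = GUARD_RAILS[modality]
        assert trace.values.min() >= low and trace.values.max() <= high


class TestMapTrace:
    def test_piecewise_constant_at_cuff_minutes(self):
        trace = generate_map_trace(10, BaselineParams(mean=90, sd=0), cuff_interval=5, seed=0)
        assert np.allclose(trace.values, 90.0)
        changes = np.flatnonzero(np.diff(trace.values) != 0) + 1
        assert set(changes) <= {5}

    def test_interval_exceeding_duration_gives_single_value(self):
        trace = generate_map_trace(10, BaselineParams(mean=90, sd=5), cuff_interval=20, seed=1)
        assert len(np.unique(trace.values)) == 1
        assert trace.defined_mask.all()

    @pytest.mark.parametrize("duration,interval", [(100, 7), (60, 30), (45, 45)])
    def test_distinct_value_count_bound(self, duration, interval):
        trace = generate_map_trace(
            duration, BaselineParams(mean=85, sd=6), cuff_interval=interval, seed=2
        )
        assert len(np.unique(trace.values)) <= int(np.ceil(duration / interval))

    def test_episode_acts_on_underlying_process(self):
        ep = EpisodeSpec("hypotension", onset=10, duration=30, magnitude=-30)
        trace, underlying = generate_map_trace(
            60, BaselineParams(mean=85, sd=0), [ep], cuff_interval=5, seed=0, return_underlying=True
        )
        assert threshold_crossed(underlying[10:40], "hypotension").any()


class TestNurseCharting:
    def _flat_visit(self, duration):
        return make_visit({HR: np.full(duration, 80.0), MAP: np.full(duration, 85.0)})

    def test_exact_cadence_no_jitter(self):
        visit = self._flat_visit(240)
        policy = NursePolicy(cadence_min=60, jitter_sd=0, reactive_prob=0)
        events = simulate_nurse_charting(visit, policy, seed=0)
        assert [e.minute for e in events] == [0, 60, 120, 180]

    def test_mean_event_count_matches_closed_form(self):
        """Simulated scheduled-event counts match the analytic expectation
        sum_k Phi((D - k*cadence) / jitter) for jittered-multiple charting."""
        duration, cadence, jitter = 240, 60.0, 10.0
        visit = self._flat_visit(duration)
        policy = NursePolicy(cadence_min=cadence, jitter_sd=jitter, reactive_prob=0)
        counts = [
            len(simulate_nurse_charting(visit, policy, seed=s)) for s in range(2000)
        ]
        # the rooming event (k=0) is clamped to minute 0 and always present
        ks = np.arange(1, int(duration / cadence) + 10)
        expected = 1.0 + norm.cdf((duration - 0.5 - ks * cadence) / jitter).sum()
        assert abs(np.mean(counts) - expected) < 0.3

    def test_reactive_charting_lands_inside_episode(self):
        ep = EpisodeSpec("tachycardia", onset=30, duration=20, magnitude=40)
        trace = generate_trace(HR, 120, BaselineParams(mean=70, sd=0), [ep], seed=0)
        visit = make_visit({HR: trace.values})
        policy = NursePolicy(cadence_min=200, jitter_sd=0, reactive_prob=1.0)
        events = simulate_nurse_charting(visit, policy, seed=0)
        assert any(30 <= e.minute < 50 for e in events)

    def test_event_times_strictly_increasing(self, small_cohort):
        for visit in small_cohort:
            minutes = [e.minute for e in visit.actual_charting]
            assert all(b > a for a, b in zip(minutes, minutes[1:]))


class TestGenerateCohort:
    def test_empty_cohort(self):
        assert generate_cohort(CohortConfig(n_visits=0, seed=1)) == []

    def test_determinism_field_for_field(self):
        a = generate_cohort(CohortConfig(n_visits=5, seed=77))
        b = generate_cohort(CohortConfig(n_visits=5, seed=77))
        for va, vb in zip(a, b):
            assert va.visit_id == vb.visit_id and va.esi == vb.esi
            assert va.duration_min == vb.duration_min
            for mod in va.traces:
                np.testing.assert_array_equal(va.traces[mod].values, vb.traces[mod].values)
            assert [e.minute for e in va.actual_charting] == [e.minute for e in vb.actual_charting]
            assert va.triage.recorded == vb.triage.recorded

    def test_injected_episodes_cross_their_threshold(self, small_cohort):
        """Every injected episode is realised on the monitor (MAP episodes on
        the recorded trace may be missed by cuff sampling and are exempt)."""
        for visit in small_cohort:
            for ep in visit.injected_episodes:
                if ep.modality == MAP:
                    continue
                window = visit.traces[ep.modality].values[ep.onset : ep.end]
                assert threshold_crossed(window, ep.abnormality_type).any()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(esi_probs=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            CohortConfig(cuff_interval=0)
        with pytest.raises(ValueError):
            CohortConfig(episode_prevalence={"tachycardia": 1.5})

    def test_visit_structure(self, small_cohort):
        for visit in small_cohort:
            assert set(visit.traces) == {"HR", "MAP", "RR", "SPO2"}
            assert visit.triage is not None and visit.triage.minute <= 0
            assert 1 <= visit.esi <= 4
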