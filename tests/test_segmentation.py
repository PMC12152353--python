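"""Objective-function segmentation: signals, peaks, and trial-level behavior."""

import numpy as np
import pytest

import pickplace as pp
from pickplace.layout import Rect
from pickplace.segmentation import Discarded


class TestPositionProbability:
    def test_inside_region_is_one(self):
        r = Rect(0, 0, 10, 10)
        assert pp.position_probability(5.0, 5.0, r, sd=3.0) == 1.0

    def test_one_sd_outside_boundary(self):
        r = Rect(0, 0, 10, 10)
        p = pp.position_probability(13.0, 5.0, r, sd=3.0)
        assert np.isclose(p, np.exp(-0.5))

    def test_far_away_is_negligible(self):
        r = Rect(0, 0, 10, 10)
        assert pp.position_probability(10 + 6 * 3.0, 5.0, r, sd=3.0) < 1e-7

    def test_degenerate_sd_rejected(self):
        with pytest.raises(ValueError):
            pp.position_probability(0, 0, Rect(0, 0, 1, 1), sd=0.0)


class TestBuildObjective:
    def test_zero_gate_zeroes_objective(self):
        n = 20
        ones = np.ones(n)
        gate = ones.copy()
        gate[7] = 0.0
        obj = pp.build_objective(ones, ones, gate, ones, ones, ones).objective
        assert obj[7] == 0.0 and np.all(obj[np.arange(n) != 7] == 1.0)

    def test_all_ones_gives_one(self):
        ones = np.ones(10)
        obj = pp.build_objective(*([ones] * 6)).objective
        assert np.all(obj == 1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pp.build_objective(np.ones(5), np.ones(6), np.ones(5),
                               np.ones(5), np.ones(5), np.ones(5))

    def test_objective_stays_in_unit_interval(self):
        rng = np.random.default_rng(0)
        parts = [rng.uniform(0, 1, 50) for _ in range(6)]
        obj = pp.build_objective(*parts).objective
        assert np.all((obj >= 0) & (obj <= 1))


class TestSuppression:
    def test_no_events_is_identity(self, seg_config):
        rng = np.random.default_rng(1)
        s, e = rng.uniform(0, 1, 300), rng.uniform(0, 1, 300)
        s2, e2 = pp.apply_mutual_suppression(s, e, config=seg_config)
        assert np.array_equal(s, s2) and np.array_equal(e, e2)

    def test_single_start_weights_end_objective_toward_offset(self, seg_config):
        n, f = 600, 100
        ones = np.ones(n)
        _, e2 = pp.apply_mutual_suppression(ones, ones, starts=[f],
                                            config=seg_config)
        assert e2[f + seg_config.suppression_offset] > 0.99
        assert e2[f] <= seg_config.suppression_floor + 0.05
        assert e2[n - 1] <= seg_config.suppression_floor + 0.05

    def test_start_windows_precede_ends(self, seg_config):
        n, f = 800, 600
        ones = np.ones(n)
        s2, _ = pp.apply_mutual_suppression(ones, ones, ends=[f],
                                            config=seg_config)
        assert s2[f - seg_config.suppression_offset] > 0.99
        assert s2[f] <= seg_config.suppression_floor + 0.05


class TestDetectEvents:
    def test_single_bump_detected_at_mode(self):
        t = np.arange(500)
        obj = np.exp(-0.5 * ((t - 211) / 8.0) ** 2)
        assert pp.detect_events(obj) == [211]

    def test_two_close_equal_bumps_keep_earlier(self):
        t = np.arange(300)
        obj = (np.exp(-0.5 * ((t - 100) / 5.0) ** 2)
               + np.exp(-0.5 * ((t - 130) / 5.0) ** 2))
        events = pp.detect_events(obj, min_distance=50)
        assert len(events) == 1
        assert abs(events[0] - 100) <= 3  # earlier bump wins (slight overlap shift)

    def test_distant_bumps_both_kept_sorted(self):
        t = np.arange(600)
        obj = (0.5 * np.exp(-0.5 * ((t - 400) / 6.0) ** 2)
               + np.exp(-0.5 * ((t - 150) / 6.0) ** 2))
        assert pp.detect_events(obj, min_distance=50) == [150, 400]

    def test_all_zero_objective_gives_no_events(self):
        assert pp.detect_events(np.zeros(100)) == []

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            pp.detect_events(np.array([0.0, np.nan, 1.0]))


class TestSegmentTrial:
    def test_clean_trial_yields_search_size_segments(self, clean_trial,
                                                     seg_config):
        spec, track, _ = clean_trial
        seg = pp.segment_trial(track, spec.search_size, seg_config)
        assert seg.reach_ok and seg.transport_ok
        assert len(seg.reach) == 4 and len(seg.transport) == 4
        combined = seg.combined()
        assert [s.phase for s in combined] == ["reach", "transport"] * 4
        for a, b in zip(combined, combined[1:]):
            assert a.end_frame < b.start_frame

    def test_boundaries_recovered_within_5_frames(self, clean_trial,
                                                  seg_config):
        spec, track, truth = clean_trial
        seg = pp.segment_trial(track, spec.search_size, seg_config)
        for phase in ("reach", "transport"):
            for m, (ts, te) in zip(getattr(seg, phase),
                                   truth.boundaries(phase)):
                assert abs(m.start_frame - ts) <= 5
                assert abs(m.end_frame - te) <= 5

    def test_dropped_object_trial_discarded_with_count_mismatch(
            self, layout, seg_config):
        params = pp.CohortParams(noise_sd_px=0.0, p_likelihood_dropout=0.0,
                                 p_drop_artifact=1.0)
        spec = pp.TrialSpec("P01", 1, 1, "collect", "blue", 4, 2000.0)
        discarded = 0
        for seed in range(5):
            track, truth = pp.generate_trial_trajectory(spec, layout, params,
                                                        rng=seed)
            assert truth.artifact
            seg = pp.segment_trial(track, spec.search_size, seg_config)
            discarded += (not seg.transport_ok) and \
                seg.transport.reason == "count-mismatch"
        assert discarded >= 4  # a dropped object defeats the count check

    def test_deterministic(self, clean_trial, seg_config):
        spec, track, _ = clean_trial
        a = pp.segment_trial(track, spec.search_size, seg_config)
        b = pp.segment_trial(track, spec.search_size, seg_config)
        assert a.reach == b.reach and a.transport == b.transport

    def test_too_short_track_discarded(self, seg_config):
        track = pp.KeypointTrack(np.zeros(10), np.zeros(10), np.ones(10))
        seg = pp.segment_trial(track, 3, seg_config)
        assert not seg.reach_ok and seg.reach.reason == "too-short"

    def test_raising_speed_threshold_never_adds_events(self, clean_trial,
                                                       layout):
        spec, track, _ = clean_trial

        def n_events(thr):
            cfg = pp.SegmentationConfig(layout=layout,
                                        speed_threshold_cm_s=thr)
            seg = pp.segment_trial(track, spec.search_size, cfg)
            count = 0
            for phase in ("reach", "transport"):
                got = getattr(seg, phase)
                count += len(got) if not isinstance(got, Discarded) else 0
            return count

        counts = [n_events(thr) for thr in (20.0, 30.0, 45.0, 60.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestParticipantQC:
    def test_exactly_one_third_removed_is_kept(self):
        statuses = [False] * 27 + [True] * 54
        assert pp.qc_participant(statuses) == "keep"

    def test_more_than_one_third_removed_is_excluded(self):
        statuses = [False] * 28 + [True] * 53
        assert pp.qc_participant(statuses) == "exclude"

    def test_no_removals_kept(self):
        assert pp.qc_participant([True] * 81) == "keep"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pp.qc_participant([])
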