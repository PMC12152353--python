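"""Dependent variables: deceleration time, path ratio, onset, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pickplace as pp
from pickplace.dependent_measures import (
    InvalidSegmentError,
    MissingMetadataError,
    UndefinedRatioError,
    deceleration_time,
    movement_onset,
    path_ratio,
)
from pickplace.kinematics import KinematicSeries
from pickplace.segmentation import MovementSegment


class TestDecelerationTime:
    def test_symmetric_triangle_is_50_percent(self):
        v = np.array([0, 1, 2, 3, 2, 1, 0.0])
        assert deceleration_time(v) == 50.0

    def test_monotonic_rise_is_0_percent(self):
        assert deceleration_time(np.arange(10.0)) == 0.0

    def test_monotonic_fall_is_100_percent(self):
        assert deceleration_time(np.arange(10.0)[::-1]) == 100.0

    def test_tie_resolves_to_first_peak(self):
        v = np.array([0, 5, 5, 5, 0.0])
        assert deceleration_time(v) == 75.0

    def test_reversal_complements_when_peak_unique(self):
        rng = np.random.default_rng(1)
        v = np.sort(rng.uniform(0, 1, 21))  # unique maximum at the end
        v = np.concatenate([v, v[::-1][1:]])
        assert np.isclose(deceleration_time(v) + deceleration_time(v[::-1]),
                          100.0)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidSegmentError):
            deceleration_time([1.0])


class TestPathRatio:
    def test_straight_path_is_one(self):
        t = np.linspace(0, 1, 50)
        assert np.isclose(path_ratio(3 * t, 4 * t), 1.0)

    def test_semicircle_is_pi_over_two(self):
        theta = np.linspace(0, np.pi, 2000)
        assert np.isclose(path_ratio(np.cos(theta), np.sin(theta)),
                          np.pi / 2, atol=1e-4)

    def test_coincident_endpoints_rejected(self):
        theta = np.linspace(0, 2 * np.pi, 100)
        with pytest.raises(UndefinedRatioError):
            path_ratio(np.cos(theta), np.sin(theta))

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(-np.pi, np.pi), st.floats(-50, 50), st.floats(-50, 50),
           st.floats(0.1, 20))
    def test_invariant_under_rotation_translation_scaling(self, angle, dx, dy,
                                                          scale):
        t = np.linspace(0, 1, 80)
        x, y = t * 10, np.sin(t * np.pi) * 3
        base = path_ratio(x, y)
        c, s = np.cos(angle), np.sin(angle)
        x2 = scale * (c * x - s * y) + dx
        y2 = scale * (s * x + c * y) + dy
        assert np.isclose(path_ratio(x2, y2), base, rtol=1e-9)


class TestMovementOnset:
    def test_audio_at_zero_frame_112_gives_560_ms(self):
        onset, flagged = movement_onset(112, 0.0, fps=200.0)
        assert onset == 560.0 and not flagged

    def test_start_at_audio_end_is_zero(self):
        onset, flagged = movement_onset(400, 2000.0, fps=200.0)
        assert onset == 0.0 and not flagged

    def test_early_start_is_negative_and_flagged(self):
        onset, flagged = movement_onset(100, 1000.0, fps=200.0)
        assert onset == -500.0 and flagged

    def test_missing_audio_time_rejected(self):
        with pytest.raises(MissingMetadataError):
            movement_onset(100, None)


class TestSummarizeSegment:
    def _summary(self, x, y, s, e, pixel_scale=0.042, fps=200.0):
        lik = np.ones_like(np.asarray(x, dtype=float))
        track = pp.KeypointTrack(x, y, lik, fps=fps, pixel_scale=pixel_scale)
        window = min(51, len(lik) - (1 - len(lik) % 2))
        kin = KinematicSeries.from_track(track, window=window if window % 2
                                         else window - 1)
        seg = MovementSegment("t", 1, "reach", s, e,
                              (e - s + 1) * 1000.0 / fps)
        return pp.summarize_segment(track, seg, kin)

    def test_straight_100px_move_distance(self):
        x = np.linspace(0, 100, 101)
        out = self._summary(x, np.zeros_like(x), 0, 100)
        assert np.isclose(out.distance_cm, 4.2)
        assert np.isclose(out.path_ratio, 1.0)

    def test_constant_speed_avg_equals_peak(self):
        x = np.arange(200.0)
        out = self._summary(x, np.zeros_like(x), 30, 160)
        assert np.isclose(out.avg_speed_cm_s, out.peak_speed_cm_s)

    def test_duration_from_frame_count(self):
        x = np.arange(300.0)
        out = self._summary(x, np.zeros_like(x), 100, 149)
        assert out.duration_ms == 250.0  # 50 frames at 200 fps

    def test_generator_leg_distance_matches_ground_truth(self, clean_trial,
                                                         seg_config):
        spec, track, truth = clean_trial
        kin = KinematicSeries.from_track(track)
        for seg_truth in truth.segments:
            seg = MovementSegment("t", 1, seg_truth.phase,
                                  seg_truth.start_frame, seg_truth.end_frame,
                                  seg_truth.duration_ms)
            out = pp.summarize_segment(track, seg, kin)
            assert abs(out.distance_cm - seg_truth.distance_cm) \
                <= 0.01 * seg_truth.distance_cm

    def test_degenerate_and_out_of_bounds_segments_rejected(self):
        x = np.arange(100.0)
        with pytest.raises(ValueError):
            MovementSegment("t", 1, "reach", 10, 10, 5.0)  # < 2 frames
        with pytest.raises(InvalidSegmentError):
            self._summary(x, np.zeros_like(x), 50, 150)  # beyond track end

    def test_avg_speed_times_duration_approximates_distance(self, clean_trial):
        _, track, truth = clean_trial
        kin = KinematicSeries.from_track(track)
        seg_truth = truth.segments[1]  # a transport
        seg = MovementSegment("t", 1, "transport", seg_truth.start_frame,
                              seg_truth.end_frame, seg_truth.duration_ms)
        out = pp.summarize_segment(track, seg, kin)
        approx = out.avg_speed_cm_s * out.duration_ms / 1000.0
        assert abs(approx - out.distance_cm) < 0.15 * out.distance_cm
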