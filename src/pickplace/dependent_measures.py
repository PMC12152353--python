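"""Kinematic dependent variables per movement segment and per trial.

Per segment: duration (ms), average and peak smoothed speed (cm/s),
deceleration time (% of movement duration after peak speed), traveled
distance (cm), and the path ratio (traveled path / straight start-to-end
distance; 1 for a perfectly straight reach). Per trial: movement onset,
the time between the end of the audio instruction and the first detected
reach start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import KinematicSeries
from .pose_io import KeypointTrack
from .segmentation import MovementSegment


class InvalidSegmentError(ValueError):
    pass


class UndefinedRatioError(ValueError):
    """Path ratio undefined: start and end positions coincide."""


class MissingMetadataError(KeyError):
    pass


@dataclass
class KinematicSummary:
    trial_id: str
    phase: str
    index: int
    duration_ms: float
    avg_speed_cm_s: float
    peak_speed_cm_s: float
    deceleration_pct: float
    distance_cm: float
    path_ratio: float
    onset_ms: float | None = None       # trial-level, first reach only
    onset_flagged: bool = False         # negative onset (moved before audio end)


def deceleration_time(speed_segment) -> float:
    """Percent of the movement spent after peak speed.

    The peak is the first frame attaining the maximum, so a monotonically
    rising profile gives 0% and a symmetric profile 50%.
    """
    v = np.asarray(speed_segment, dtype=float)
    if v.size < 2:
        raise InvalidSegmentError("segment needs at least 2 frames")
    peak = int(np.argmax(v))
    return 100.0 * (v.size - 1 - peak) / (v.size - 1)


def path_ratio(x, y) -> float:
    """Traveled path length divided by the straight start-to-end distance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise InvalidSegmentError("segment needs at least 2 frames")
    traveled = float(np.hypot(np.diff(x), np.diff(y)).sum())
    direct = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    if direct < 1e-9:
        raise UndefinedRatioError("start and end positions coincide")
    return traveled / direct


def movement_onset(first_reach_start_frame: int, audio_end_time_ms: float | None,
                   fps: float = 200.0) -> tuple[float, bool]:
    """Onset in ms relative to the end of the audio instruction.

    Returns (onset_ms, flagged); the flag marks negative onsets, i.e. the
    hand left the key before the instruction finished. Negative values are
    retained, not clamped.
    """
    if audio_end_time_ms is None or (isinstance(audio_end_time_ms, float)
                                     and np.isnan(audio_end_time_ms)):
        raise MissingMetadataError("audio_end_time_ms missing from trial metadata")
    onset = first_reach_start_frame * 1000.0 / fps - float(audio_end_time_ms)
    return onset, onset < 0


def summarize_segment(track: KeypointTrack, segment: MovementSegment,
                      kin: KinematicSeries, use_raw_peak: bool = False
                      ) -> KinematicSummary:
    """Dependent variables for one movement segment.

    Speeds come from the smoothed series (raw-series peak behind
    ``use_raw_peak``); distance is the summed raw per-frame Euclidean step,
    converted to cm.
    """
    s, e = segment.start_frame, segment.end_frame
    if e - s < 1:
        raise InvalidSegmentError("segment shorter than 2 frames")
    if s < 0 or e >= track.n_frames:
        raise InvalidSegmentError("segment exceeds track bounds")
    to_cms = track.pixel_scale * track.fps
    smoothed = kin.smoothed_speed[s:e + 1] * to_cms
    peak_series = kin.speed[s:e + 1] * to_cms if use_raw_peak else smoothed
    # speed[i] is the displacement into frame i, so frames s+1..e cover the move
    distance = float(kin.speed[s + 1:e + 1].sum()) * track.pixel_scale
    return KinematicSummary(
        trial_id=segment.trial_id,
        phase=segment.phase,
        index=segment.index,
        duration_ms=(e - s + 1) * 1000.0 / track.fps,
        avg_speed_cm_s=float(smoothed.mean()),
        peak_speed_cm_s=float(peak_series.max()),
        deceleration_pct=deceleration_time(smoothed),
        distance_cm=distance,
        path_ratio=path_ratio(track.x[s:e + 1], track.y[s:e + 1]),
    )
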