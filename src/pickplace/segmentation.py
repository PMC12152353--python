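"""Objective-function segmentation of trials into reach and transport movements.

A trial's hand trajectory alternates between rest (at the start key, over a
grasped target, or at a placing location) and ballistic legs. Movement
starts and ends are found by multiplying per-frame probability signals into
a single objective function per event type:

* a position signal (1 inside the relevant region, Gaussian falloff outside),
* inverted smoothed speed (starts/ends happen near speed minima),
* soft gates requiring that a genuine movement (speed above 30 cm/s,
  acceleration above 0.5 cm/s per frame) follows a candidate start or
  precedes a candidate end, and that tracking confidence is high,
* a shifted-Gaussian localization term (sd 9 frames) centered on the
  movement-onset estimate derived from each speed-threshold crossing.

Start and end detection mutually suppress each other: the end objective is
down-weighted outside plausibility windows that follow each detected start
(nominal lag 100 frames), and vice versa. Peaks of the final objectives are
kept greedily by height with a minimum separation of 50 frames (250 ms).
A trial is discarded from an analysis when the detected number of starts or
ends does not equal the search size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.signal import find_peaks

from .kinematics import KinematicSeries
from .layout import Rect, WorkspaceLayout
from .pose_io import KeypointTrack, interpolate_low_confidence, to_physical

Phase = Literal["reach", "transport"]


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the segmentation stage.

    Speed threshold is in cm/s (the printed "cm/frame" unit is impossible
    at 200 fps on a 30-cm pad); acceleration threshold in cm/s per frame.
    ``suppression_window`` is (pre, post): the plausibility window for the
    complementary event spans [offset - pre, offset + post] frames with
    Gaussian edges of sd ``suppression_size``.
    """

    layout: WorkspaceLayout = field(default_factory=WorkspaceLayout.default)
    speed_threshold_cm_s: float = 30.0
    accel_threshold: float = 0.5          # cm/s per frame
    likelihood_threshold: float = 0.9
    position_sd_cm: float = 3.0
    shifted_gaussian_sd: float = 9.0      # frames
    onset_speed_fraction: float = 1.0 / 6.0
    onset_max_lookaround: int = 150       # frames to search for the onset frame
    onset_bias: int = 5                   # constant correction, frames (see docs)
    suppression_offset: int = 100         # frames
    suppression_size: float = 9.0         # Gaussian edge sd, frames
    suppression_window: tuple[int, int] = (60, 200)
    suppression_floor: float = 0.05
    peak_min_distance: int = 50           # frames
    peak_rel_height: float = 0.2
    soft_gates: bool = True
    gate_slack: float = 0.1
    gate_horizon: int = 70                # frames
    smoothing_window: int = 59
    smoothing_order: int = 3

    def __post_init__(self) -> None:
        for name in ("speed_threshold_cm_s", "accel_threshold",
                     "likelihood_threshold", "position_sd_cm",
                     "shifted_gaussian_sd", "suppression_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.peak_min_distance < 1:
            raise ValueError("peak_min_distance must be >= 1")


@dataclass
class ObjectiveSignals:
    """Component probability signals and their per-frame product."""

    position_prob: np.ndarray
    inverted_speed_prob: np.ndarray
    speed_gate: np.ndarray
    accel_gate: np.ndarray
    likelihood_gate: np.ndarray
    shifted_gaussian_weight: np.ndarray
    kind: Literal["start", "end"] = "start"

    @property
    def objective(self) -> np.ndarray:
        return (self.position_prob * self.inverted_speed_prob * self.speed_gate
                * self.accel_gate * self.likelihood_gate
                * self.shifted_gaussian_weight)


@dataclass(frozen=True)
class MovementSegment:
    trial_id: str
    index: int          # ordinal within trial, 1-based, per phase sequence
    phase: Phase
    start_frame: int
    end_frame: int
    duration_ms: float

    def __post_init__(self) -> None:
        if self.start_frame >= self.end_frame:
            raise ValueError("segment start must precede its end")


@dataclass(frozen=True)
class Discarded:
    """A trial (or one analysis of it) rejected with a machine-readable reason."""

    reason: str


@dataclass
class TrialSegmentation:
    """Reach and transport segmentations of one trial.

    The two analyses pass or fail independently: a trial may yield clean
    reaches while its transports cannot be separated, and vice versa.
    """

    trial_id: str
    reach: list[MovementSegment] | Discarded
    transport: list[MovementSegment] | Discarded

    @property
    def reach_ok(self) -> bool:
        return not isinstance(self.reach, Discarded)

    @property
    def transport_ok(self) -> bool:
        return not isinstance(self.transport, Discarded)

    def combined(self) -> list[MovementSegment]:
        """All segments sorted by start frame (only when both analyses pass)."""
        if not (self.reach_ok and self.transport_ok):
            raise ValueError("cannot combine: one analysis was discarded")
        return sorted(self.reach + self.transport, key=lambda s: s.start_frame)


# ---------------------------------------------------------------------------
# component signals


def position_probability(x_cm, y_cm, region: Rect, sd: float) -> np.ndarray:
    """1 inside the region, Gaussian falloff of the boundary distance outside."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    d = region.distance_outside(x_cm, y_cm)
    return np.exp(-0.5 * (d / sd) ** 2)


def _soft_gate(values: np.ndarray, threshold: float, slack: float,
               soft: bool) -> np.ndarray:
    if not soft:
        return (values >= threshold).astype(float)
    scale = max(abs(threshold) * slack, 1e-12)
    return 1.0 / (1.0 + np.exp(-(values - threshold) / scale))


def _forward_max(v: np.ndarray, horizon: int) -> np.ndarray:
    """max(v[i : i + horizon + 1]) for every i."""
    pad = np.concatenate([v, np.full(horizon, v[-1])])
    return np.lib.stride_tricks.sliding_window_view(pad, horizon + 1).max(axis=1)


def _backward_max(v: np.ndarray, horizon: int) -> np.ndarray:
    """max(v[i - horizon : i + 1]) for every i."""
    return _forward_max(v[::-1], horizon)[::-1]


def _threshold_crossings(v: np.ndarray, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices of upward and downward crossings of ``threshold``."""
    above = v >= threshold
    up = np.flatnonzero(~above[:-1] & above[1:]) + 1
    down = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    return up, down


def _onset_centers(v: np.ndarray, crossings: np.ndarray, level: float,
                   direction: int, max_steps: int, bias: int) -> list[int]:
    """Movement-boundary estimates near speed-threshold crossings.

    For a start (direction -1) walk backward from each upward crossing to
    the last frame at or below ``level``; for an end (direction +1) walk
    forward from each downward crossing to the first such frame. Because
    speed leaves rest quadratically (v ~ k t^2 for a smooth bell profile),
    the rest boundary is then extrapolated a further 2 v / |dv/dt| frames
    toward the dwell. Crossings whose neighborhood never gets slow (e.g. a
    mid-flight wobble) yield no center.
    """
    centers = []
    n = v.size
    dv = np.gradient(v)
    # rectified tracking noise leaves a positive speed floor during rest;
    # the onset level sits above the trial's own baseline
    baseline = float(np.percentile(v, 10))
    level = baseline + level
    for c in crossings:
        lo = max(c - max_steps, 0) if direction < 0 else c
        hi = c + 1 if direction < 0 else min(c + max_steps + 1, n)
        window = v[lo:hi]
        slow = np.flatnonzero(window <= level)
        if slow.size == 0:
            continue
        f = lo + (slow[-1] if direction < 0 else slow[0])
        slope = abs(dv[f])
        excess = max(v[f] - baseline, 0.0)
        pullback = min(2.0 * excess / slope, 30.0) if slope > 1e-6 else 0.0
        centers.append(int(np.clip(round(f + direction * pullback) + bias,
                                   0, n - 1)))
    return centers


def _gaussian_bumps(n: int, centers: Sequence[int], sd: float) -> np.ndarray:
    w = np.zeros(n)
    t = np.arange(n)
    for c in centers:
        w = np.maximum(w, np.exp(-0.5 * ((t - c) / sd) ** 2))
    return w


def build_objective(position_prob, inverted_speed_prob, speed_gate, accel_gate,
                    likelihood_gate, shifted_gaussian_weight,
                    kind: Literal["start", "end"] = "start") -> ObjectiveSignals:
    """Multiply component probability signals into one objective function."""
    parts = [np.asarray(p, dtype=float) for p in
             (position_prob, inverted_speed_prob, speed_gate, accel_gate,
              likelihood_gate, shifted_gaussian_weight)]
    n = parts[0].size
    if any(p.size != n for p in parts):
        raise ValueError("all component signals must have the same length")
    return ObjectiveSignals(*parts, kind=kind)


def apply_mutual_suppression(start_objective: np.ndarray,
                             end_objective: np.ndarray,
                             starts: Sequence[int] | None = None,
                             ends: Sequence[int] | None = None,
                             config: SegmentationConfig | None = None
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Re-weight each objective toward its complementary events.

    Given provisional starts, the end objective is multiplied by
    ``floor + (1 - floor) * w(t)`` where w is 1 inside the plausibility
    window [s + offset - pre, s + offset + post] after any start s, with
    Gaussian edges (sd ``suppression_size``), and likewise the start
    objective with windows placed before each provisional end. With no
    provisional events an objective is returned unchanged.
    """
    config = config or SegmentationConfig()
    pre, post = config.suppression_window
    off, sd, floor = (config.suppression_offset, config.suppression_size,
                      config.suppression_floor)

    def window_weight(n: int, events: Sequence[int], sign: int) -> np.ndarray:
        t = np.arange(n)
        w = np.zeros(n)
        for e in events:
            lo = e + sign * off - (pre if sign > 0 else post)
            hi = e + sign * off + (post if sign > 0 else pre)
            inside = np.clip(np.maximum(lo - t, t - hi), 0, None)
            w = np.maximum(w, np.exp(-0.5 * (inside / sd) ** 2))
        return floor + (1.0 - floor) * w

    start_out = np.asarray(start_objective, dtype=float).copy()
    end_out = np.asarray(end_objective, dtype=float).copy()
    if starts is not None and len(starts):
        end_out *= window_weight(end_out.size, starts, +1)
    if ends is not None and len(ends):
        start_out *= window_weight(start_out.size, ends, -1)
    return start_out, end_out


def detect_events(objective: np.ndarray, min_distance: int = 50,
                  height: float | None = None) -> list[int]:
    """Local maxima kept greedily by descending height, min separation apart.

    Equal-height conflicts resolve to the earlier frame. Returns frames in
    ascending order; an all-zero objective yields no events.
    """
    objective = np.asarray(objective, dtype=float)
    if not np.all(np.isfinite(objective)):
        raise ValueError("objective contains non-finite values")
    if objective.size == 0 or not np.any(objective > 0):
        return []
    peaks, _ = find_peaks(objective, plateau_size=(1, None))
    if height is not None:
        peaks = peaks[objective[peaks] >= height]
    if peaks.size == 0:
        return []
    heights = objective[peaks]
    order = np.lexsort((peaks, -heights))  # height desc, frame asc on ties
    kept: list[int] = []
    for i in order:
        p = peaks[i]
        if all(abs(p - q) >= min_distance for q in kept):
            kept.append(int(p))
    return sorted(kept)


# ---------------------------------------------------------------------------
# per-trial pipeline


def _objectives(track_phys, kin: KinematicSeries, likelihood: np.ndarray,
                analysis: Phase, config: SegmentationConfig
                ) -> tuple[ObjectiveSignals, ObjectiveSignals]:
    lay = config.layout
    x, y = track_phys.x_cm, track_phys.y_cm
    v = kin.smoothed_speed_cm_s
    a = np.abs(kin.acceleration_cm_s_frame)
    n = v.size

    if analysis == "reach":
        pos_start = np.maximum(
            position_probability(x, y, lay.key_region, config.position_sd_cm),
            position_probability(x, y, lay.placing_pad, config.position_sd_cm))
        pos_end = position_probability(x, y, lay.picking_pad, config.position_sd_cm)
    else:
        pos_start = position_probability(x, y, lay.picking_pad, config.position_sd_cm)
        pos_end = position_probability(x, y, lay.placing_pad, config.position_sd_cm)

    vmax = v.max()
    inv = 1.0 - v / vmax if vmax > 0 else np.ones(n)

    lik_gate = _soft_gate(likelihood, config.likelihood_threshold,
                          config.gate_slack, config.soft_gates)

    fwd_v = _forward_max(v, config.gate_horizon)
    bwd_v = _backward_max(v, config.gate_horizon)
    fwd_a = _forward_max(a, config.gate_horizon)
    bwd_a = _backward_max(a, config.gate_horizon)
    start_speed_gate = _soft_gate(fwd_v, config.speed_threshold_cm_s,
                                  config.gate_slack, config.soft_gates)
    end_speed_gate = _soft_gate(bwd_v, config.speed_threshold_cm_s,
                                config.gate_slack, config.soft_gates)
    start_accel_gate = _soft_gate(fwd_a, config.accel_threshold,
                                  config.gate_slack, config.soft_gates)
    end_accel_gate = _soft_gate(bwd_a, config.accel_threshold,
                                config.gate_slack, config.soft_gates)

    up, down = _threshold_crossings(v, config.speed_threshold_cm_s)
    level = config.onset_speed_fraction * config.speed_threshold_cm_s
    start_centers = _onset_centers(v, up, level, -1,
                                   config.onset_max_lookaround, config.onset_bias)
    end_centers = _onset_centers(v, down, level, +1,
                                 config.onset_max_lookaround, -config.onset_bias)
    start_weight = _gaussian_bumps(n, start_centers, config.shifted_gaussian_sd)
    end_weight = _gaussian_bumps(n, end_centers, config.shifted_gaussian_sd)

    start = build_objective(pos_start, inv, start_speed_gate, start_accel_gate,
                            lik_gate, start_weight, kind="start")
    end = build_objective(pos_end, inv, end_speed_gate, end_accel_gate,
                          lik_gate, end_weight, kind="end")
    return start, end


def _detect_analysis(start_obj: np.ndarray, end_obj: np.ndarray,
                     config: SegmentationConfig) -> tuple[list[int], list[int]]:
    """Starts first, then ends under suppression, then one start refinement."""

    def detect(obj: np.ndarray) -> list[int]:
        h = config.peak_rel_height * obj.max() if obj.max() > 0 else None
        return detect_events(obj, min_distance=config.peak_min_distance, height=h)

    starts0 = detect(start_obj)
    _, end_sup = apply_mutual_suppression(start_obj, end_obj, starts=starts0,
                                          config=config)
    ends = detect(end_sup)
    start_sup, _ = apply_mutual_suppression(start_obj, end_obj, ends=ends,
                                            config=config)
    starts = detect(start_sup)
    return starts, ends


def segment_trial(track: KeypointTrack, search_size: int,
                  config: SegmentationConfig | None = None,
                  trial_id: str = "") -> TrialSegmentation:
    """Segment one trial into reach and transport movements.

    ``search_size`` is the instructed number of targets; each analysis must
    detect exactly that many starts and ends or it is discarded with reason
    ``count-mismatch``. Low-confidence frames are repaired first
    (interpolation is idempotent, so pre-interpolated tracks are fine).
    """
    config = config or SegmentationConfig()
    if search_size < 1:
        raise ValueError("search_size must be >= 1")
    if track.n_frames < config.smoothing_window:
        short = Discarded("too-short")
        return TrialSegmentation(trial_id, short, short)

    track = interpolate_low_confidence(track)
    phys = to_physical(track)
    kin = KinematicSeries.from_track(track, order=config.smoothing_order,
                                     window=config.smoothing_window)
    fps = track.fps

    results: dict[str, list[MovementSegment] | Discarded] = {}
    for analysis in ("reach", "transport"):
        start_obj, end_obj = _objectives(phys, kin, track.likelihood,
                                         analysis, config)
        starts, ends = _detect_analysis(start_obj.objective, end_obj.objective,
                                        config)
        if len(starts) != search_size or len(ends) != search_size:
            results[analysis] = Discarded("count-mismatch")
            continue
        segs = []
        ok = True
        for i, (s, e) in enumerate(zip(starts, ends)):
            if s >= e or (i + 1 < search_size and e > starts[i + 1]):
                ok = False
                break
            segs.append(MovementSegment(trial_id=trial_id, index=i + 1,
                                        phase=analysis, start_frame=s,
                                        end_frame=e,
                                        duration_ms=(e - s + 1) * 1000.0 / fps))
        results[analysis] = segs if ok else Discarded("pairing-error")
    return TrialSegmentation(trial_id, results["reach"], results["transport"])


def qc_participant(trial_statuses: Sequence[bool]) -> str:
    """'keep' unless strictly more than one third of trials were removed."""
    statuses = list(trial_statuses)
    if not statuses:
        raise ValueError("participant has no trials")
    removed = sum(1 for ok in statuses if not ok)
    return "exclude" if removed / len(statuses) > 1.0 / 3.0 else "keep"
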