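"""Synthetic pick-and-place foraging data with known ground truth.

Emulates the study design end to end so every downstream stage is testable
without any recorded video: balanced trial schedules (blocks of 9 trials,
3 instructions x 3 colors x 3 search sizes), hand trajectories at 200 fps
that alternate reach and transport legs between a start key, a picking pad
and a placing pad, grasp/place dwell pauses, tracking noise and likelihood
dropouts, planted condition effects (instruction-specific transport
deceleration fractions, size-biased first target choice, near-left picking
bias), and start/end scene-image pairs with colored bricks removed from the
picking pad and added to the placing pad.

Movement legs use a Beta-kernel speed profile: v(u) proportional to
u^(a-1) (1-u)^(b-1) with a + b = 6, which for a = b = 3 is exactly the
minimum-jerk speed profile and whose peak location (a-1)/4 — hence the
deceleration fraction — is controlled smoothly by one parameter.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw
from scipy.special import betainc

from .layout import Rect, WorkspaceLayout
from .pose_io import DEFAULT_JOINT, KeypointTrack, save_track_csv, save_tracks_hdf5

INSTRUCTIONS = ("collect", "sort", "pile")
COLORS = ("blue", "red", "yellow")
SEARCH_SIZES = (3, 4, 5)

FPS = 200.0
TARGET_MARGIN_CM = 2.0   # keep bricks away from pad edges


class InvalidLayoutError(ValueError):
    pass


@dataclass(frozen=True)
class TrialSpec:
    participant_id: str
    block: int
    trial_index: int
    instruction: str
    target_color: str
    search_size: int
    audio_end_time_ms: float

    def __post_init__(self) -> None:
        if self.block < 1:
            raise ValueError("block must be >= 1")
        if self.instruction not in INSTRUCTIONS:
            raise ValueError(f"instruction must be one of {INSTRUCTIONS}")
        if self.target_color not in COLORS:
            raise ValueError(f"target_color must be one of {COLORS}")
        if self.search_size not in SEARCH_SIZES:
            raise ValueError(f"search_size must be one of {SEARCH_SIZES}")
        if self.audio_end_time_ms < 0:
            raise ValueError("audio_end_time_ms must be non-negative")


@dataclass
class SegmentTruth:
    phase: str               # "reach" or "transport"
    start_frame: int
    end_frame: int
    planted_decel_fraction: float
    decel_fraction: float    # realized on the clean trajectory
    distance_cm: float
    duration_ms: float
    peak_speed_cm_s: float
    avg_speed_cm_s: float


@dataclass
class GroundTruth:
    """True segmentation and planted effects for one synthetic trial.

    For artifact trials (a dropped object merges a transport with the next
    reach) the merged legs carry no truth segments and the reach/transport
    counts deliberately do not match the search size.
    """

    segments: list[SegmentTruth]
    first_target_size: str          # "small" or "large"
    target_quadrants: list[int]     # picking-pad quadrant id per picked target
    onset_ms: float
    artifact: bool
    picked_positions: list[tuple[float, float]]   # cm, image frame
    placed_positions: list[tuple[float, float]]

    def boundaries(self, phase: str | None = None) -> list[tuple[int, int]]:
        return [(s.start_frame, s.end_frame) for s in self.segments
                if phase is None or s.phase == phase]


@dataclass
class CohortParams:
    """Cohort size, planted condition effects, and noise model.

    Defaults mirror the study conditions: 24 participants x 81 trials,
    transport deceleration fractions 0.510 / 0.535 / 0.547 for collect /
    sort / pile, first-target large-size probabilities 0.844 / 0.819 /
    0.888, and picking biased toward the near-left pad quadrant.
    """

    n_participants: int = 24
    trials_per_participant: int = 81
    deceleration_fraction: dict[str, float] = field(default_factory=lambda: {
        "collect": 0.510, "sort": 0.535, "pile": 0.547})
    reach_deceleration_fraction: float = 0.5
    decel_jitter: float = 0.02
    p_large_first: dict[str, float] = field(default_factory=lambda: {
        "collect": 0.844, "sort": 0.819, "pile": 0.888})
    quadrant_weights: tuple[float, float, float, float] = (0.25, 0.15, 0.40, 0.20)
    noise_sd_px: float = 1.0
    p_likelihood_dropout: float = 0.01
    dwell_ms: float = 300.0
    dwell_jitter_frac: float = 0.2
    leg_avg_speed_cm_s: float = 46.0
    arc_height_frac: float = 0.18
    onset_mean_ms: float = 562.6
    onset_sd_ms: float = 120.0
    p_drop_artifact: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.trials_per_participant < 1:
            raise ValueError("cohort must have at least one participant and trial")
        for name in ("p_likelihood_dropout", "p_drop_artifact"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        for d in (self.deceleration_fraction, self.p_large_first):
            for instr in INSTRUCTIONS:
                if instr not in d:
                    raise ValueError(f"missing instruction {instr!r}")
                if not 0.0 <= d[instr] <= 1.0:
                    raise ValueError("fractions must lie in [0, 1]")
        w = np.asarray(self.quadrant_weights, dtype=float)
        if w.size != 4 or np.any(w < 0) or not math.isclose(w.sum(), 1.0,
                                                            abs_tol=1e-9):
            raise ValueError("quadrant_weights must be 4 non-negative values summing to 1")
        if self.noise_sd_px < 0 or self.dwell_ms <= 0:
            raise ValueError("invalid noise or dwell parameters")


# ---------------------------------------------------------------------------
# schedules


def generate_schedule(seed: int, n_blocks: int,
                      participant_id: str = "P01") -> list[TrialSpec]:
    """Balanced trial schedule: blocks of 9 with each instruction and each
    color three times, search sizes balanced per instruction x color pair
    across blocks (for 9 blocks every condition triple occurs exactly 3x).
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    pairs = [(i, c) for i in INSTRUCTIONS for c in COLORS]
    reps = -(-n_blocks // len(SEARCH_SIZES))  # ceil
    sizes_by_pair = {}
    for pair in pairs:
        seq = np.tile(SEARCH_SIZES, reps)[:n_blocks]
        rng.shuffle(seq)
        sizes_by_pair[pair] = seq
    trials: list[TrialSpec] = []
    idx = 1
    for b in range(n_blocks):
        block_trials = [(instr, color, int(sizes_by_pair[(instr, color)][b]))
                        for instr, color in pairs]
        order = rng.permutation(len(block_trials))
        for j in order:
            instr, color, size = block_trials[j]
            trials.append(TrialSpec(
                participant_id=participant_id, block=b + 1, trial_index=idx,
                instruction=instr, target_color=color, search_size=size,
                audio_end_time_ms=float(rng.uniform(1800.0, 2600.0))))
            idx += 1
    return trials


# ---------------------------------------------------------------------------
# trajectories


def _beta_profile(n_frames: int, decel_fraction: float) -> np.ndarray:
    """Normalized position profile s(u) on a frame grid.

    Beta-kernel speed with peak at u = 1 - decel_fraction; s is the
    regularized incomplete beta function, 0 at the start and 1 at the end.
    """
    u0 = np.clip(1.0 - decel_fraction, 0.05, 0.95)
    a = 1.0 + 4.0 * u0
    b = 6.0 - a
    u = np.arange(1, n_frames + 1) / n_frames
    return betainc(a, b, u)


def _leg_positions(a: np.ndarray, b: np.ndarray, n_frames: int,
                   decel_fraction: float, arc_height_cm: float) -> np.ndarray:
    """Frame positions of one movement leg from a to b (cm).

    The path bows sideways with a parabolic offset of sagitta
    ``arc_height_cm`` (signed), emulating gently curved natural reaches.
    """
    s = _beta_profile(n_frames, decel_fraction)
    chord = b - a
    length = np.hypot(*chord)
    if length < 1e-9:
        raise InvalidLayoutError("leg endpoints coincide")
    perp = np.array([-chord[1], chord[0]]) / length
    bulge = 4.0 * s * (1.0 - s) * arc_height_cm
    return a[None, :] + s[:, None] * chord[None, :] + bulge[:, None] * perp[None, :]


def _sample_in_rect(rect: Rect, rng: np.random.Generator,
                    margin: float = TARGET_MARGIN_CM) -> np.ndarray:
    if rect.width <= 2 * margin or rect.height <= 2 * margin:
        raise InvalidLayoutError("region too small for the placement margin")
    return np.array([rng.uniform(rect.x0 + margin, rect.x1 - margin),
                     rng.uniform(rect.y0 + margin, rect.y1 - margin)])


def _placing_positions(instruction: str, k: int, pad: Rect,
                       rng: np.random.Generator) -> list[np.ndarray]:
    cx, cy = pad.center
    if instruction == "pile":
        base = np.array([cx, cy]) + rng.normal(0.0, 0.5, 2)
        return [base + rng.normal(0.0, 0.3, 2) for _ in range(k)]
    if instruction == "sort":
        # distinct fields: 2 x 3 grid of cell centers
        xs = np.linspace(pad.x0, pad.x1, 3)[:2] + pad.width / 4
        ys = np.linspace(pad.y0, pad.y1, 4)[:3] + pad.height / 6
        cells = [np.array([x, y]) for x in xs for y in ys]
        chosen = rng.choice(len(cells), size=k, replace=False)
        return [cells[i] + rng.normal(0.0, 0.6, 2) for i in chosen]
    # collect: loose cluster
    out = []
    for _ in range(k):
        p = np.array([cx, cy]) + rng.normal(0.0, 2.5, 2)
        p[0] = np.clip(p[0], pad.x0 + TARGET_MARGIN_CM, pad.x1 - TARGET_MARGIN_CM)
        p[1] = np.clip(p[1], pad.y0 + TARGET_MARGIN_CM, pad.y1 - TARGET_MARGIN_CM)
        out.append(p)
    return out


def _quadrant_of(pad: Rect, pos: np.ndarray) -> int:
    for qid, rect in pad.quadrants().items():
        if rect.contains(pos[0], pos[1]):
            return qid
    return 4


def generate_trial_trajectory(spec: TrialSpec, layout: WorkspaceLayout,
                              params: CohortParams,
                              rng: np.random.Generator | int | None = None
                              ) -> tuple[KeypointTrack, GroundTruth]:
    """One trial's hand trajectory (200 fps) with ground-truth segmentation.

    The hand rests on the start key until the audio instruction ends plus a
    planted onset latency, then alternates reach and transport legs over
    the ``search_size`` targets, dwelling ``dwell_ms`` at every grasp and
    placing location, and finally returns to the key. Positions carry
    Gaussian pixel noise; the likelihood series sits near 0.99 with
    dropouts below 0.7 at the configured rate (dropout positions get 10x
    noise so that confidence-based interpolation is consequential).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    k = spec.search_size
    fps = FPS
    pick_pad = layout.picking_pad

    # -- targets -----------------------------------------------------------
    brick_pos = [_sample_in_rect(pick_pad, rng) for _ in range(6)]
    sizes = ["large"] * 3 + ["small"] * 3
    rng.shuffle(sizes)
    want_large = rng.random() < params.p_large_first[spec.instruction]
    want = "large" if want_large else "small"
    first_candidates = [i for i, s in enumerate(sizes) if s == want]
    first = int(rng.choice(first_candidates))
    rest = [i for i in range(6) if i != first]
    order = [first] + [int(i) for i in
                       rng.choice(rest, size=k - 1, replace=False)]
    targets = [brick_pos[i] for i in order]
    place_pos = _placing_positions(spec.instruction, k, layout.placing_pad, rng)

    artifact = bool(k >= 2 and rng.random() < params.p_drop_artifact)
    drop_idx = int(rng.integers(1, k)) if artifact else -1   # transport 1..k-1
    drop_point = None
    if artifact:
        gap_x = 0.5 * (layout.placing_pad.x1 + layout.picking_pad.x0)
        drop_point = np.array([gap_x + rng.normal(0, 2.0),
                               pick_pad.center[1] + rng.normal(0, 3.0)])

    # -- assemble the frame-by-frame clean trajectory ----------------------
    key = np.asarray(layout.start_key, dtype=float)
    onset = max(150.0, rng.normal(params.onset_mean_ms, params.onset_sd_ms))
    jit = params.dwell_jitter_frac

    chunks: list[np.ndarray] = []
    truth_segments: list[SegmentTruth] = []
    cursor = 0

    def dwell(pos: np.ndarray, ms: float) -> None:
        nonlocal cursor
        n = max(1, int(round(ms / 1000.0 * fps)))
        chunks.append(np.repeat(pos[None, :], n, axis=0))
        cursor += n

    def leg(a: np.ndarray, b: np.ndarray, decel: float,
            phase: str | None) -> None:
        nonlocal cursor
        dist = float(np.hypot(*(b - a)))
        n = max(24, int(round(dist / params.leg_avg_speed_cm_s * fps)))
        h = (params.arc_height_frac * dist * rng.uniform(0.7, 1.3)
             * rng.choice([-1.0, 1.0]))
        pos = _leg_positions(a, b, n, decel, h)
        chunks.append(pos)
        if phase is not None:
            truth_segments.append(SegmentTruth(
                phase=phase, start_frame=cursor, end_frame=cursor + n - 1,
                planted_decel_fraction=decel, decel_fraction=np.nan,
                distance_cm=np.nan, duration_ms=n * 1000.0 / fps,
                peak_speed_cm_s=np.nan, avg_speed_cm_s=np.nan))
        cursor += n

    def planted_decel(phase: str) -> float:
        base = (params.deceleration_fraction[spec.instruction]
                if phase == "transport" else params.reach_deceleration_fraction)
        return float(np.clip(base + rng.normal(0.0, params.decel_jitter),
                             0.25, 0.75))

    def dwell_ms() -> float:
        return params.dwell_ms * (1.0 + rng.uniform(-jit, jit))

    dwell(key, spec.audio_end_time_ms + onset)
    prev = key
    for i in range(k):
        leg(prev, targets[i], planted_decel("reach"),
            None if artifact and i == drop_idx else "reach")
        dwell(targets[i], dwell_ms())
        if artifact and i == drop_idx - 1:
            # dropped object: transport merges with the next reach, no
            # placing dwell and no speed minimum on a pad in between
            leg(targets[i], drop_point, planted_decel("transport"), None)
            prev = drop_point
            continue
        leg(targets[i], place_pos[i], planted_decel("transport"), "transport")
        dwell(place_pos[i], dwell_ms())
        prev = place_pos[i]
    leg(prev, key, 0.5, None)   # return to the key; neither reach nor transport
    dwell(key, 300.0)

    clean_cm = np.concatenate(chunks, axis=0)
    n_frames = clean_cm.shape[0]

    # -- realized kinematics on the clean trajectory -----------------------
    step = np.hypot(np.diff(clean_cm[:, 0]), np.diff(clean_cm[:, 1]))
    speed_cm = np.concatenate([[step[0]], step])   # cm/frame, frame-aligned
    for seg in truth_segments:
        s, e = seg.start_frame, seg.end_frame
        v = speed_cm[s:e + 1]
        peak = int(np.argmax(v))
        seg.decel_fraction = float((v.size - 1 - peak) / (v.size - 1))
        # speed_cm[s] is the step from the last dwell frame onto the leg
        seg.distance_cm = float(speed_cm[s:e + 1].sum())
        seg.peak_speed_cm_s = float(v.max() * fps)
        seg.avg_speed_cm_s = float(v.mean() * fps)

    # -- noise, likelihood, pixel conversion -------------------------------
    xy_px = clean_cm / layout.pixel_scale
    if params.noise_sd_px > 0:
        xy_px = xy_px + rng.normal(0.0, params.noise_sd_px, xy_px.shape)
    likelihood = rng.uniform(0.98, 1.0, n_frames)
    dropout = rng.random(n_frames) < params.p_likelihood_dropout
    if dropout.any():
        likelihood[dropout] = rng.uniform(0.0, 0.7, int(dropout.sum()))
        xy_px[dropout] += rng.normal(0.0, 10.0 * params.noise_sd_px,
                                     (int(dropout.sum()), 2))

    track = KeypointTrack(x=xy_px[:, 0], y=xy_px[:, 1], likelihood=likelihood,
                          fps=fps, pixel_scale=layout.pixel_scale,
                          joint_name=DEFAULT_JOINT)
    placed = [tuple(p) for i, p in enumerate(place_pos)
              if not (artifact and i == drop_idx - 1)]
    truth = GroundTruth(
        segments=truth_segments,
        first_target_size="large" if want_large else "small",
        target_quadrants=[_quadrant_of(pick_pad, t) for t in targets],
        onset_ms=float(onset), artifact=artifact,
        picked_positions=[tuple(t) for t in targets],
        placed_positions=placed)
    return track, truth


# ---------------------------------------------------------------------------
# scene images


_BRICK_COLORS = [(205, 30, 30), (30, 60, 205), (235, 200, 25),
                 (30, 160, 45), (235, 120, 25), (150, 30, 180)]
BRICK_CM = (3.2, 1.6)


def _draw_bricks(draw: ImageDraw.ImageDraw, rects: list[tuple], colors: list) -> None:
    for rect, color in zip(rects, colors):
        draw.rectangle(rect, fill=color)


def _brick_rect(pos_cm, layout: WorkspaceLayout, swap: bool) -> tuple:
    w, h = (BRICK_CM[1], BRICK_CM[0]) if swap else BRICK_CM
    x, y = pos_cm
    s = layout.pixel_scale
    return ((x - w / 2) / s, (y - h / 2) / s, (x + w / 2) / s, (y + h / 2) / s)


def _rects_overlap(r1, r2) -> bool:
    return not (r1[2] <= r2[0] or r2[2] <= r1[0]
                or r1[3] <= r2[1] or r2[3] <= r1[1])


def generate_scene_pair(layout: WorkspaceLayout,
                        placed_positions: list, picked_positions: list,
                        seed: int, n_distractors: int = 12
                        ) -> tuple[Image.Image, Image.Image]:
    """Start/end scene photographs of one trial.

    The start image shows saturated colored bricks at all picking-pad
    positions (picked targets plus seeded distractors) on a gray
    background; the end image lacks the picked bricks and shows them at
    their placing-pad positions instead. Bit-identical under a fixed seed;
    overlapping bricks trigger a warning, not an error.
    """
    rng = np.random.default_rng(seed)
    pick_pad, place_pad = layout.picking_pad, layout.placing_pad
    for p in picked_positions:
        if not bool(pick_pad.contains(p[0], p[1])):
            raise ValueError(f"picked position {p} is not on the picking pad")
    for p in placed_positions:
        if not bool(place_pad.contains(p[0], p[1])):
            raise ValueError(f"placed position {p} is not on the placing pad")

    distractors = [_sample_in_rect(pick_pad, rng) for _ in range(n_distractors)]
    all_sources = [np.asarray(p, float) for p in picked_positions] + distractors
    swaps = rng.random(len(all_sources) + len(placed_positions)) < 0.5
    colors = [_BRICK_COLORS[i] for i in
              rng.integers(0, len(_BRICK_COLORS), len(all_sources))]

    pick_rects = [_brick_rect(p, layout, bool(swaps[i]))
                  for i, p in enumerate(all_sources)]
    placed_rects = [_brick_rect(p, layout, bool(swaps[len(all_sources) + i]))
                    for i, p in enumerate(placed_positions)]

    all_rects = pick_rects + placed_rects
    if any(_rects_overlap(all_rects[i], all_rects[j])
           for i in range(len(pick_rects)) for j in range(i + 1, len(pick_rects))):
        warnings.warn("overlapping bricks in the scene", stacklevel=2)

    size = layout.image_size
    gray = (110, 110, 110)
    start = Image.new("RGB", size, gray)
    end = Image.new("RGB", size, gray)
    n_picked = len(picked_positions)
    _draw_bricks(ImageDraw.Draw(start), pick_rects, colors)
    _draw_bricks(ImageDraw.Draw(end), pick_rects[n_picked:], colors[n_picked:])
    placed_colors = [colors[i % max(n_picked, 1)] for i in range(len(placed_rects))]
    if placed_rects:
        _draw_bricks(ImageDraw.Draw(end), placed_rects, placed_colors)
    return start, end


# ---------------------------------------------------------------------------
# cohorts


class Cohort:
    """Lazily generated synthetic dataset: schedules up front, trajectories
    and scenes regenerated deterministically per trial from stored seeds."""

    def __init__(self, params: CohortParams, layout: WorkspaceLayout,
                 metadata: pd.DataFrame):
        self.params = params
        self.layout = layout
        self.metadata = metadata

    def __len__(self) -> int:
        return len(self.metadata)

    def spec(self, i: int) -> TrialSpec:
        row = self.metadata.iloc[i]
        return TrialSpec(participant_id=row["participant"],
                         block=int(row["block"]),
                         trial_index=int(row["trial_index"]),
                         instruction=row["instruction"],
                         target_color=row["target_color"],
                         search_size=int(row["search_size"]),
                         audio_end_time_ms=float(row["audio_end_time_ms"]))

    def trial(self, i: int) -> tuple[TrialSpec, KeypointTrack, GroundTruth]:
        spec = self.spec(i)
        seed = int(self.metadata.iloc[i]["trial_seed"])
        track, truth = generate_trial_trajectory(spec, self.layout, self.params,
                                                 rng=seed)
        return spec, track, truth

    def iter_trials(self):
        for i in range(len(self)):
            yield self.trial(i)

    def scene_pair(self, i: int, downscale: int = 1
                   ) -> tuple[Image.Image, Image.Image]:
        """Scene pair for trial i (optionally at reduced resolution)."""
        _, _, truth = self.trial(i)
        layout = self.layout
        if downscale != 1:
            layout = WorkspaceLayout.default(
                pixel_scale=self.layout.pixel_scale * downscale,
                image_size=(self.layout.image_size[0] // downscale,
                            self.layout.image_size[1] // downscale))
        seed = int(self.metadata.iloc[i]["scene_seed"])
        return generate_scene_pair(layout, truth.placed_positions,
                                   truth.picked_positions, seed)


def generate_cohort(params: CohortParams,
                    layout: WorkspaceLayout | None = None) -> Cohort:
    """Schedules and per-trial seeds for a full cohort; deterministic in
    ``params.seed``. Trials are synthesized on demand (see :class:`Cohort`).
    """
    layout = layout or WorkspaceLayout.default()
    master = np.random.default_rng(params.seed)
    rows = []
    n_blocks = -(-params.trials_per_participant // 9)
    for p in range(params.n_participants):
        pid = f"P{p + 1:02d}"
        sched_seed = int(master.integers(0, 2**31))
        schedule = generate_schedule(sched_seed, n_blocks, pid)
        schedule = schedule[:params.trials_per_participant]
        for spec in schedule:
            rows.append({
                "participant": pid, "block": spec.block,
                "trial_index": spec.trial_index,
                "instruction": spec.instruction,
                "target_color": spec.target_color,
                "search_size": spec.search_size,
                "audio_end_time_ms": spec.audio_end_time_ms,
                "trial_seed": int(master.integers(0, 2**31)),
                "scene_seed": int(master.integers(0, 2**31)),
            })
    return Cohort(params, layout, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# on-disk dataset


def write_dataset(cohort: Cohort, outdir: str | Path, scenes: bool = False,
                  scene_downscale: int = 4, csv_tracks: bool = False) -> Path:
    """Write a cohort to disk: per-trial HDF5 tracks, JSON ground-truth
    sidecars, a metadata CSV, and optionally PNG scene pairs."""
    outdir = Path(outdir)
    (outdir / "tracks").mkdir(parents=True, exist_ok=True)
    if scenes:
        (outdir / "scenes").mkdir(exist_ok=True)
    cohort.metadata.to_csv(outdir / "metadata.csv", index=False)
    for i in range(len(cohort)):
        spec, track, truth = cohort.trial(i)
        stem = f"{spec.participant_id}_t{spec.trial_index:03d}"
        save_tracks_hdf5(outdir / "tracks" / f"{stem}.h5", track)
        if csv_tracks:
            save_track_csv(outdir / "tracks" / f"{stem}.csv", track)
        payload = asdict(truth)
        with open(outdir / "tracks" / f"{stem}.json", "w") as f:
            json.dump(payload, f, indent=1, default=float)
        if scenes:
            start, end = cohort.scene_pair(i, downscale=scene_downscale)
            start.save(outdir / "scenes" / f"{stem}_start.png")
            end.save(outdir / "scenes" / f"{stem}_end.png")
    return outdir
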