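"""Cohort-scale glue: segmentation -> dependent measures -> tidy tables.

Pure plumbing over the analysis modules, used by the CLI, the examples and
the acceptance checks: runs every trial of a (synthetic or loaded) cohort
through interpolation, segmentation and the dependent-variable extraction,
applies the participant-level quality criterion (exclude when more than a
third of trials were removed), and returns tidy per-segment and per-trial
tables ready for aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dependent_measures import movement_onset, summarize_segment
from .kinematics import KinematicSeries
from .pose_io import KeypointTrack, interpolate_low_confidence
from .segmentation import SegmentationConfig, qc_participant, segment_trial
from .synthetic_data import Cohort, GroundTruth, TrialSpec


@dataclass
class CohortResults:
    """Tidy outputs of a full cohort run.

    ``segments``: one row per retained movement segment with its dependent
    variables. ``trials``: one row per trial with pass/fail status of both
    analyses, onset, and (when ground truth is available) planted-effect
    bookkeeping. ``retention``: fractions of trials surviving each
    analysis, after participant exclusion. ``excluded``: participants
    removed by the one-third criterion, per analysis.
    """

    segments: pd.DataFrame
    trials: pd.DataFrame
    retention: dict
    excluded: dict


def process_trial(spec: TrialSpec, track: KeypointTrack,
                  config: SegmentationConfig,
                  truth: GroundTruth | None = None
                  ) -> tuple[list[dict], dict]:
    """Segment and measure one trial; returns (segment rows, trial row)."""
    track = interpolate_low_confidence(track)
    seg = segment_trial(track, spec.search_size, config,
                        trial_id=f"{spec.participant_id}_t{spec.trial_index:03d}")
    kin = KinematicSeries.from_track(track, order=config.smoothing_order,
                                     window=config.smoothing_window)
    base = {"participant": spec.participant_id, "block": spec.block,
            "trial_index": spec.trial_index, "instruction": spec.instruction,
            "target_color": spec.target_color, "search_size": spec.search_size}

    seg_rows: list[dict] = []
    trial_row = dict(base)
    trial_row.update({
        "reach_ok": seg.reach_ok, "transport_ok": seg.transport_ok,
        "reach_reason": "" if seg.reach_ok else seg.reach.reason,
        "transport_reason": "" if seg.transport_ok else seg.transport.reason,
        "onset_ms": np.nan, "onset_flagged": False,
    })
    if truth is not None:
        trial_row["first_target_large"] = truth.first_target_size == "large"
        trial_row["artifact"] = truth.artifact

    for phase in ("reach", "transport"):
        segments = getattr(seg, phase)
        if isinstance(segments, list):
            for m in segments:
                summary = summarize_segment(track, m, kin)
                row = dict(base)
                row.update({"phase": phase, "index": m.index,
                            "start_frame": m.start_frame,
                            "end_frame": m.end_frame,
                            "duration_ms": summary.duration_ms,
                            "avg_speed_cm_s": summary.avg_speed_cm_s,
                            "peak_speed_cm_s": summary.peak_speed_cm_s,
                            "deceleration_pct": summary.deceleration_pct,
                            "distance_cm": summary.distance_cm,
                            "path_ratio": summary.path_ratio})
                seg_rows.append(row)
    if seg.reach_ok and seg.reach:
        onset, flagged = movement_onset(seg.reach[0].start_frame,
                                        spec.audio_end_time_ms, fps=track.fps)
        trial_row["onset_ms"] = onset
        trial_row["onset_flagged"] = flagged
    return seg_rows, trial_row


def process_cohort(cohort: Cohort, config: SegmentationConfig | None = None
                   ) -> CohortResults:
    """Run every trial of a cohort through segmentation and measurement."""
    config = config or SegmentationConfig(layout=cohort.layout)
    all_segments: list[dict] = []
    all_trials: list[dict] = []
    for spec, track, truth in cohort.iter_trials():
        seg_rows, trial_row = process_trial(spec, track, config, truth)
        all_segments.extend(seg_rows)
        all_trials.append(trial_row)
    segments = pd.DataFrame(all_segments)
    trials = pd.DataFrame(all_trials)

    excluded: dict[str, list[str]] = {}
    retention: dict[str, float] = {}
    for phase, ok_col in (("reach", "reach_ok"), ("transport", "transport_ok")):
        verdicts = trials.groupby("participant")[ok_col].apply(
            lambda ok: qc_participant(list(ok)))
        excluded[phase] = sorted(verdicts.index[verdicts == "exclude"])
        kept = trials[~trials["participant"].isin(excluded[phase])]
        retention[phase] = float(kept[ok_col].mean()) if len(kept) else np.nan
        if not segments.empty:
            drop = segments["participant"].isin(excluded[phase]) & (
                segments["phase"] == phase)
            segments = segments[~drop]
    return CohortResults(segments=segments.reset_index(drop=True),
                         trials=trials, retention=retention, excluded=excluded)


def condition_means(segments: pd.DataFrame, dv: str, phase: str,
                    by: str = "instruction") -> pd.Series:
    """Grand mean of participant means of one dependent variable per condition."""
    sub = segments[segments["phase"] == phase]
    per_part = sub.groupby(["participant", by], observed=True)[dv].mean()
    return per_part.groupby(by, observed=True).mean()


def participant_condition_table(segments: pd.DataFrame, dv: str, phase: str,
                                by: str = "instruction") -> pd.DataFrame:
    """Participant x condition matrix of one dependent variable (paired tests)."""
    sub = segments[segments["phase"] == phase]
    per = sub.groupby(["participant", by], observed=True)[dv].mean().unstack(by)
    return per


def first_large_proportions(trials: pd.DataFrame,
                            by: str | None = "instruction") -> pd.DataFrame:
    """Per-participant proportion of trials whose first pick was a large item."""
    keys = ["participant"] + ([by] if by else [])
    out = trials.groupby(keys, observed=True)["first_target_large"].mean()
    return out.rename("p_large_first").reset_index()
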