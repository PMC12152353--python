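"""Extract the kinematic dependent variables for each movement of a trial.

Per movement: duration, average and peak smoothed speed, deceleration time
(share of the movement after peak speed), traveled distance, and the path
ratio (traveled path over straight-line distance; 1 = perfectly straight).
Per trial: movement onset, the latency from audio-instruction end to the
first reach start.
"""

import pickplace as pp
from pickplace.dependent_measures import movement_onset, summarize_segment
from pickplace.kinematics import KinematicSeries

layout = pp.WorkspaceLayout.default()
spec = pp.TrialSpec("P01", 1, 1, "pile", "red", 3, audio_end_time_ms=2000.0)
track, truth = pp.generate_trial_trajectory(spec, layout, pp.CohortParams(),
                                            rng=12)
track = pp.interpolate_low_confidence(track)
seg = pp.segment_trial(track, spec.search_size,
                       pp.SegmentationConfig(layout=layout), trial_id="demo")
kin = KinematicSeries.from_track(track)

print(f"{'movement':12s} {'dur ms':>7s} {'avg cm/s':>9s} {'peak cm/s':>10s} "
      f"{'decel %':>8s} {'dist cm':>8s} {'path ratio':>10s}")
for m in seg.combined():
    s = summarize_segment(track, m, kin)
    print(f"{m.phase + ' ' + str(m.index):12s} {s.duration_ms:7.0f} "
          f"{s.avg_speed_cm_s:9.1f} {s.peak_speed_cm_s:10.1f} "
          f"{s.deceleration_pct:8.1f} {s.distance_cm:8.1f} {s.path_ratio:10.2f}")

onset, flagged = movement_onset(seg.reach[0].start_frame,
                                spec.audio_end_time_ms, fps=track.fps)
print(f"\nmovement onset: {onset:.0f} ms after the audio instruction ended"
      + (" (moved early!)" if flagged else ""))
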