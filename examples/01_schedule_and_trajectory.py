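"""Generate a balanced trial schedule and one synthetic hand trajectory.

The schedule mirrors the study design: blocks of nine trials in which each
placing instruction (collect, sort, pile) and each target color occurs
three times, with search sizes (3-5 targets) balanced so that every
condition triple appears exactly three times over nine blocks.
"""

from collections import Counter

import pickplace as pp

schedule = pp.generate_schedule(seed=1, n_blocks=9)
print(f"schedule: {len(schedule)} trials in {schedule[-1].block} blocks")
triples = Counter((t.instruction, t.search_size, t.target_color)
                  for t in schedule)
print(f"distinct condition triples: {len(triples)}, "
      f"each occurring {set(triples.values())} times")

layout = pp.WorkspaceLayout.default()
params = pp.CohortParams(noise_sd_px=0.0, p_likelihood_dropout=0.0)
spec = schedule[0]
track, truth = pp.generate_trial_trajectory(spec, layout, params, rng=7)
print(f"\ntrial 1: {spec.instruction} {spec.search_size} {spec.target_color} "
      f"bricks -> {track.n_frames} frames at {track.fps:.0f} fps "
      f"({track.n_frames / track.fps:.1f} s)")
print("ground-truth movement legs (frames are 0-based):")
for seg in truth.segments:
    print(f"  {seg.phase:9s} {seg.start_frame:5d}-{seg.end_frame:5d}  "
          f"{seg.distance_cm:5.1f} cm, peak {seg.peak_speed_cm_s:5.1f} cm/s, "
          f"deceleration {100 * seg.decel_fraction:.1f}% of the leg")
# A reach crosses to the picking pad empty-handed; the transport carries the
# grasped brick to the placing pad. The deceleration percentage is the share
# of the movement spent after peak speed.
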