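"""Quantify where picking happened from a start/end scene image pair.

The two photographs of a trial differ exactly where bricks were taken or
put down. Binarizing in HSV (saturation and value > 50 marks colored
bricks on the gray pad), blurring, differencing, thresholding and
rescaling yields a 0-100% activation map; mean activation per pad quadrant
(1 far-left, 2 far-right, 3 near-left, 4 near-right) localizes the
activity.
"""

import pickplace as pp

layout = pp.WorkspaceLayout.default(pixel_scale=0.168, image_size=(360, 270))
quadrants = layout.picking_pad.quadrants()

# a trial that picked two bricks: one near-left, one far-right
picked = [quadrants[3].center, quadrants[2].center]
placed = [layout.placing_pad.center, layout.placing_pad.quadrants()[4].center]
start, end = pp.generate_scene_pair(layout, placed, picked, seed=0,
                                    n_distractors=6)

amap = pp.activation_map(start, end, "picking", layout=layout)
print("picking-pad quadrant mean activation (0-100%):")
for qid, mean in enumerate(amap.quadrant_means, start=1):
    label = {1: "far-left", 2: "far-right", 3: "near-left", 4: "near-right"}[qid]
    print(f"  quadrant {qid} ({label:10s}): {mean:6.2f}")
# The two picked quadrants light up; untouched quadrants stay near zero.

place_map = pp.activation_map(start, end, "placing", layout=layout)
print("\nplacing-pad quadrant mean activation (0-100%):")
print("  " + "  ".join(f"{m:6.2f}" for m in place_map.quadrant_means))
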