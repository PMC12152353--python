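# Methods

This note documents the models, parameter choices, and limitations behind
`pickplace`, in the order data flows through the package.

## Input model

Tracks are per-frame (x, y, likelihood) series for a single hand joint (by
default the metacarpophalangeal joint of the right index finger, the joint
best visible from a top-down camera), sampled at 200 fps with a spatial
calibration of 0.042 cm per pixel. Frames whose likelihood falls below 0.7
are treated as tracking dropouts: their positions are linearly
interpolated between the nearest confident frames. Runs of unconfident
frames at the very start or end of a track are filled with the nearest
confident value; the alternative, extrapolation, can inject spurious speed
into the segmentation signals, which is why it is avoided. Interpolation
is idempotent and never touches confident frames.

## Kinematic series

Speed is the frame-to-frame Euclidean displacement in pixels, attributed
to the later frame; index 0 repeats index 1's value so the speed series
has the same length as the track, which keeps the elementwise products in
the segmentation stage aligned. Speed is smoothed with a third-order
Savitzky–Golay filter, window 59 frames (295 ms), using polynomial edge
interpolation rather than wrap-around padding (wrap-around creates
artifacts exactly where movements begin). Acceleration is the
central-difference gradient of smoothed speed, smoothed again with the
same filter.

## Segmentation

Each trial is segmented twice, independently: a *reach* analysis (legs
toward the picking area, starting at the start key or placing area) and a
*transport* analysis (legs from the picking to the placing area). For each
analysis two per-frame objective functions are formed as products of
probability signals, one for starts and one for ends:

* **Position**: 1 inside the relevant region, Gaussian falloff
  (sd 3 cm) of the distance to the region boundary outside.
* **Inverted speed**: `1 − v/max(v)` over the trial; boundaries are speed
  minima.
* **Gates**: soft logistic gates (10 % slack; a hard-threshold switch is
  available) requiring tracking likelihood ≥ 0.9 at the frame, and — over
  a 70-frame horizon after a candidate start / before a candidate end —
  smoothed speed above 30 cm/s and |acceleration| above 0.5 cm/s per
  frame. The speed/acceleration gates encode that a real movement follows
  a start and precedes an end; they remove rest-period false alarms and
  low-amplitude artifacts. The printed speed-threshold unit in the source
  material ("cm/frame") is physically impossible at 200 fps on a 30-cm
  pad; this package interprets both thresholds per second (30 cm/s;
  0.5 cm/s per frame = 100 cm/s², versus ~600 cm/s² peak for a genuine
  leg), and both remain configurable.
* **Onset localization**: for every upward (downward) crossing of the
  30 cm/s threshold, the rest boundary is estimated by walking back
  (forward) to the nearest frame at or below a low onset level and
  extrapolating the remaining distance as `2·v/|dv/dt|` — exact when speed
  leaves rest quadratically, as it does for minimum-jerk-like profiles. A
  Gaussian of sd 9 frames centered on each estimate is the localization
  signal multiplied into the objective. The onset level sits
  `onset_speed_fraction` (default 1/6) of the speed threshold above the
  trial's own rest baseline (10th percentile of smoothed speed), which
  makes it robust to the positive speed floor that rectified tracking
  noise leaves during dwells. A constant 5-frame bias correction
  compensates the smoothing-induced softening of the velocity kink at
  rest; it was calibrated once on noise-free synthetic trials and is
  fixed in the defaults.

Starts are detected first from the unsuppressed start objective; ends are
then detected with the end objective re-weighted toward windows that
follow each provisional start; finally starts are re-detected under the
analogous suppression from the detected ends. The suppression weight is
multiplicative, `ε + (1−ε)·w(t)` with ε = 0.05, where w is 1 inside a
plausibility window `[s + 100 − 60, s + 100 + 200]` frames after each
start (mirrored before each end) with Gaussian edges of sd 9 frames. The
window brackets physiologically plausible movement durations (0.2–1.5 s)
around the nominal 0.5-s lag; a bare Gaussian of sd 9 at a fixed 100-frame
lag would only tolerate durations of 100 ± 27 frames, narrower than real
movement variability. This suppression is what removes the start-like
signature of the final placing dwell (low speed on the placing pad, with
the return-to-key movement following) — no reach ends after it, so it is
down-weighted to ε and falls below the peak threshold.

Peaks of the final objectives are local maxima kept greedily in descending
height with a minimum separation of 50 frames (250 ms) and a relative
height floor of 0.2 of the objective's maximum; equal-height conflicts
resolve to the earlier frame for determinism. An analysis is discarded
with reason `count-mismatch` unless the numbers of detected starts and
ends both equal the search size, and with `pairing-error` if the events do
not interleave. The two analyses pass or fail independently. A participant
is excluded from an analysis when strictly more than one third of their
trials were removed.

On noise-free synthetic cohorts, ≥ 99 % of boundaries are recovered within
5 frames (25 ms); with the default tracking noise, boundary jitter grows
to ~9 frames sd while the count check still retains essentially all clean
trials, and planted dropped-object artifacts (a transport merging into the
next reach with no on-pad speed minimum between them) are discarded at
their planted rate.

## Dependent variables

Per segment: duration = frame count × 5 ms; average and peak speed from
the smoothed series converted to cm/s (a raw-series peak is available
behind a flag); deceleration time = 100 × (frames after the first maximum
of smoothed speed) / (segment length − 1); distance = summed raw
per-frame steps × pixel scale; path ratio = traveled path / straight
start-to-end distance. Ties at the peak resolve to the first attaining
frame. Movement onset = first reach start time − audio-instruction end;
negative onsets (the hand moved early) are retained and flagged, not
clamped, since discarding them would bias the onset distribution.

## Activation maps

Scene start/end images are cropped to the pad, converted to HSV, and
binarized (saturation > 50 and value > 50 marks a colored brick against
the gray pad). Each mask is blurred (Gaussian, radius 5 px), the absolute
difference is taken, normalized to 0–255 by the per-image maximum (an
all-zero difference stays zero), blurred again, floored at 150 to remove
small lighting/jitter artifacts, blurred a final time, and rescaled to
0–100 %. The ordering — normalize, floor at the literal 150, rescale to a
percentage only at the end — keeps the published threshold meaningful; a
0–100 scale before flooring would make a threshold of 150 unreachable.
Quadrant means use the convention 1 = far-left, 2 = far-right,
3 = near-left, 4 = near-right ("near" meaning closer to the participant),
with the extra pixel row/column of odd-sized crops assigned to the
near/right quadrants. The map is symmetric in image order; per-image
normalization trades absolute comparability across trials for per-trial
contrast, matching how such heatmaps are aggregated and displayed.

## Statistics

Measures are aggregated by participant × instruction × search size
(arithmetic means, with trial counts retained). Descriptives use t-based
95 % confidence intervals. Extreme proportions (outside 0.3–0.7) are
variance-stabilized with arcsin √p before testing; chance (p = 0.5) maps
to 0.785.

The JZS Bayes factor places a Cauchy(0, r = 1/√2) prior on the
standardized effect size δ and integrates the noncentral-t likelihood over
it: `BF10 = ∫ f_nct(t; ν, δ√n) dC(δ) / f_t(t; ν)`. The substitution
δ = r·tan θ maps the integral to a finite interval, evaluated with
adaptive quadrature at relative tolerance 1e-8; one-sided variants
restrict the prior to a half-line and double its density. The
implementation agrees with an independent fine-grid quadrature of the
inverse-gamma g-mixture representation (and with an external reference
implementation) to well beyond four significant digits. The Bayesian
repeated-measures ANOVA with matched-model inclusion factors that
typically accompanies these tests in analysis software is deliberately out
of scope; the package exposes paired and one-sample Bayes factors only,
without multiplicity correction of the prior odds.

## Synthetic data generator

The generator emulates the study conditions: 24 participants × 81 trials
by default, in blocks of nine trials where each instruction and color
occurs three times and search sizes are balanced so every condition triple
occurs exactly three times across nine blocks.

Movement legs use a Beta-kernel speed profile,
`v(u) ∝ u^(a−1)(1−u)^(b−1)` with a + b = 6: at a = b = 3 this is exactly
the minimum-jerk speed profile `v ∝ u²(1−u)²`, and the peak location
(a−1)/4 — hence the deceleration fraction — is controlled smoothly by a
single parameter. Positions follow the regularized incomplete beta
function along the chord, plus a parabolic sideways bow (sagitta ~18 % of
leg length, randomly signed) that emulates the gentle curvature of natural
reaches and yields reach path ratios around 1.1. Planted effects:
transport deceleration fractions 0.510 / 0.535 / 0.547 for collect / sort
/ pile (reaches at 0.5), per-leg jitter sd 0.02; first-pick large-size
probabilities 0.844 / 0.819 / 0.888; picking-pad quadrant weights
(0.25, 0.15, 0.40, 0.20) biased toward the near-left quadrant. Legs are
paced at 46 cm/s average speed, bracketed by 300 ms dwells (±20 % jitter)
at every grasp and placing location — long enough to create clear speed
minima at the 59-frame smoothing scale; grasp dwell duration is not
reported for the original study, so this is a free parameter of the
generator. Movement onset is drawn from N(562.6, 120) ms, truncated at
150 ms. Tracking noise is white Gaussian pixel noise (sd 1 px) plus
likelihood dropouts (rate 0.01, likelihood uniform on [0, 0.7), positions
perturbed with 10× noise so interpolation is consequential). An optional
artifact rate merges a randomly chosen non-final transport with the
following reach via an off-pad drop point, reproducing the
dropped-object failure mode that the count check is designed to catch.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: between-participant variability in the
planted effects (every synthetic participant shares the same effect size,
so synthetic Bayes factors are systematically larger than real-data
ones), visual search and decision behavior (target order beyond the
first-pick size bias is random), obstacle avoidance, grasp kinematics and
finger articulation, correlated or non-Gaussian pose-estimation error,
and realistic object appearance in scenes (bricks are flat saturated
rectangles). Ground truth records both the planted and the realized
deceleration fraction of every leg; the sideways bow shifts the realized
speed peak slightly (fractions recover to ~1 frame only for straight
legs), and the realized value is what downstream recovery is measured
against.

## Problem sizes and determinism

All randomness flows from integer seeds through `numpy` generators; trial
synthesis is reproducible bit-for-bit from the cohort seed. The test
suite runs cohorts of 4 × 27 trials for stage-level checks and one
24-participant × 81-trial cohort (the full study scale) for end-to-end
planted-effect recovery, which completes in well under a minute; the
examples use 12 × 54 as a fast but statistically meaningful demonstration
size.
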