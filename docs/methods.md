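# Methods

## Pipeline model

The package treats video-based dry-eye screening as five composable stages:

1. **Slicing.** A recording (30 or 60 fps) is resampled onto the 200-ms
   analysis grid: for each tick t = 0, 0.2, 0.4, … s the nearest source
   frame is taken and relabeled with the tick time. The t = 0 tick is
   included; a source frame is reported at most once, so slicing at the
   source frame period is the identity. 0.2 s is the grid on which breakup
   times are read, hence the quantization unit of every TFBUT measurement.
2. **Quality screening.** Three exclusion rules, applied in order:
   *no_focus* (variance of the Laplacian of the green channel, computed
   after rescaling the short image side to 256 px so the score is
   resolution-independent, below 2·10⁻⁴), *no_cornea* (bright
   fluorescein-green pixels — green > 0.35 and exceeding red by 0.05 —
   cover less than 3% of the frame; this also catches blink closure), and
   *noise* (near-black pixels, green < 0.12, cover more than 1% of the
   estimated corneal disc — eyelashes and deep shadows). Excluded frames
   keep their timestamps: they leave gaps in a segment's timeline, never a
   time shift.
3. **Standardization.** The corneal circle is the minimal enclosing circle
   (Welzl's algorithm on convex-hull vertices) of the largest bright-green
   connected component. The square crop around it, padded by 10% of the
   radius, is resized bilinearly to 384×384 with intensities in [0, 1].
4. **Classification.** Each usable frame gets a confidence in [0, 1] that
   it shows tear-film breakup (≥ 1 dark spot on the cornea); label =
   positive at confidence ≥ 0.5 by default, with the threshold exposed for
   ROC sweeps.
5. **Timing and diagnosis.** Blinks are maximal runs of *no_cornea* frames;
   a segment opens at the first usable frame after a blink and ends at the
   next blink's onset. The segment breakup time is the delay from opening
   to the first breakup-positive usable frame (required to persist for k
   consecutive usable frames; k = 1 by default, matching the "first dry
   spot" reading). The per-eye TFBUT is the mean of the first three
   measured segments. The ADES rule then gives DED ⇔ TFBUT ≤ 5 s and
   OSDI > 13, with both boundaries sharp.

### Censoring

A segment with no positive frame before the next blink only bounds its
breakup time from below; the bound equals the segment length. If fewer than
three segments are measured, the available ones are averaged and the result
flagged; if none are, the reported value is the smallest censored bound,
marked `is_lower_bound`, and usable only on the "TFBUT > 5 s" side of the
diagnostic decision. This policy is a package choice — a deployed
frame-classifier has no defined output for a never-breaking eye — and is
deliberately conservative: an all-censored eye with bounds above 5 s can
never be called short.

## Classifiers

**Rule-based detector (default).** The corneal background is the median
green intensity inside the standardized disc mask (eroded by 8 px to avoid
limbus edge effects); pixels below 0.7 × background are dark; 8-connected
dark components of ≥ 25 px² are spots. Confidence is
1 − exp(−k · Σ area × mean_depth) with k = −ln(0.3)/25, calibrated so one
minimum-area spot at full depth scores 0.7. The score is monotone in spot
number, area and depth, and the per-pixel depth of detected spots is the
attribution map.

**Trainable surrogate.** A logistic regression over two feature groups per
frame: a 16×16 bilinear downsample of the ImageNet-normalized frame (coarse
appearance) and low percentiles (0.1–50) of the corneal-interior green
channel, absolute and relative to the corneal median — translation-invariant
evidence that a small dark region exists somewhere on the disc. Features are
z-scored on the training split. The development set splits 8:2 into train
and validation, grouped by source video so no video straddles the split;
training frames are additionally passed through the augmentation recipe
(horizontal flip p = 0.5, transpose p = 0.5; the deterministic channel
normalization is part of the featurizer and applied everywhere). The L2
strength is selected from {0.1, 1, 10} by validation log-loss. Training is
fully deterministic given the seed. Its attribution map is an occlusion
sweep: corneal pixels under a sliding patch are replaced by the median
corneal color and the confidence drop is credited to the patch through a
tent kernel, so the map peaks at the center of the strongest evidence
region; only patches touching the disc are swept.

The surrogate deliberately has ~10³ parameters, not 10⁸: it preserves the
pipeline contract (standardized frame → confidence) and the training
protocol (grouped split, augmentation, validation-based selection) at desk
scale, which is what the surrounding modules need from a classifier.

## The simulator

`simulate` generates what the pipeline assumes about a fluorescein exam:

- **Scene.** Dark periocular background; a fluorescein-green disc of radius
  0.35 × min(height, width), center jittered ±2% per seed; blink frames are
  full eyelid occlusion (skin tone, no disc) — an unambiguous eye-opening
  signal. Intensities are float32 in [0, 1] with additive Gaussian sensor
  noise (σ = 0.02) clipped to range.
- **Blinks.** n ≥ 3 closures (a valid exam requires at least three blinks),
  evenly spaced with ±10%-of-spacing seeded jitter, each 0.3 s long.
  Segments are the post-opening intervals; the pre-first-blink prefix
  carries no spots, because time-since-opening is undefined there and the
  exam protocol reads TFBUT only after the dye has been blinked into place.
- **Breakup.** One circular spot per segment at a seeded position within
  0.55 of the disc radius, appearing at the configured breakup time with
  initial radius 6 px and growing at 8 px/s, rendered as a multiplicative
  darkening of depth 0.6 with a 1.5-px soft edge. The nonzero initial
  radius makes "spot visible" coincide with the configured breakup time
  (a nucleating rupture is a finite dry patch, not a point), so per-frame
  labels turn positive exactly at onset and timing error is purely grid
  quantization. A frame is labeled positive iff a spot of radius ≥ 3 px is
  visible at its timestamp; labels are monotone within a segment.
- **Artifacts.** Each open-eye frame is independently spoiled with
  probability 0.2 — the exclusion rate such exams show in practice — half
  by defocus blur (σ scaled to resolution), half by a dark curved eyelash
  stroke across the disc.
- **Determinism.** Every random element derives from
  `(seed, stream, frame_index)`, so a video is bit-identical whether frames
  are materialized fully, sparsely (`generate_sliced` renders only the
  grid frames, 6× cheaper at 30 fps), or twice.

Default duration (56.1 s) and the resolution/fps envelope (720×1280 to
1080×1920 at 30/60 fps) follow the smartphone slit-lamp recording
conditions; the device envelope is checked only when
`enforce_device_profile=True` so that studies can run at reduced resolution.
The validation suites use 192×256 and 20–55 s recordings — geometry and
timing are resolution-independent, and this keeps 50-video suites at
minutes on one CPU.

**What the simulator does not emulate:** tear-film interference color,
irregular spot shapes and streak/area breakup patterns, partial blinks,
gaze shifts and specular reflexes, camera motion, and the intensity
statistics of real sensors. Passing the synthetic suites therefore
establishes the correctness of the pipeline logic (timing, censoring,
diagnosis, metrics) and the internal consistency of the imaging chain — not
clinical performance. Published clinical accuracies for this class of
pipeline come from private patient video and are out of reach of any
synthetic validation.

## Statistics

Proportion CIs (accuracy, sensitivity, specificity, PPV, NPV) are exact
binomial (Clopper–Pearson). AUC is the Mann–Whitney rank statistic with
midrank ties — identical, to numerical precision, to the trapezoid area
under the full threshold sweep — with a seeded stratified bootstrap CI
(2000 replicates, percentile). F1 uses a seeded item-level bootstrap.
Spearman CIs use the Fisher z transform with SE 1/√(n−3), a documented
approximation for rank correlations. Undefined metrics (empty denominators,
constant vectors) are flagged, never silently zeroed. The case-level ROC
sweeps the estimated TFBUT as the continuous score (negated, so shorter =
more disease-like) with OSDI held at its criterion.

OSDI scoring follows the instrument's standard formula,
100 · Σ answered / (4 · n_answered), tolerant of skipped items; a
precomputed score can be supplied instead.

## Validation design

- **Oracle routes.** Heavy pipeline checks run twice: with *oracle labels*
  (the simulator's own frame labels and quality statuses) to isolate the
  timing/diagnosis logic from imaging, and with the *detector* route
  (rendered frames through the full imaging chain). Oracle-route recovery
  uses artifact-free timelines, since an artifact landing on an opening or
  onset frame legitimately delays the reading by a tick or two — an
  irreducible property of gap-leaving exclusion, visible in the detector
  route's scatter instead.
- **Recovery.** Over 50 seeded videos with true TFBUT ~ U[1, 10] s,
  oracle-route error is bounded by one 0.2-s tick; the detector route at
  full defaults (noise and artifacts on) is checked by Spearman correlation
  ≥ 0.9 between true and estimated TFBUT.
- **Cohort.** 40 simulated eyes span the four quadrants of the diagnostic
  rule, with breakup times drawn from [2.0, 4.2] s (short) or [6.2, 8.0] s
  (stable) — clear of the 5-s boundary by more than the quantization bias —
  and OSDI responses drawn strictly on one side of 13. Oracle labels must
  separate perfectly; the imaging route must reach sensitivity and
  specificity ≥ 0.9.
- **Dual routes everywhere.** Spot detection is checked against a
  hand-coded threshold + flood-fill scan, AUC against exhaustive pair
  counting, the 2×2 metrics against formula oracles, Spearman against a
  hand-ranked Pearson computation.

## Known limitations

- The spot model is circular with linear growth; breakup-pattern
  classification (spot vs line vs area) is out of scope.
- Quality thresholds were calibrated on the simulator's renders; real video
  will need recalibration (all thresholds are exposed in `QualityParams`).
- A spot of depth ≥ ~0.9 approaches the *noise* occluder threshold and a
  very deep spot could be excluded as an artifact; default depth is 0.6.
- The censoring policy for never-breaking eyes is a convention; clinical
  protocols typically cap the exam instead (e.g., report "> 10 s").
- Interpolation of breakup onset between grid ticks is deliberately not
  done; all reported times lie on the 0.2-s grid divided by the number of
  averaged segments.
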