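# tearfilm

Tear-film breakup time (TFBUT) estimation and criteria-based dry eye
disease (DED) diagnosis from fluorescein slit-lamp video.

## The problem

Dry eye is commonly diagnosed from two findings: an unstable tear film and
subjective symptoms. Under the revised Asia Dry Eye Society (ADES) criteria,

```
DED  ⇔  TFBUT ≤ 5 s  AND  OSDI > 13
```

where the TFBUT is the time from an eye opening (after a blink) until the
first dry spot appears on the fluorescein-stained cornea, and the OSDI is a
12-item symptom questionnaire scored 0–100. In a video exam the TFBUT can be
read automatically: under cobalt-blue light the tear film fluoresces bright
green and ruptures appear as dark spots, so per-frame breakup classification
plus blink segmentation yields the measurement.

`tearfilm` implements that pipeline end to end, for anyone who wants to
study or prototype video-based DED screening without clinical data:

- **simulate** — a synthetic fluorescein-video generator with complete
  ground truth (blink schedule, per-frame labels, per-segment breakup
  times), standing in for the private clinical recordings such pipelines
  are trained on;
- **preprocess** — 200-ms frame slicing, quality screening (defocus, blink
  closure, eyelash/reflex occluders), corneal circle detection, and
  standardization to 384×384 crops;
- **classify** — per-frame breakup classification with a 0–1 confidence: an
  interpretable dark-spot detector (local-background thresholding +
  connected components, confidence `1 − exp(−k·Σ area×depth)`), an optional
  small trainable surrogate (regularized logistic regression on featurized
  frames, 8:2 grouped train/validation split), and an occlusion-based
  attribution heatmap;
- **tfbut** — blink segmentation and the three-measurement protocol: the
  reported TFBUT is the mean of the first three measured inter-blink
  segments, with censoring when no breakup occurs before the next blink;
- **diagnose** — OSDI scoring (`100 · Σ answered / (4 · n_answered)`) and
  the ADES rule with its exact boundary semantics (5.0 s inclusive, 13
  exclusive);
- **evaluate** — 2×2-table metrics (accuracy, F1, sensitivity, specificity,
  PPV, NPV), rank-statistic ROC/AUC, and Spearman correlation, each with
  95% confidence intervals (Clopper–Pearson, bootstrap, Fisher z).

## Worked example

```python
from tearfilm import simulate as sim
from tearfilm.pipeline import analyze_sequence, config_for_breakup_times

config = config_for_breakup_times((2.0, 3.0, 2.5), seed=7,
                                  resolution=(192, 256), artifact_rate=0.1)
seq, truth = sim.generate_sliced(config)          # frames on the 0.2-s grid
table, result = analyze_sequence(seq, already_sliced=True)
```

prints, via `examples/estimate_tfbut.py`:

```
segment 1: opened 5.8 s, breakup after 2.00 s (measured)
segment 2: opened 10.2 s, breakup after 3.20 s (measured)
segment 3: opened 15.4 s, breakup after 2.80 s (measured)
estimated TFBUT: 2.67 s (true: 2.50 s, grid resolution 0.2 s, 3 segments averaged)
```

Each segment's breakup time is read off the 200-ms grid (so individual
measurements quantize upward by at most one tick), and their mean is the
per-eye TFBUT. With an OSDI of 30 this eye is diagnosed DED
(`diagnose.diagnose(2.67, 30.0) → "DED"`).

The other scripts in `examples/` demonstrate one capability each:
simulation ground truth, quality screening, frame classification with
attribution, and cohort-level evaluation, which ends with:

```
sensitivity: 1.000 (95% CI 0.692-1.000, n=10)
specificity: 1.000 (95% CI 0.692-1.000, n=10)
AUC (TFBUT-swept ROC): 0.955 (95% CI 0.850-1.000)
Spearman r, estimated vs reference TFBUT: 0.968
```

A thin CLI mirrors the stages: `tearfilm simulate | analyze | train |
diagnose | evaluate` (see `tearfilm --help`).

## Scope

The simulator is a structural stand-in for clinical video, not a
photorealistic one, and the published clinical metrics of smartphone
slit-lamp studies (computed on private patient data) are not reproducible
here; see `docs/methods.md` for the model, parameter choices, and what the
synthetic validation does and does not establish.
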