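# Methods

## Problem setting

A fixed overhead camera watches a feed trough shared by a small herd.
An upstream detector (outside this package) emits, every few frames, one
box per visible animal face with a confidence, a score per known
identity, and a re-identification embedding. `feedtrack` converts that
stream into per-individual ethograms of two trough behaviors — *feeding*
(mouth in contact with the feed) and *picking* (head inside the trough
rail, mouth above the feed) — plus durations, activity rasters, and
evaluation metrics.

## Geometry model

The trough is an image-space polygon (a general simple polygon, so
slanted rails and perspective are representable; a horizontal band is
just a rectangle). The feed surface is a degree-k polynomial fitted by
ordinary least squares to manually marked highest-feed points; k
defaults to 3 — the pile's crest line under a wide lens is gently curved
— and is a config key. Image coordinates are raster convention (origin
top-left, y down), so "mouth touches the feed" is `y >= curve(x)`. The
tie `y == curve(x)` counts as feeding, because contact is the behavioral
trigger. The curve is treated as static per run; if the feed level
changes materially the points should be re-marked and the run split.

The mouth is proxied by the box's bottom-center (a face box's lowest
midpoint is where the muzzle is under a downward-looking camera); a
box-center mode is available for detectors that box the whole head.

## Tracker

DeepSORT-lineage design: per-track Kalman filter on
(cx, cy, a, h, and velocities), constant-velocity transition with dt = 1
tracker step (one *sampled* frame, not one video frame — the process
noise is sized accordingly).

* **Measurement noise** R is a preset constant diagonal (stds: 2 px on
  center/height, 0.05 on aspect ratio). The NSA rule scales it per
  detection: R̃ = (1 − c)·R. At c = 1 this is singular, so a floor
  ε_R·R with ε_R = 1e-6 is applied and logged; the posterior then pins
  to the measurement to ~1e-6 relative rather than bitwise.
* **Update form** is the Joseph-stabilized covariance update, which
  stays symmetric PSD even at the floored near-zero R̃.
* **Appearance** is a unit-norm EMA with momentum α = 0.9, renormalized
  after every update (keeping cosine costs in [0, 2]); an exact
  antipodal cancellation keeps the previous state and warns.
* **Association** minimizes C = λ·A_a + (1 − λ)·A_m, λ = 0.98, in one
  global pass via the Jonker-Volgenant solver; A_m is squared
  Mahalanobis in measurement space, gated at the chi-square 95% quantile
  for 4 dof (9.4877); matched pairs costing more than 0.7 are demoted.
  No matching cascade: a single global solve is simpler and loses
  nothing when tracks are few.
* **Lifecycle**: tracks confirm after n_init = 3 consecutive hits,
  tentative tracks die on their first miss, confirmed tracks die after
  max_age = 30 missed steps. All of these are config keys.
* **Identity** of a track is the argmax of accumulated per-detection
  identity-score votes (ties to the lowest label); this pools away
  per-detection score noise, including most confusable-pair errors.
* Camera-motion compensation is the identity transform: the cameras are
  rigidly mounted.

A 95% gate rejects a small tail of legitimate matches by construction;
each rejection spawns a short-lived tentative track. This costs ~1–2% of
matched frames in the default noisy scenario and is the main reason
reported mAP sits below the miss-rate ceiling.

## Ethogram

Detection runs every `stride` = 3 frames of `fps` = 25 video (config
keys; the duration formula uses whatever is configured). Events come
from confirmed tracks only (config-exposed): tentative tracks are
one-or-two-frame hypotheses whose identity vote is unstable. Durations:
t_b = d·stride/(fps·60) minutes per (identity, behavior). The raster
places one dot per 12-s window in which a behavior occurred, at the
window's first event.

## Synthetic scenarios

The generator emulates the monitored pen, not its pixels:

* **Schedules**: per individual, a semi-Markov alternation of rest /
  picking / feeding bouts with log-normal lengths (arithmetic means 15 /
  8 / 30 s, log-sd 0.6). Feeding bouts start only inside configured
  delivery windows (defaults: two windows spanning 5–35% and 55–90% of
  the run, the scaled analog of morning and evening feed delivery) and
  end at least 1 s before the window closes. Log-normal bouts give
  durations realistic autocorrelation; per-frame coin flips would not.
* **Trajectories**: acceleration-capped pursuit (1 px/frame², speed cap
  15 px/frame) of per-bout anchors at the individual's trough slot, plus
  a slow sinusoidal wander. Smoothness matters: it is what makes a
  constant-velocity filter the right model.
* **Labels** are derived by classifying each frame's mouth proxy against
  the generated geometry itself, so ground truth is consistent with the
  geometric behavior definition by construction.
* **Corruption**: boxes dropped i.i.d. (miss rate 0.05), Gaussian jitter
  (2 px) on all four box coordinates, embeddings as renormalized noisy
  identity prototypes (noise 0.05), confidence uniform on [0.5, 1],
  occlusion as visibility gaps (0.02 starts/s, mean 2 s). Identity
  scores are a sharpened softmax (temperature 0.05) of prototype
  similarities.
* **Confusable pairs**: prototype pairs placed at cosine 0.98. With
  noise σ, a pair at cosine s is misread at rate ≈ Φ(−√((1−s)/2)/σ) per
  detection; 0.98 with σ = 0.05 gives ~2%, the off-diagonal magnitude
  observed between visually similar herd-mates, and random 64-d
  prototypes leave all other pairs near-orthogonal (error rate ~0).

What the generator does **not** model: partial occlusion (boxes are
dropped, never truncated), detector-correlated errors (misses and jitter
are i.i.d.), appearance drift with pose or lighting, animals entering or
leaving the pen, and inter-animal interaction (displacement at the
trough appears only as whatever the schedules produce). Passing tests
therefore demonstrate the pipeline's correctness and its robustness to
these specific noise channels, not detector quality on real video.

## Problem sizes

The exact round-trip check uses a 10-minute, 6-individual uncorrupted
scenario (5,000 sampled frames); the noisy-recovery check uses 20 seeds
of the default 5-minute scenario. Five minutes is enough for every
individual to cycle through multiple bouts of all three states, which is
what the duration statistics need; the acceptance script completes in
about two minutes on one CPU at these sizes.

## Metrics

Standard definitions: accuracy (TP+TN)/(TP+TN+FP+FN), recall TP/(TP+FN),
precision TP/(TP+FP), F1 = 2TP/(2TP+FP+FN). A zero-denominator metric is
reported as undefined (None), never as 0. AP uses confidence-sorted
greedy matching (each truth box matchable once, IoU ≥ threshold
inclusive) and all-point interpolation by default — the modern
COCO-style convention; 11-point is a config switch. mAP@0.5:0.95 is the
mean over exactly the ten thresholds 0.50, 0.55, …, 0.95. For the
multi-class identity problem folded into binary counts, a
misclassification contributes FP to the predicted class and FN to the
true class, and TN counts (detection, non-involved class) pairs —
binary TP/TN language applied to a multi-class task is ambiguous, so
this operationalization is stated explicitly. Duration MAE is the mean
of |estimated − true| minutes over (identity, behavior) keys; both
tables are completed with explicit zero rows so a never-observed
behavior is an error, not a silently dropped key.

## Numerical choices and degenerate inputs

* Least-squares fits go through a Vandermonde `lstsq`; rank-deficient
  designs (e.g. duplicate x) and insufficient points raise rather than
  silently extrapolate. Curve evaluation outside the fitted x-span warns
  but returns (extrapolation is logged, not fatal).
* A singular innovation covariance is regularized by +1e-9·I with a
  warning.
* Assignment ties are resolved deterministically (row-major scan order);
  identical inputs produce byte-identical tracker output.
* All randomness in the generator flows from a single integer seed;
  derived seeds stay below 2³¹.

## Known limitations

* Identity labels must be a fixed set known to the detector; the tracker
  does not discover new individuals.
* The boundary curve is static per run; feed-level change within a run
  biases picking/feeding attribution.
* The 95% motion gate trades a small match loss for protection against
  identity theft by nearby detections; herds much denser than the
  modeled slot spacing would need a tuned gate or an appearance-only
  fallback.
* MOT-specific metrics (MOTA, IDF1) are not implemented; the evaluation
  suite covers detection-style metrics and duration error.
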