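# Methods

This note documents the model, the numerical choices and the design
decisions behind `brainstage`, and what the synthetic phantoms do and do
not demonstrate.

## Coordinate and gradient conventions

All grids are row-major, 0-based, indexed `(row, col)`; `row` grows
downward.  Gradients are central differences with replicate borders:
`g_x(r,c) = I(r,c+1) − I(r,c−1)` along columns and
`g_y(r,c) = I(r−1,c) − I(r+1,c)` measured *upward*, so `(g_x, g_y)` forms a
right-handed x-right/y-up frame and the orientation
`θ = atan2(g_y, g_x) mod 2π` behaves like a conventional mathematical
angle.  Note the central difference spans two pixels and is deliberately
not divided by 2: the Harris response and the descriptor are invariant to
a uniform gradient scale, so the factor is immaterial and omitting it
keeps ramp examples integer-valued.

## Preprocessing

* **Intensity normalisation** is a per-slice linear min–max stretch
  (histogram stretching taken literally).  It is monotone and idempotent.
  A percentile-clipped variant (e.g. 1st/99th) is available for robustness
  to hot pixels; the default is the plain stretch.  A constant slice
  degenerates to all zeros with a warning.
* **Smoothing** uses the discrete 2D Gaussian, default 5×5 with σ = 1 px,
  renormalised to unit sum so the DC level is preserved.  Convolution uses
  replicate padding: zero padding would fabricate strong artificial
  gradients at slice borders that the corner detector would latch onto.
* **Morphological cleanup** thresholds a support mask with Otsu's method
  (the goal — suppressing small objects and thin lines — does not fix a
  threshold, so a standard adaptive one is used), opens it with a 3×3
  structuring element, and zeroes pixels of foreground components smaller
  than `min_object_px` (default 64).  Surviving objects and the background
  are untouched.
* **Resampling** is trilinear; output voxel *i* sits at physical position
  `i × target_spacing`, so a linear ramp resamples exactly and spacing
  metadata stays truthful.
* **Slice selection** defaults to 9 axial slices centred on the volume
  midplane.  Which slices of a subject volume feed a 2D pipeline is a
  protocol choice with no canonical answer; 9 centred slices capture the
  ventricle-bearing mid-brain without entering apex/base regions where the
  phantom analogy breaks down.

## Harris interest points

The structure tensor accumulates `g_x²`, `g_x g_y`, `g_y²` under a 5×5
window — rectangular by default (matching the classical formulation with a
box window), Gaussian optional.  The response is
`R = det(M) − k·trace(M)²`.  Tunables, with defaults and rationale:

| parameter | default | why |
|---|---|---|
| `k` | 0.04 | the classical choice; any k < 0.25 keeps isotropic corners positive (R = λ²(1−4k)) |
| `rel_threshold` | 0.01·max R | scale-free: R grows with the fourth power of contrast, so an absolute threshold would be meaningless across slices |
| `nms_radius` | 5 px | suppresses duplicate responses on the same corner; below the 16 px patch pitch so nearby distinct structures survive |
| `max_points` | 200/slice | bounds descriptor count and runtime; responses are kept in descending order so the cap keeps the strongest structure |

Points within 8 px of a border are discarded rather than padded: a padded
patch would contain fabricated gradient structure.  Detection is a strict
3×3 local-maximum test followed by greedy radius suppression in descending
response order.

## The patch descriptor

Each 16×16 patch is divided into a 4×4 grid of 4×4-pixel cells; each cell
accumulates gradient magnitude into **8 orientation bins** over [0, 2π)
(45° per bin, bin centres at (k+0.5)·45°).  Votes are split linearly
between the two nearest bins with circular wrap ("soft binning"): with
fractional position `p = θ/45° − 0.5`, bin ⌊p⌋ mod 8 receives `1−frac` and
its successor `frac` of the pixel's magnitude.  This eliminates aliasing
at bin boundaries and conserves vote mass exactly (Σbins = Σμ), which the
tests assert to 1e-9.  Concatenation gives the **128-dim (4×4×8)**
descriptor.

**Block normalisation.**  The cell grid is tiled by four non-overlapping
2×2-cell blocks; each 32-value block is L2-normalised with an ε = 1e-6
guard, clipped at 0.2 and renormalised — the standard recipe for limiting
the influence of single dominant gradients.  Overlapping blocks would
inflate the descriptor beyond 128 values; the non-overlapping tiling is
the only 2×2 arrangement consistent with the fixed 128-dim layout.
Clipping can be disabled (`clip=None`), which makes the descriptor exactly
equivariant under 90° patch rotation (cells remapped, bins cyclically
shifted by 2) — a property the suite verifies to 1e-6.

**Orientation choice.**  Signed orientation over [0, 2π) is the default,
consistent with the 8-bin × 45° layout; an unsigned [0, π) mode is
available behind a flag for contrast-polarity-invariant applications.

**Binarized orientation-shift code.**  For a cell pair (c1, c2) the 8×8
bit matrix `b(k, ε) = [v_c1(k) ≥ v_c2((k+ε) mod 8)]` captures the rank
relationship of the two histograms under all cyclic shifts; ties give 1,
exactly as the ≥ comparison reads.  The default pairing is the 4-grid
right/down adjacency (24 pairs).  The code is an optional feature channel
(default **off**): when enabled, the mean per-pair bit count (24 values,
scaled to [0, 1]) is appended to the image feature vector.  It is kept
optional because its contribution to classification is an open empirical
question, whereas the 128/256-dim pipeline is the fixed core.

**Pooling.**  An image yields a variable number of patch descriptors; the
classifier needs a fixed width.  The default pooling concatenates the
element-wise mean and element-wise max over patches → **256 values**,
matching the MLP input width; mean-only (128) is selectable.  Pooling
columns are sorted before reduction so the result is bitwise independent
of patch order.  An image with no detected points yields a zero vector and
a warning.

## Classifier heads

All heads sit behind a `StandardScaler` fitted on training folds only.

* **SVM**: RBF kernel, C = 1, γ = 1/(n_features·Var X) (`scale`), wrapped
  in an explicit one-vs-rest ensemble of binary machines.  The solver is
  scikit-learn's; only the kernel configuration is this package's concern.
* **KNN**: k = 1, Euclidean metric.  For k > 1, majority-vote ties break
  to the label of the single nearest neighbour.
* **MLP** (`MLPDropoutClassifier`): 256 → 9 × 128 ReLU layers → 3-way
  softmax; inverted dropout 0.3 between hidden layers, L2 weight decay
  1e-3, Adam at lr 0.01, batch 32, ≤ 50 epochs, early stopping when the
  inner-validation loss (stratified 80:20 split) fails to improve for 10
  consecutive epochs, best weights restored.  The layer count and the
  optimisation hyperparameters are the protocol's; the **width (128) is a
  free choice** — nothing pins it, and a constant width is the simplest
  reproducible option.  The network is written on numpy with He
  initialisation so training is bit-reproducible under a fixed seed in
  single-threaded runs; the evaluation protocol's reproducibility test
  relies on this.

One documented discrepancy: the hidden-layer count is stated inconsistently
at 9 vs 10 in the protocol's own description; the hyper-tuned configuration
(9) wins and is the default.

**Augmentation** (rotate ±15°, mirror, shift ±10 %, scale 0.9–1.1, crop
90 %, Gaussian noise σ = 0.02; all seeded) is implemented but **off by
default**, because the protocol description is self-contradictory about
whether augmentation was used.  When enabled it applies to training folds
only; the CV harness asserts by provenance index that no augmented sample
derives from a test-fold original.

## Evaluation protocol

Stratified 5-fold CV, seeded: every sample is tested exactly once, and
per-fold class counts differ by at most 1 — both asserted at run time.
Per class, one-vs-rest TP/FP/TN/FN are read off the confusion matrix
(rows = actual, columns = predicted, order CN/MCI/AD) and

    accuracy = (TP+TN)/(TP+TN+FP+FN)   recall = TP/(TP+FN)
    precision = TP/(TP+FP)             f1 = 2TP/(2TP+FP+FN)
    specificity = TN/(TN+FP)

are macro-averaged.  Precision and specificity are distinct quantities and
both are reported (protocol texts in this area sometimes conflate the two
headings).  Zero denominators report 0 with a flag, never NaN.  Because
"average over folds" is ambiguous, headline numbers are emitted both as
the unweighted fold mean (default) and pooled over the summed confusion
matrix; with equal fold sizes the two coincide.  ROC curves are per-class
one-vs-rest threshold sweeps on out-of-fold scores with trapezoidal AUC.

## Synthetic phantoms

A phantom is a concentric structure — bright skull rim, mid-gray cortical
ring, brighter white-matter annulus, dark central ventricle — plus seeded
dark notches on the cortical ring ("sulcal widening") and additive
Gaussian noise, clipped to [0, 1].  Class presets encode the gross
radiological ordering CN → MCI → AD:

| preset | ventricle/brain radius | cortical thickness (px) | notches |
|---|---|---|---|
| CN  | 0.16 | 13 | 1 |
| MCI | 0.26 | 10 | 4 |
| AD  | 0.38 | 7  | 8 |

with noise σ = 0.03, image size 128, and per-image jitter (ventricle
±0.02, thickness ±1 px, centre ±2 px).  These effect sizes are chosen so
that the default study (150 images/class) is cleanly separable by the
descriptor pipeline — the end-to-end suite requires ≥ 0.90 mean 5-fold
accuracy for the MLP head and ≥ 0.85 for SVM/1-NN, with label-shuffled
controls at chance.  That is a **harness property, not a claim about
brains**: phantoms have no tissue texture, no acquisition physics, no
inter-subject anatomy, and their class differences are far larger relative
to noise than real MCI/CN differences.  Passing tests demonstrate that the
implementation is correct and leak-free, not that the method reaches any
particular accuracy on clinical data.  Conversely, raising `noise_sigma`
toward 0.3 degrades accuracy toward chance, which the harness uses to
confirm that no label information leaks through the protocol.

## Problem sizes

The default study is 150 phantoms per class (450 slices, ≤ 200 interest
points each); feature extraction takes a few seconds and the full
three-head cross-validation under a minute on one CPU, which makes the
end-to-end protocol cheap enough to run in every test cycle.  The
acceptance script uses the same sizes.

## Known limitations

* 2D only: interest points and descriptors operate per slice; a thin
  wrapper stacks phantom slices into NIfTI volumes to exercise IO, but no
  3D descriptor exists.
* No skull stripping or atlas registration; preprocessing stands in with
  masking and resampling only.
* Harris has no scale-space pyramid and no subpixel refinement.
* The MLP is plain dense layers; no convolutional or attention variants.
* Degenerate inputs (constant slices, empty detections) are handled with
  warnings and zero vectors rather than errors, so a pathological dataset
  can silently produce uninformative features — the warnings are the
  signal to check.
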