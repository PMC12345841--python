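# Methods

## Focused augmentation operator

The operator acts on the union of the pixel rectangles of all boxes whose
class id is in `target_classes` (default `{1}`, the fracture class).
Overlapping boxes are unioned first and processed once, so no pixel is
noised twice. Two stages run in order:

1. **Speckle noise** — `I' = clip(I + I·n, 0, 255)` with `n ~ N(0, σ²)`
   drawn once per pixel *position* and shared across channels, so a
   grayscale CT stored as RGB stays channel-consistent. `σ` defaults to
   0.10, i.e. roughly ±10 gray levels of spread at mid intensity — strong
   enough to emulate degraded acquisitions without destroying the lesion's
   contrast. `σ = 0` is the exact identity and `I = 0` is a fixed point
   (the noise is multiplicative).
2. **Gaussian smoothing** — convolution with a normalized
   `(2k+1)×(2k+1)` kernel, `w(i,j) ∝ exp(−(i²+j²)/2σ_b²)`, default 5×5
   (`k = 2`) with `σ_b = 1` px. Neighborhoods are read from the full
   noise-applied image, reflect-padded at the frame border, but written
   only inside the mask: the convolution sees real context just outside a
   box, which avoids seam artifacts at box edges.

Numerical conventions: all arithmetic in float64; each stage's output is
clipped to [0, 255] and rounded half-away-from-zero to 8-bit integers.
Box geometry is never modified, so the augmented copy's label text is
byte-identical to the original's.

`augment_training_set` appends `copies_per_image` augmented variants
(default 1, doubling the split) after the untouched originals. Each copy's
noise stream is seeded from a SHA-256 mix of (run seed, image id, copy
index), so outputs are independent of processing order and reproducible
across platforms. Validation and test splits are never augmented.

## Conventional baseline

The whole-image strategy applies, in a fixed order, optional rotation
(angle uniform in ±30°), optional brightness/contrast
(`clip(round(c·I + b))`, `c` in 0.8–1.2, `b` in ±25 gray levels), and an
optional whole-frame Gaussian blur (3×3, σ = 1), each firing with
probability 0.5. If all three draws decline, the rotation is forced so a
copy is never pixel-identical to its original. The magnitude defaults
beyond ±30° mirror common augmentation-library settings and are exposed in
`GlobalAugmentConfig`; they are configuration, not claims about any
specific study.

Rotation resamples bilinearly about the frame center (continuous-coordinate
convention: pixel index (x, y) sits at position (x+½, y+½)), fills
out-of-frame pixels with 0 (the dark CT background), and keeps the canvas
size. Boxes are transformed by rotating their four corners exactly and
taking the axis-aligned envelope, clipped to the frame; a box whose clipped
area falls below `min_box_visibility` (default 0.2) of its original area is
dropped. The envelope convention necessarily grows boxes under non-right
angles — rotating by θ then −θ returns a box that *contains* the original
rather than equals it, except at multiples of 90°.

## Dataset model and I/O

Labels use the normalized `class cx cy w h` text dialect: space-separated,
6-decimal fixed point, one box per line, UTF-8 with `\n`. Coordinates are
fractions of the frame; boxes leaking past [0, 1] by ≤ 1e−6 are clamped on
read (annotation-tool slop), larger violations are rejected.
Rasterization uses floor/ceil expansion on half-open 0-based pixel
intervals, so the continuous annotation is always covered with less than
one pixel of slack per side; a 1e−9 epsilon snaps products like
`0.2 × 100 = 20.000000000000004` back to the grid. Images are written as
PNG (lossless 8-bit round trip); JPEG is accepted read-only. Splitting
shuffles indices with a seeded generator and slices at
`round(n·f_train)` / `round(n·f_val)`, remainder to test — 2000 images at
(0.7, 0.2, 0.1) give exactly (1400, 400, 200).

## Evaluation engine

Matching is greedy per image, per class, per IoU threshold: detections in
descending confidence (ties by input order) claim their best-IoU unmatched
same-class ground truth if the IoU reaches the threshold; each ground truth
matches at most once. TP/FP flags are pooled across images before the PR
sweep. AP interpolates the precision envelope (max precision at recall ≥ r)
at the 101 recall points 0, 0.01, …, 1.00 — the convention of the COCO
family of tools; mAP@50–95 averages AP over IoU 0.50:0.05:0.95. Scalar
precision/recall are reported at the confidence maximizing F1 = 2PR/(P+R)
on the IoU-0.50 curve, ties toward higher confidence, matching how
detector toolchains report their headline P/R. Zero-denominator
conventions: a class with no predictions scores precision 0; a class
present in detections but absent from ground truth is excluded from macro
means. Percent change between runs is `100·(new − old)/old` rounded to two
decimals and rendered with an explicit ASCII sign (`+0.99%`).

## Phantom generator

`generate_phantom` draws a dark background (mean 18, Gaussian noise σ = 5
gray levels) crossed by `n_rib_bands` bright arcs (intensity 170–220,
thickness ≈ 1.8 % of the frame, parabolic sag) standing in for rib
cross-sections. With probability `fracture_prob_per_band` (default 0.3) a
band receives a gap darkened to 22–38 gray levels — the "fracture" — boxed
as class 1 with a 2-pixel margin so floor/ceil rasterization never truncates
the defect. One or two intact segments per band are boxed as class 0, so
non-fracture boxes outnumber fracture boxes in expectation, mirroring the
imbalance of clinical datasets. The default frame is 640 px to match the
study resolution; the test suite runs at 64–128 px, which exercises the
identical code paths at a fraction of the cost. The phantom is schematic by
design: it provides geometry, contrast and imbalance, not anatomy, noise
texture or scanner physics — passing tests demonstrate the correctness of
the operators and metrics, not clinical detection performance.

`simulate_detections` is a test double for a trained detector: each ground
truth is emitted with probability `1 − miss_rate`, optionally jittered in
center and size by `loc_jitter_std` (a fraction of the box extent), with a
confidence uniform in `tp_conf_range`; Poisson(`fp_per_image`) false boxes
are placed uniformly with confidences in `fp_conf_range`, kept strictly
below the TP range so PR curves are non-degenerate. This yields closed-form
expectations the tests check — e.g. pooled recall at confidence 0 is
Binomial, within 4·√(m(1−m)/n_gt) of `1 − miss_rate`.

## Problem sizes

The acceptance script and test suite use 64–128 px phantoms, 40–72-image
datasets (≈ 500–600 ground-truth boxes for the binomial checks), 200
random phantom/config pairs for the region-isolation sweep, and 1000
random scenes for the AP-oracle comparison; these sizes give tight
statistical checks while keeping a full run under ten seconds.

## Known limitations

- Phantoms are schematic; no Hounsfield-unit physics, 3-D volumes, or
  anatomical atlases.
- Rotated-box envelopes overestimate object extent at oblique angles, the
  standard trade-off for box-only annotations.
- The evaluator does not compute cross-class confusion matrices or
  area-stratified (small/medium/large) breakdowns, and reads detections
  from per-image text files only.
- Fixed-threshold (rather than max-F1) operating points can be obtained
  from `class_pr_curve` but are not the reported default.
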