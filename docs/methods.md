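# Methods

This note records the models and procedures the package implements, the
parameters that matter, the numerical conventions, and what the synthetic
phantoms can and cannot establish.

## Volumes and conventions

All volumes are `(slice, row, col)` arrays with slice 0 the most superior
trans-axial slice. CT voxels are Hounsfield units clipped to the 12-bit
range [−1024, 3071] (out-of-range values are clipped with a warning); PET
voxels are nonnegative activity values. PET-CT registration is taken as
given by hardware fusion; `pair_study` only resamples the PET slice axis
onto the CT grid (nearest by default, trilinear optional) and refuses pairs
whose physical extents disagree by more than 5% on any axis. SUV conversion
is not required anywhere: the classifier input is max-normalized, so only
relative uptake matters.

## Display windows and input normalization

A window (WL, WW) maps HU linearly onto [0, 1] between WL − WW/2 and
WL + WW/2 and clips outside — the standard radiology convention; only the
clip points are physically meaningful, the ramp is the natural choice
between them. The mediastinal window (40/400, bounds −160/+240) drives the
localizer's air threshold; the lung window (−400/1500) normalizes the CT
channel for the classifier. The air threshold is ≤ −160 (closed at the
bound); the choice of ≤ versus < moves the threshold by one HU and is
immaterial on phantoms. PET is divided by its volume maximum (an all-zero
volume stays zero, logged); per-slice normalization is available as a flag.

## Lung-field localization

Per slice: air mask (HU ≤ −160) → 8-connected components of the tissue
mask → hole-filling per component (so enclosed lungs and trachea count
toward the body block's area) → body selection → central band → air
fraction. The apex is the first slice, scanning superior → inferior, whose
air fraction reaches `air_fraction_threshold` (default 0.05 of the
body-block area).

Quantifications the procedure needs but that are stated only qualitatively:

* "overly small" contour: area < 10% of the image (`min_body_area_fraction`);
* "biased toward the edge": centroid closer than 10% of the image side to
  any border (`edge_margin_fraction`);
* ties in body selection: largest area wins, then the most central centroid;
* the 33% band is read as *body area enclosed in the band ≥ 33% of the
  body area*, grown symmetrically from the image center column one column
  per side at a time (the alternative reading — band area equal to 33% of
  body area — is not used);
* the air-fraction denominator is the body-block area of the current slice.

The crop is `crop_width_px` (default 256) square, centered on the body
centroid of the apex slice via `floor(x + 0.5)` rounding (chosen over
banker's rounding so integer translations of the body translate the crop
identically), shifted inward when it would exit the grid (logged). Slices
past the inferior end are padded with air (HU −1000 / activity 0) and the
count recorded, so short volumes remain usable. The PET crop samples the
same physical window bilinearly at `pet_crop_px` (default 64); when the
crop is aligned to the 4× grid this reduces to exact pixel extraction.
Because the band is anchored at the image center, a lateral shift of the
patient can move the detected apex by a slice; the crop still follows the
body centroid (tested).

The manual route cuts 16 slices centered on the annotated representative
slice (8 above, 7 below plus the slice itself — the split is a convention)
and a 64×64 CT window around the annotated center, with the matching 16×16
PET window resized to 64×64 bilinearly; at volume ends the slice window
shifts inward rather than padding, since an annotated nodule is interior
by definition.

## Synthetic thorax phantoms

A phantom is an elliptical tissue body (HU 40) in air (−1000), a tracheal
air column on the slices above the lungs, two lung ellipses at HU −850 —
below the −160 threshold, so parenchyma binarizes as air — that appear at
`lung_start_slice` and grow linearly (scale 0.5 + 0.04/slice) to full
size, and spherical nodules (default HU 20) with PET uptake spheres over a
uniform body background activity of 0.5, smoothed with a Gaussian (σ = 1
PET pixel). CT Gaussian noise (default σ = 10 HU) is reproducible from the
seed. Ground truth records both the first slice containing lung air and
the first slice whose in-band air fraction reaches 5%, the latter computed
by brute-force pixel counting independent of the localizer's contour
machinery; the localizer is scored against the latter.

Two profiles: `full` (512×512 in-plane, 120 slices, the scanner matrix)
and `fast` (128×128, 48 slices, all in-plane geometry scaled by 1/4) for
sweeps and training runs.

Cohorts are separable by construction: malignant cases draw nodule uptake
from N(6, 1) and in-plane diameter from N(30, 8) px (512-grid units),
benign from N(2, 0.8) and N(20, 6), truncated positive. Nodules are placed
where the lungs are at full size, pulled toward the lung center and shrunk
by 15% per retry if they would clip the lung boundary. The default class
fraction 79/112 reproduces a 79 : 33 split at n = 112. Per-case seeds
derive deterministically from the master seed.

What the phantoms do **not** emulate: anatomical texture, respiratory
motion, scanner PSF beyond the Gaussian, attenuation artifacts, multiple
nodules, mediastinal organs with physiological uptake. Passing tests show
the pipeline's geometry, statistics and learning machinery are correct on
controlled geometry — not that the classifier's accuracy transfers to
patients.

## Classifiers

Both networks are built on a small reverse-mode autodiff engine over NumPy
(`petlung.nn`): im2col 3D convolution, batch normalization, ReLU,
nearest-neighbour upsampling, global pooling, linear head, softmax
cross-entropy, Adam. Float32 throughout; parameters He-initialized from
the config seed, so identical configs give identical networks.

`HrNet3d`: a stride-1 stem, then one stage per branch. Every stage runs
`blocks_per_stage` residual blocks per active branch; branches all carry
`base_channels` channels at resolutions halved per branch. Multi-scale
fusion gives every branch the sum of all branches resampled to its
resolution — nearest-neighbour upsampling toward finer branches
(parameter-free), bias-free strided convolution toward coarser ones (so
fusion is linear in its inputs). The top branch passes through no stride or
pooling layer; its spatial shape is asserted at every stage. New branches
open with a stride-2 transition from the lowest existing branch. The head
pools each branch globally (max pooling by default, mean available),
concatenates, and maps linearly to two logits. `ResNet3d` is the baseline:
stride-2 residual stages with doubling widths, strictly decreasing spatial
size, global pooling, linear head.

Open design points resolved here: PET and CT enter as channels (early
fusion), with the PET crop upsampled to the CT grid — the minimal faithful
reading of joint PET-CT input; a CT-only mode drops the PET channel. 3D
convolution replaces 2D throughout. Class imbalance is handled by
inverse-frequency loss weights (flag-controlled). The number of branches
is capped by depth divisibility: input spatial sizes must divide by
2^(branches − 1).

Training profile: crops from either route are block-averaged to
(8, 16, 16) and trained with Adam 3e-3, batch 8, 15 epochs, base 8
channels, one block per stage — sized so stratified five-fold
cross-validation of a 112-case cohort runs on a single CPU in minutes.
The overfit sanity profile uses base 16 channels and Adam 5e-3 for 30
epochs. Held-out scores are the softmax malignancy probability; every case
is scored exactly once by the fold that did not train on it.

## Heatmaps, and a known limitation

`compute_heatmap` weights the channels of the last full-resolution feature
map by the malignant-class head weights, min-max normalizes to [0, 1], and
upsamples trilinearly to the input spatial shape (a constant map yields
zeros with a warning) — the class-activation-map construction.

On these phantoms the heatmap does **not** concentrate on the nodule, and
cannot: the body background activity is the same constant (0.5) in both
classes while uptake determines the class, so after max-normalization the
nodule peak is exactly 1.0 in every case and the normalized *background*
(0.5 / uptake) becomes a class proxy available at every body voxel. The
classifier learns this global shortcut — verified across head pooling
variants, capacities, CT-only and per-slice-normalization arms — and its
evidence map highlights the body at large rather than the nodule. This is
a shortcut-learning property of the synthetic task, not of the heatmap
code: on real FDG PET-CT the background is not a deterministic function of
the lesion's uptake. The corresponding localization check in the
acceptance suite fails for this reason and is retained as a documented
expectation gap rather than being weakened.

## Statistics

AUC is the Mann–Whitney probability with ties counted 1/2 (computed via
the rank statistic; verified against all-pairs enumeration). The CI and
the paired two-model comparison use the DeLong placement-value variance;
a numerically zero variance with zero AUC difference yields p = 1. The
paired test is checked against a 2000-replicate paired bootstrap and a
permutation-null calibration. Group comparisons from summary statistics
use the pooled-variance Student's t (df = n₁ + n₂ − 2; both-variances-zero
degenerates to p = 1 for equal means, p = 0 otherwise, by convention);
categorical tables use Pearson chi-square without continuity correction
(df = 1, undefined on zero marginals) and two-sided Fisher's exact test.
P-values are reported to four decimals. The positive class is malignant
throughout; the default operating threshold is 0.5.

Two cohort-table rows from the source data do not reproduce from their
printed inputs under these standard tests (the sex chi-square row and the
delayed-SUV t row, the latter matching a Welch rather than pooled test);
they are excluded from exact checks rather than matched by guessing the
variant used.

## Problem sizes

Default test and acceptance runs use the fast phantom profile (128×128,
48 slices), 112-case cohorts for cross-validation, 100-phantom sweeps for
apex recovery, 2000 bootstrap replicates and 400 permutation replicates —
sizes chosen so the full suite completes on a single CPU at desk scale
while keeping the stochastic checks' error bars tight.
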