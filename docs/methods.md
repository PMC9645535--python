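# Methods

This note records the models, the synthetic-data assumptions, the numerical
choices, and the limits of what the test suite demonstrates.

## Coordinate and label conventions

Arrays are indexed `(x, y, z)`: `x` transverse (left-right), `y`
anteroposterior (AP), `z` axial with the slice index growing superior →
inferior.  Voxel indices are 0-based, boxes half-open, and a voxel center's
world position is `origin + index · spacing` (mm).  Labels are 0 background,
1 lumen, 2 wall structure / intraluminal thrombus (WS/ILT).  Intensities
are "HU-like" floats: they sit on a Hounsfield-style scale (soft tissue
≈ 40, contrast-opacified blood ≈ 300) but carry no DICOM rescale metadata.

## The phantom

The aorta is modelled as a tube of circular cross-section swept along an
interpolating cubic spline through control points, with

* a piecewise-linear lumen-radius profile in normalized arc length:
  baseline tube radius (default 10 mm, i.e. a normal ~2 cm aorta) rising to
  a bulge peak (default 22 mm, a ~48 mm outer-diameter aneurysm — clearly
  beyond the 3 cm threshold that defines AAA) over a bulge segment;
* a constant wall thickness (default 2 mm), so the true outer diameter is
  `lumen + 2·wall`;
* an optional crescentic thrombus inside the bulge: an angular fraction
  (default 0.55) of the circumference is thickened inward to a fraction
  (default 0.55) of the local lumen radius at the crescent center, the
  depth tapering as a half-cosine both angularly and along the bulge — the
  crescent shape seen on axial slices of thrombosed aneurysms;
* flat end caps: points projecting beyond the first/last curve sample along
  the local tangent are background, so tube volume is exactly the profile
  integral (no spherical caps).

A voxel's class is decided by its center point against this analytic
geometry (no anti-aliasing); the *sub-voxel oracle* quantifies the
resulting discretisation error by subdividing every surface-band voxel
5×5×5 and classifying sub-centers exactly.  Mask-derived volumes agree with
the oracle to ≈ 0.2 % at 1.5 mm voxels, far inside the 3 % bound the
recovery suite asserts.

Closest points on the curve are found against a dense polyline resampling
(0.25 mm steps, keeping the arc-length error well under 0.1 mm); the
angular coordinate for the crescent uses rotation-minimizing frames
transported along the curve.

Two renditions are produced per spec: a contrast analogue (lumen ≈ 300,
1.25 mm slices) and a non-contrast analogue (lumen ≈ 45 against background
≈ 40 — within one noise SD, as on unenhanced CT — at 2.5 mm slices).  With
the default noise SD of 10, the contrast lumen-background separation is
26 SD and the non-contrast separation 0.5 SD; the generator's invariants
(contrast > 10·SD, non-contrast < 2·SD) are asserted in tests.  The label
grid is a deterministic function of the spec; the seed controls only noise
and cohort draws.

Cohorts draw tube radius U(8, 12) mm, bulge excess U(6, 14) mm, wall
U(1.5, 2.5) mm, thrombus fraction U(0.3, 0.8) and smooth lateral bends up
to 6 mm — clinically plausible ranges for surveillance-stage AAA.  What the
phantom does *not* emulate: branch vessels, calcification, streak/beam
artefacts, organs, patient-to-patient intensity variation.  Passing tests
therefore demonstrate that the pipeline's machinery is correct and that the
networks can learn cleanly separable anatomy; they say nothing about
accuracy on clinical CT.

## Preprocessing

Isotropic conversion (default 1 mm; linear for images, nearest for masks —
labels are never interpolated) and a 3.2× down-sampling of all axes for the
ROI stage (512 → 160 in-plane).  Non-integer output dimensions round
half-away-from-zero, which reproduces 512/3.2 = 160 exactly and is
deterministic.  Intensity normalization clips to a window (default −100 to
400, a standard soft-tissue window) and maps affinely to [0, 1]; the window
lives in config since real protocols vary.

## Augmentation

*Divergence warps* (offline, ratio 10:1 with originals retained, so 75
cases become 825 sets and a 50-case training fold 550): the displacement
field is a sum of Gaussian-windowed radial bumps
`u(x) = Σ mₖ (x−cₖ)/‖x−cₖ‖ exp(−‖x−cₖ‖²/2σₖ²)` applied by backward
warping — a minimal family of locally divergent/convergent deformations at
predefined locations.  Control points are sampled inside the dilated
foreground so deformations target the vessel; defaults are 3 points,
magnitudes ±5 mm, σ 15 mm.  *Online affines*: rotation U(0°, 15°) about a
random axis, isotropic scale U(0.7, 1.3), translation within ±10 % of the
field of view (a conventional choice; the image border is edge-padded).
Images are interpolated linearly, masks nearest, with the identical
transform; every augmentation is a pure function of (input, parameters,
seed) and is recorded in per-case provenance.

## Network and training

A 3D encoder-decoder with `depth` resolution levels: each encoder level is
(conv3 → instance norm → ReLU) ×2 followed by 2×2×2 max-pooling; the
decoder mirrors it with nearest-neighbour ×2 upsampling and concatenation;
a 1×1×1 head produces per-class scores, softmax-normalized per voxel
(classes are mutually exclusive, so binarization is per-voxel argmax, not a
0.5 threshold per channel).

Attention gates sit on the skip connections: the skip features are
average-pooled to the gating resolution, both inputs are projected by 1³
convolutions to an intermediate width (half the skip channels), added,
rectified, projected to a single coefficient channel, squashed by a
sigmoid, and the upsampled coefficients multiply the skip features.
Coefficients are per-voxel by default, with a per-voxel-per-channel switch
(`attention_per_channel`) for the multidimensional variant; gates verify
the identity (α→1) and suppression (α→0) limits exactly.  With attention
disabled the architecture is the generic 3D U-Net baseline.

The loss is soft multi-class DICE over non-background classes with
ε = 1e-5; two empty sets have DICE 1 by convention (loss contribution 0).
On hard one-hot inputs it equals `1 − mean DICE` of the evaluation metric,
cross-checked in tests.

The layer stack is implemented directly in NumPy with explicit
forward/backward passes — convolutions as one BLAS matrix product per
kernel offset on shifted views — and verified against finite differences.
Optimisation is Adam (lr 1e-3).  Training is patch-based: each step draws a
patch centered with jitter on a random foreground voxel; online affine
augmentation is applied to the whole pair before extraction.  Desk-scale
defaults — depth 3, 8 base channels, 32³ patches, ≤ 30 epochs on eight 64³
phantoms — train in ~3 minutes on one CPU and reach held-out combined-aorta
DICE ≈ 0.93–0.95; training stops early when the epoch loss falls below
0.02.  Channel counts, learning rate and epochs are free parameters held in
`ModelConfig`.  Runs are reproducible from (data seed, model seed); losses
are bitwise-stable across repeats on the same BLAS.

Inference is sliding-window with 50 % overlap and probability averaging;
volumes smaller than the patch are symmetrically padded and the padding
removed afterwards.

## Cascade

Stage 1 predicts aorta-vs-background on the down-sampled volume.  The
foreground probability is thresholded at 0.5, components smaller than
1 cm³ are discarded, and the largest component is kept.  For contrast scans
the thoracic/abdominal split is geometric: scanning axial slices from
superior, the thoracic box ends at the most inferior slice with ≥ 2
in-plane components (ascending + descending aorta, i.e. below the arch)
plus a 20 mm margin; the abdominal box runs from that slice minus the
margin to the inferior extent.  A contrast scan without arch geometry
degrades to a single abdominal box, logged.  Boxes map to high-resolution
indices by the down-sampling factor, padded by 10 voxels per side to absorb
localisation error.  Stage 2 crops, segments each box, and stitches:
overlaps resolve per voxel by maximum class probability; voxels outside all
boxes stay background.

## Morphometry

* **Axial calipers**: AP diameter = extent of the largest in-plane
  component along the fixed y-axis (transverse along x), as
  `(index span + 1) · spacing` — the pixel-footprint caliper, so a single
  pixel measures one spacing unit.  This matches clinical axial-caliper
  practice.  In oblique planes orthogonal to the centerline, anatomical
  axes are undefined, so the diameter is the maximal Feret diameter
  (largest pairwise distance, computed on the convex hull) of the component
  containing the centerline point.  Both definitions are deliberate and
  documented; extent is the primary axial measure.
* **Three-slice protocol**: AP + transverse at the max-AP slice and at the
  nearest slices ±10 mm; a span exceeding the mask is truncated and
  flagged.
* **Centerlines**: topology-preserving 3D thinning (Lee's algorithm via
  scikit-image) of the class region (largest component if several, logged),
  then the longest geodesic path through the 26-connected skeleton graph
  (double-sweep Dijkstra with physical edge lengths), ordered superior →
  inferior with a lexicographic tie-break, in world mm.  On phantoms the
  recovered line stays within ~1 voxel (mean) of the generating spline;
  skeletons erode a few voxels at the vessel ends, which is why measured
  profiles are compared to the oracle via nearest-truth-point arc lookup
  rather than raw arc offsets.
* **Centerline agreement**: mean closest-point distance symmetrized by
  averaging both directions (the directed variants are available), and the
  symmetric Hausdorff distance, which upper-bounds it — asserted on every
  tested pair.
* **Diameter profiles**: tangent from finite differences after a 5-point
  moving average with odd-reflection padding (endpoints stay fixed); the
  binary mask is resampled (nearest) on a 2D grid in the orthogonal plane
  at the finest in-plane spacing; default sampling step 1–4 mm.  Planes
  where the centerline point falls outside the class are marked missing and
  dropped.  Profile comparison interpolates the second profile onto the
  first's positions over the overlapping arc range; RMSE plus mean
  percentage difference `mean(|d₁−d₂| / mean(d₁,d₂))·100`.
* **Straightened views**: the same orthogonal-plane resampling (linear)
  stacked along arc length; output z is arc length.
* **Agreement statistics**: bias = mean difference, 95 % CI
  `bias ± 1.96·SD/√n`, limits of agreement `bias ± 1.96·SD`, Spearman rank
  correlation, ICC(2,1) — two-way random effects, absolute agreement,
  single rater, via pingouin and cross-checked against a hand ANOVA — and
  %CV as the RMS over pairs of (pair SD / pair mean)·100, with zero-mean
  pairs excluded and logged.  The ICC variant and the %CV definition are
  stated because several incompatible conventions circulate.

## Cross-validation bookkeeping

`make_folds` partitions a cohort into k disjoint test sets (3 folds of 25
from 75 cases, training on the remaining 50).  Test cases are always
pre-augmentation originals; augmented copies inherit their parent's fold,
so a 50-case fold trains on 550 sets at 10:1 — enforced by the splitter,
never recomputed by hand.

## Problem sizes and determinism

The shipped tests and `scripts/acceptance.py` run at desk scale: 64³
phantoms at 1.5 mm, 20-phantom recovery cohorts, 8-phantom training runs,
depth-3/8-channel networks.  These sizes were chosen so the whole
validation runs in minutes on a single CPU while every tolerance asserted
(voxel-level diameter recovery, 3 % volumes, 1.5-voxel centerlines,
DICE ≥ 0.8 learning smoke) is already meaningful at that resolution.  All
randomness flows through explicit integer seeds; identical seeds give
bit-identical phantoms, augmentations and training histories.

## Known limitations

* Phantom realism as above: clean two-tissue contrast, no branches or
  artefacts; learned models will not transfer to clinical CT without
  retraining.
* The thoracic/abdominal split rule is geometric and assumes the arch is
  the only place with two in-plane aortic cross-sections; unusual
  anatomies (or masks with spurious components surviving the 1 cm³ filter)
  would mis-split.
* Thinning-based centerlines are voxel-resolution limited and erode at the
  ends; sub-voxel centerline accuracy would need model-based refinement.
* The NumPy training stack is single-sample and CPU-bound; it is meant for
  desk-scale validation, not clinical-scale training.
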