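# Methods

## Model and assumptions

The package estimates a single global 3D similarity transform — uniform
scale `s > 0`, proper rotation `R` (det +1), translation `T` — mapping an
atlas head onto a subject head, from their exterior surfaces alone.  The
underlying assumptions:

* the head/face is effectively rigid over the acquisition (no breathing
  or cardiac deformation; soft-tissue change is treated as noise);
* body and air separate cleanly by intensity in both CT and MR, so the
  exterior surface is recoverable slice-by-slice without modality-specific
  modelling;
* inter-individual head-size difference is well approximated by one
  uniform scale factor (no anisotropic or deformable component);
* the acquisitions are approximately axial: the facial feature step
  projects along the anterior–posterior axis, which presumes the face is
  visible in a face-on depth map.  Large oblique acquisitions are out of
  model.

Anything deformable (lesion growth, postoperative change) is *not*
corrected — the method's purpose is localization, not segmentation, and
a deformed structure is expected to be indicated approximately.

## Coordinate conventions

Arrays are indexed `(slice, row, col)` = `(z, y, x)`, 0-based; physical
coordinates are `(x, y, z)` in millimetres; voxel `(i, j, k)` has centre
`origin + (k·dx, j·dy, i·dz)`.  Transforms use the column-vector
convention: composition "apply A, then B" is the matrix product `B·A`.
With the worked-example step matrices this order reproduces the
published final matrix (row-1 entries agree to ~1e-3, the precision of
4-decimal printing), which fixes the convention unambiguously.

## Contour extraction

Per slice: binarize (CT: −300 HU; otherwise per-slice Otsu) → fill
border-connected background's complement (4-connected background /
8-connected foreground) → pad the canvas by `opening_radius + 1` →
binary opening with a disk (default radius 3 px) → crop → keep the
largest 8-connected component → subtract the disk erosion (default
radius 1 px), leaving a boundary ring whose thickness equals the erosion
radius.  With erosion radius 1 the ring is exactly the set of body
pixels with a background 4-neighbour, which is the oracle the tests
check.  The opening removes headrest-type clutter smaller than the
structuring element, at the cost of rounding convex corners and erasing
structures thinner than the element (the first nose-tip slices of the
phantom, for instance) — acceptable because registration consumes
thousands of ring points.

An empty post-opening slice yields an empty ring plus a warning, not an
error: clinical stacks legitimately begin or end in air.

## Depth maps and feature sampling

The surface cloud is orthographically binned into a `cell_size` grid
(default 1 mm) over the projection plane; each cell keeps the point
nearest the viewer.  Because the per-slice rings are thin, a column may
contain no near-surface point and would otherwise show the far side of
the head; cells deviating from their 3×3 neighbourhood median by more
than `4·cell_size` are therefore discarded.  This despeckling is what
makes the nose-tip detector and the face patches robust to
half-voxel surface noise (without it a single show-through cell could
throw the registration by tens of degrees).

The eye–nose rectangle is sampled on a uniform `rows × cols` node grid
(default 4×7 = 28 points).  Each node adopts the depth of its nearest
occupied cell within a capture radius (default `2·cell_size`); nodes
with no surface in reach are dropped.  Nodes are enumerated
viewer-consistently (columns along the viewer's horizontal), so node
`(r, c)` on the atlas face and on the subject face correspond
anatomically regardless of which direction each head faces — this is
what lets a back-to-front subject be registered without a GUI.

The nose tip — the nearest-to-viewer cell of a 3×3-median-filtered depth
map — anchors the default feature rectangle (±24 mm horizontally, −8 to
+26 mm vertically) and the circular band.  It is a convenience standing
in for the interactive rectangle/trackbar selection, not a
facial-landmark detector.

## Registration

`fit_rigid` implements both the Horn unit-quaternion eigen-solution and
SVD Procrustes with the det-correction reflection guard; the two agree
to machine precision and the tests cross-check them.  `fit_similarity`
is the Umeyama closed form with one global scale.  Degenerate (collinear
or zero-variance) configurations raise.

ICP alternates nearest-neighbour correspondence (cKDTree; exact ties to
the lowest target index) with a closed-form refit from the *original*
moving set, which makes the RMS objective provably non-increasing; the
loop stops when the RMS improves by less than `tol` (default 1e-4 mm) or
after `max_iter` (default 100) rounds.  No trimming or outlier rejection
is applied.

The two-step orchestration (`TSPRRegistration.fit`):

1. *Orientation.*  The node-paired 28-point grids give a closed-form
   rigid starting estimate; rigid ICP between the dense face patches
   (every occupied depth cell inside the rectangles) refines it into
   `M1`.  The dense patch is used rather than 28-vs-28 ICP because
   sparse-to-sparse correspondences form their own coarse fixed points
   that retain several degrees of in-plane roll; the grid remains the
   initializer and the API for choosing the region.
2. *Scale.*  The atlas band is pushed through the accumulated transform
   and registered to the subject band with similarity ICP; the step may
   repeat progressively (`n_scale_steps`, capped at 5 — repeating the
   orientation step instead risks over-registration).  The final
   transform is the exact composition of all steps.

Two crop-margin rules prevent a systematic bias discovered during
development: when the moving region maps slightly outside the target
region's crop, its edge points latch onto the target's cut edge and drag
the fit (several degrees of rotation at worst).  The target face patch
is therefore expanded by `patch_margin` (default 10 mm) and the target
band by `band_margin` (default 15 mm ≈ band height × 10% scale slack +
half head width × sin 10° tilt) relative to the moving selections.  The
two bands should cover approximately the same anatomy; a point-count
ratio above 3:1 triggers a warning.

## ROI mapping and recall

Labels are pulled into the subject grid: each subject voxel centre is
sent through the inverse transform and looks up the nearest atlas voxel
(pull resampling leaves no holes at scale ≠ 1, unlike pushing atlas
voxels forward).  Recall is computed per axial slice as intersection
area over reference area, in voxel counts (numerator and denominator
share the grid, so units cancel); slices with empty reference are
skipped.  The summary reports max, min, median (mean of the middle two
for even n), mean, and the normal-approximation 95% CI with the sample
(n−1) standard deviation and fixed z = 1.96; no CI for n < 2.  The
published summary table for the six clinical series is reproduced by
these definitions exactly at 4 decimals for the rows that are internally
consistent with their per-slice values; two printed averages and one
median are not derivable from their own per-slice tables and are
excluded from the checks.

## The synthetic phantom

`generate_atlas` renders an analytic head: ellipsoid cranium (semi-axes
42 × 43 × 40 mm in x/y/z), a conical nose protruding 18 mm beyond the
ellipsoid on the anterior midline (base radius 12 mm), and two
spherical eye-socket depressions (radius 10 mm, carved at the anterior
surface ±17 mm laterally, 15 mm above nose level), on a 128×128×96 mm
grid at 1 mm isotropic spacing — small enough for sub-minute end-to-end
runs.  Foreground intensity is 100 on a 0 background, so threshold 50
recovers the solid exactly at zero noise.  The facial relief is
deliberately strong (real faces have far more relief than a smooth
ellipsoid): with subtler features, roll about the viewing axis is
unobservable at 1 mm voxelization and no surface-based method could
recover it.

Embedded ROI structures mirror clinical targets by role: a midline
sphere ("pituitary", r = 5 mm), paired tubes ("optic nerves", r =
2.5 mm), and a lateral slab ("temporalis", 10×20×14 mm).

`derive_subject` applies a known similarity transform about the head
centre (intrinsic rotations x→y→z, degrees), resamples onto a possibly
different grid (linear for intensity, nearest for labels), then applies
local defects in subject space (`missing_region` zeroes a sphere —
missing teeth; `bulge` adds one — post-traumatic protrusion) and
Gaussian noise last, so the stored ground-truth transform is exact for
the defect-free anatomy.  All randomness is confined to the noise
fields under integer seeds.

**Study conditions for the recovery suite:** scale U(0.90, 1.10), tilt
about x and y U(−10°, 10°), yaw U(−30°, 30°), in-plane translation
U(−30, 30) mm, axial translation U(−15, 15) mm, zero noise; the subject
grid is 160×160×128 voxels with origin (−16, −16, −16) mm so the
scanned field of view always contains the whole head.  Under these
conditions the pipeline recovers rotation within 2° (typically ≤0.5°),
scale within 2% (typically ≤0.4%) and the head-centre position within
2 voxels (typically ≤0.5 mm); with 0.5-voxel Gaussian jitter on every
surface point, rotation stays within 5° (typically ≤1°).  The rotation
error is the geodesic angle of `R_est·R_trueᵀ`; the translation error
is the displacement of the head centre, because the raw translation
column difference conflates rotation error through the origin lever
arm.

What the phantom does *not* emulate — and hence what passing tests do
not certify: real cranial shape variation, soft-tissue intensity
structure, modality-specific artefacts (beam hardening, MR bias
fields), non-axial acquisitions, and truncated fields of view that cut
into the facial band.  Surface truncation in particular degrades the
scale step (the moving band loses its counterpart) and is the main
practical failure mode to watch on real data.

## Numerical choices

* Resampling: output grids span first to last input voxel centre
  (closed extent, `floor(extent/spacing)+1` samples); linear for
  intensities, nearest for labels; no extrapolation.
* Correspondence ties break to the lowest target index; the pipeline is
  otherwise deterministic for fixed inputs.
* `decompose_similarity` recovers `s = det(A)^(1/3)` and checks
  orthonormality within 1e-3 by default, loose enough for matrices
  printed at 4 decimals; exact transforms satisfy it to 1e-9.
* ICP degeneracies (all points matched to one target) propagate as
  errors from the fit layer rather than being silently absorbed.

## Known limitations

Single global similarity only — no deformable refinement; sagittal or
coronal primary acquisitions are unsupported; the automatic nose-tip
anchoring presumes the face is present in the scan; recall on
structures one or two voxels wide on a slice can drop to zero under
sub-voxel misalignment (nearest-neighbour mapping), which is visible on
the phantom's pituitary end slices.
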