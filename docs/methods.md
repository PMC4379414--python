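# Methods

This note documents the models and procedures implemented in `wristseg`, the
choices made where the design was genuinely open, and what the synthetic
phantom does and does not establish about behaviour on real data.

## Segmentation model

The method treats wrist-bone segmentation as marker-driven watershed
flooding.  The image is converted to a relief: a Gaussian blur with one-voxel
half-size (3-tap kernel per axis, σ = 0.5 voxel — the smallest smoothing
consistent with that support), per-axis Prewitt derivatives, Euclidean norm.
Cortical bone is dark between bright marrow and bright soft tissue, so each
bone contributes a closed double ridge; flooding from one marker per bone
plus one background marker assigns every voxel to the basin whose flood
reaches it first.  Since only the *ordering* of relief values matters, the
result is invariant under monotone rescaling of the relief, and the Prewitt
normalization is irrelevant.

### Flooding rules

The watershed is a priority-queue flood over face neighbours (6-neighbourhood,
consistent with the unit-diamond morphology used everywhere): pop the
frontier voxel with the lexicographically smallest `(relief value, insertion
age)`, label its unlabelled neighbours, push them.  Labelling at push time
makes the flood breadth-first across flat zones; the insertion-age tie-break
makes it fully deterministic.  Watershed lines are *not* left unlabelled by
default — every voxel joins the first-arriving basin, because the downstream
cortical dilation and the voxel-complete metrics need total labelings; an
`emit_lines` flag demotes contested voxels to label 0 instead.  The kernel is
numba-compiled; a naive heap-free flooding oracle in the test suite checks
voxel-for-voxel identity on random reliefs.

### Cortical compensation

Watershed basins capture marrow; the dark cortical shell (≈ one voxel at
0.7–0.75 mm spacing) belongs to the bone but hosts the gradient ridge.  Each
basin is therefore dilated by the unit diamond (half-size 1).  A voxel
claimed by several dilated bones takes the label of its face neighbour with
the lowest relief (lowest label on ties); background-marker voxels are never
claimed.

## Stage parameters

All operating constants live in `PipelineConfig`, in gray levels, voxels or
slices:

| parameter | default | role |
|---|---|---|
| `i_low`, `i_high` | 200, 500 | search range for the hand-mask histogram valley |
| `smooth_box` | 11 | running-average width for that histogram |
| `box` | 5 px | closing half-size for the hand mask (full 11 px ≈ 8 mm spans cortical/tendon thickness); final erosion uses half of it (2 px ≈ 1.5 mm, below skin thickness) |
| `min_rel_depth`, `max_dist_frac` | 0.10, 0.15 | profile-classifier acceptance rules for the radioulnar slice |
| `buffer` | 200 | added to the maximum-entropy threshold so thresholded clusters separate per bone |
| `n_keep`, `x_th_frac` | 10, 0.35 | cluster-extent cap and distal-position filter for the metacarpal slice |
| `growth_depth` | 10 slices ≈ 7 mm | best-first marker growth, about the extent of the wrist joint |
| marker thresholds | 1, 1, 240 | re-binarization of propagated (8-bit-scaled) markers per stage |
| component caps | 2, 5, 8 | markers kept per stage |
| `dilation_half_size` | 1 voxel ≈ 0.7 mm | cortical compensation |

The axial axis is always axis 2, increasing distal → proximal; the
distal-positive cluster coordinate is `x = L − 1 − z` with the origin at the
distal field-of-view edge.  The anatomical origin this approximates (the
styloid apex) cannot be located before segmentation; the offset only shifts
the `x_min > 0.35·L` comparison, which has wide margins on both bone groups.

## Registration

Each stage registers an atlas image (moving) to a case image (fixed) by
minimizing the mean-squared intensity difference with a regular-step
gradient-descent optimizer and linear interpolation, through four stages:
rigid (centered initialization), affine, then coarse- and fine-grid
free-form (B-spline) deformations with mesh sizes 1 and 5 (≈ 4 and 8 control
points per axis — a 2× refinement).  Stage transforms compose innermost:
each new stage is optimized with the already-accepted chain as the moving
initial transform.  Two practical rules:

* Once the chain contains a B-spline it cannot serve as a moving initial
  transform (ITK does not expose its position Jacobian), so from then on the
  moving image is resampled through the chain and the next stage is
  optimized alone, then composed analytically.
* A stage that does not improve the (optionally mask-restricted)
  mean-squares metric is dropped with a warning.  The regular-step optimizer
  occasionally diverges on the affine stage; dropping it keeps the chain
  monotone, and the deformable stages recover the residual.

Learning rates default to 2.0 (rigid), 1.0 (affine, B-spline) with physical
shift scaling, minimum step 10⁻⁴ of the learning rate, 120 iterations for 2D
stages and 80/40 (linear/deformable) for 3D.  The 3D carpal registration
runs on a single shrink-by-4 pyramid level with smoothing σ = 2: at the
regression problem size (below) the full-resolution level multiplies runtime
several-fold with no measurable gain in marker purity, because markers are
re-binarized at coarse tolerances anyway.  Propagated markers are resampled
with linear interpolation at 8-bit scale (foreground 255) and re-thresholded,
exactly in that order, so the carpal threshold of 240 keeps only voxels with
≈ 94 % marker support.

Registration runs single-threaded; combined with the deterministic flooding
and integer morphology, the whole pipeline is bit-reproducible.

## Carpal region

The carpal region is bounded distally by the proximal envelope of the
metacarpal segmentation, proximally by the distal envelope of the
ulna/radius segmentation (per-column extrema, nearest-neighbour extrapolated
across bone-free columns and regularized by an in-plane 5×5 grey
dilation/erosion so that columns grazing a warped bone surface do not punch
through), and laterally by two support planes in the coronal projection —
convex-hull bridge edges tangent to ulna + fifth metacarpal and radius +
first metacarpal, chosen so that both bodies *and* the carpals lie in the
kept half-plane.  The complement of the region is the background marker of
the carpal watershed, so the earlier segmentations bound the carpal basins
by construction.

## Synthetic phantom

The phantom emulates the *decision structure* the pipeline faces, not wrist
anatomy: an elliptical soft-tissue column (mean 430, SD 45) with a two-voxel
bright skin rim (980 ± 55) in dark air (80 ± 45); two proximal shafts with
bulged distal ends (radius, ulna), two rows of four carpal ellipsoids
(7–10 mm bodies), five metacarpal bars with bulged bases; every body a
marrow core (980 ± 55) in a one-voxel cortical shell (280 ± 50).  Skin and
marrow deliberately share one band — the failure mode that rules out global
thresholding.  The intensity model is calibrated once so the pipeline's
printed constants hold: the histogram valley falls inside [200, 500], and
the maximum-entropy threshold + 200 separates soft tissue from marrow.
Geometry is defined implicitly and rasterized at coordinates displaced by a
smooth random field (peak 2 voxels, 5×5×4 control grid), so each seed is a
plausibly deformed individual with exact labels; the generator refuses
configurations whose bodies touch.  Atlas bundles are derived by warping a
phantom (peak 1.5 voxels), jittering intensity, and extracting the
largest-cross-section slices, the carpal region, and markers from the ground
truth (2D markers eroded twice; carpal markers kept at full volume, since
the 240-threshold plus intensity filter perform the trimming, and eroding
the small carpals makes them vanish under resampling).

What passing phantom tests shows: the marker construction, flooding,
region logic, metrics and determinism work end-to-end under noise,
deformation and the skin/marrow ambiguity.  What it does not show: robustness
to pathology (erosions deform real bones beyond a smooth warp), to
inter-subject shape variation beyond the warp family, to acquisition
artifacts (bias fields, wrap-around, motion), or to anatomical outliers; the
ellipsoidal carpals are also easier registration targets than real ones.

## Problem sizes and runtime

The regression corpus is 20 phantoms of 96 × 96 × 72 voxels (seeds 1–20,
atlas from seed 100), roughly half the clinical grid in each direction —
small enough that a full end-to-end run takes ≈ 20 s on one CPU core while
keeping every structural feature (the coarsest grid at which all 15 bodies
rasterize with closed shells and ≥ 1-voxel separations).  On this corpus all
20/20 phantoms yield 15/15 bones with per-bone MS ≥ 0.79 and MAD = 1.0.

## Degenerate inputs and tie rules

* Histogram valley and maximum-entropy searches take the lowest qualifying
  gray level on ties; both reject histograms with fewer than two occupied
  bins.
* MAD of identical masks is defined as 0 (the spectrum ratio is 0/0; the
  segmentation is perfect).
* Granulometric MAD measures the city-block *radius* of the XOR band: a
  band of width k is removed at opening size ⌈k/2⌉, so symmetric one-voxel
  boundary offsets give exactly 1 while a two-voxel one-sided offset also
  gives 1 — it is a scale estimate, not a mean surface distance.
* `keep_largest` and marker finalization order equal-sized components by
  their first raster voxel.
* Best-first growth expands equal intensities in insertion order (FIFO), so
  flat regions grow breadth-first; growth hitting the volume edge returns
  the truncated path with a warning.
* Empty markers, overlapping object markers, degenerate (constant) images
  and geometry/file-length mismatches raise immediately with the offending
  object named; a failing pipeline stage raises a `StageError` naming the
  stage and carrying partial results.
* Per-bone AUC counts true negatives inside the joint bounding box of the
  two masks (padded by one voxel), not the whole field of view, so the ROC
  is not saturated by empty background.

## Known limitations

* The watershed-line policy (first arrival) and the dilation conflict rule
  are deterministic conventions, not claims about the true boundary; both
  matter only on the one-voxel scale that MAD already reports.
* The affine registration stage is dropped when it diverges rather than
  re-tuned per case; a line-search optimizer would be more robust.
* The metacarpal and radioulnar stages assume the standard field-of-view
  layout (metacarpals distal, forearm proximal, one hand per volume).
* The per-slice MAD variant pools 2D spectra across axial slices; for masks
  thinner than one slice it degenerates to the 3D value.
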