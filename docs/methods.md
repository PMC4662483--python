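# Methods

This note documents the measurement model implemented in `woundquant`, the
synthetic data it is validated on, the numerical choices involved, and the
limits of what the validation shows.

## Assay and measurement model

A scratch (wound-healing) assay produces pairs of phase-contrast micrographs
of the same field at 0 h and after incubation.  The quantity of interest is
the width of the denuded band, measured perpendicular to the band's long
("main") axis, before and after incubation, for a treated and a control
condition.  The pipeline is a three-step appearance-based reader:

1. split each image into cell and wounded areas from texture differences;
2. extract the detailed cell/wound boundary contours;
3. measure N user-chosen, equally-spaced lines perpendicular to the wound
   main axis (default N = 5) and average them.

Derived assay arithmetic: relative migration distance
100·(A−B)/(a−b) (A/a widths before incubation, B/b after; capital = treated,
lower-case = control), caliper tumour volume V = L·W²/2, and
normalization-to-control 100·value/control.  The formula string is read as a
ratio of closures; the treated and control closures must share one unit, and
the percentage is invariant to a common rescaling (px vs µm).  A control that
did not move (a = b) makes the ratio undefined and is an explicit error.

## Segmentation

Cell monolayers are granular under phase contrast; the scratch is smooth.
The discriminating statistic is the moving-window **local variance** of
intensity (window 15 px square, reflect boundary), lightly smoothed with an
isotropic Gaussian (σ 2 px).

Thresholding is done in two steps:

* **Class identification.** Otsu's criterion applied to log10(variance).
  The wound and monolayer variance levels differ multiplicatively (often by
  orders of magnitude), so the log domain gives a stable two-class split
  where the raw-variance histogram is dominated by the skewed monolayer
  mode.  Ties in the Otsu criterion resolve to the lowest threshold
  (scikit-image behaviour), and the statistic is deterministic, so
  segmentation carries no randomness.
* **Level placement.** Each class's representative variance level is the
  mean over the class eroded by a full window (so windows straddling the
  boundary contribute to neither).  The final split level is the midpoint of
  the two levels.  Rationale: as a window slides across a straight boundary,
  its variance is (to first order) the cell-area fraction f times the
  monolayer variance plus (1−f) times the wound variance; the midpoint level
  is crossed exactly at f = ½, i.e. when the window is centred on the true
  boundary.  A direct Otsu cut on a texture map does not have this property
  and systematically eats into the wound.

The thresholded map is cleaned by morphological opening then closing (disk
radius 5 px) and the largest connected low-texture component is kept — the
assay has a single scratch; smaller components are discarded.  A second pass
re-smooths the variance map **along** the estimated main axis (oriented
Gaussian line kernel, σ 20 px along, 0.6 px across) and re-thresholds at the
same level.  Because the boundary runs along the axis, this averages the
variance-estimator noise out of the level set without moving the transition
midpoint; it roughly halves the boundary wiggle that otherwise dominates the
width error.

Outcomes are graded: a fully closed monolayer returns an *empty* wound mask
(not an exception) — declared when the two appearance classes are not
separated by at least a factor 4 in variance, or when the largest low-texture
component is under 2% of the frame; a constant image, where the texture map
is uniformly zero and no split exists, raises a degenerate-appearance error.

## Axis, contours, measurement lines

* **Axis**: principal eigenvector of the second central moments of the wound
  pixel coordinates, sign-normalized (first nonzero component positive).  If
  the two eigenvalues agree within 5% the region is isotropic and has no
  main axis — an error, since "perpendicular to the wound" is then
  undefined.  The axial extent is the [min, max] projection of wound pixels
  onto the direction.
* **Contours**: marching squares at level ½ on the binary mask.  With the
  package's convention — (row, col) coordinates, pixel centers at integers,
  a pixel owning the half-open square [r−0.5, r+0.5)×[c−0.5, c+0.5) — the
  traced boundary sits at half-integer offsets between wound and cell pixel
  centers.  Segments are assigned to the two sides of the axis by the sign
  of their mean perpendicular offset, ordered by axial projection (enforced
  strictly monotone), and smoothed with a 9-vertex moving average, which
  stays within a pixel of the mask boundary while removing the half-pixel
  staircase.  A wound with no boundary on one side of the axis (e.g. a
  frame-filling region that touches all four borders) is not separable and
  raises an error.
* **Line placement**: N lines at interior fractions k/(N+1), k = 1..N, of
  the axial extent — equally spaced by construction, never on the wound's
  axial tips.  N is the user's choice (default 5); explicit positions can be
  supplied instead, covering the fully manual reading of "user-defined
  lines".
* **Width measurement**: each side is parametrized by (axial projection s,
  perpendicular projection d); the intersection of a side with the
  perpendicular line at position p is d interpolated linearly at s = p, and
  the width is |d_a − d_b|.  Units: width_um = width_px × scale exactly when
  a µm/px scale is known, absent otherwise (never 0).

Degenerate lines are graded by cause.  A line where the two sides coincide,
or where a side has genuinely ended inside the frame, is a **closed** gap:
width 0 with a flag, not missing data (dropping it would bias the mean of a
closing wound upward).  A side that terminates *on the image border* is a
different situation — the scratch boundary has left the field of view, as
happens in the frame corners of a strongly angled band — and is linearly
extrapolated from its last fitted segment (least squares over up to 60
vertices, skipping the 15 nearest the corner, where morphology rounds the
trace).  Without this distinction, interior lines of a wide oblique wound
would be reported as closed and the mean width collapses.

## Synthetic data: what it emulates and what it does not

The generator draws an analytic wound band — straight centerline through the
image center plus a configurable perpendicular offset, at an angle in
[−90°, 90°) from vertical, of constant or linearly tapering width — through
a textured monolayer.  Ground truth is exact: the wound mask is the set of
pixels whose centers lie strictly inside the band (so a zero-width band is
empty), and the true width at any axial position is available as a function
in the same axial coordinate the pipeline uses.  A band whose boundaries do
not both cross the frame is rejected.

Appearance model (these are this package's choices; the assay itself fixes
no resolution, scale or bit depth):

* frame 600×800 px, written as 16-bit grayscale TIFF, background 0.5 on a
  [0, 1] intensity scale;
* monolayer texture = granules (Gaussian-filtered noise, σ 3 px,
  soft-thresholded, then high-passed so the field is locally zero-mean) over
  a fine speckle floor (σ 0.8 px), mixed 0.5 : 0.85 and scaled to standard
  deviation `texture_contrast` (default 0.12).  The high-pass matters: a
  local mean offset at the wound edge would add an f(1−f)·Δµ² term to the
  boundary variance transition and bias any variance-based split;
* additive Gaussian sensor noise, σ `noise_sigma` (default 0.02) — giving a
  cell:wound local-texture ratio of about 5, comfortably above the factor 3
  the segmenter needs;
* one integer seed drives a single stream (draw order: granule field,
  speckle field, sensor noise); equal specs and seeds are bit-identical.

A 0 h/24 h pair reuses the texture and noise fields of the first frame and
only narrows the band, so the pair differs exactly where biology would
differ.  Not emulated: curved or multiple scratches, cell-scale migration
dynamics (straggler cells inside the gap, ragged fronts), illumination
gradients, Poisson noise, optical halo.  Passing the synthetic benchmarks
therefore demonstrates the geometry and measurement chain is correct and
unbiased on ideal monolayers; it does not certify performance on real
micrographs with debris or uneven illumination, where the `min_texture_ratio`
and window parameters may need adjustment.

## Validation summary (recomputed by tests and scripts/acceptance.py)

Over 20 random geometries (width U[40, 200] px, angle U[−45°, 45°]), the
mean absolute error of the per-image mean width is well under 1 px without
sensor noise and under 2 px at default noise; segmentation IoU against the
analytic mask exceeds 0.95 (noiseless) and 0.90 (default noise); widths are
invariant (<1%) under 90° rotation; measured t1 widths decrease strictly
with imposed closure and a fully closed pair measures exactly 0; batch
reruns are byte-identical.  The benchmark sizes (20 images for width
recovery, 6 geometries × 2 noise levels for IoU, one pair per closure level)
keep the whole suite and the acceptance script at a few minutes on one CPU
while leaving the estimates' Monte-Carlo error far below the tolerances
checked.

## Known limitations

* The wound model is a single straight band; strongly curved scratches
  violate the single-main-axis assumption (the axis is still estimated, but
  perpendicular widths lose their meaning).
* Axis estimation by moments is biased by up to ~1° when the frame clips an
  oblique band asymmetrically; the effect on widths is second order
  (cos of the angle error).
* The segmentation threshold assumes two texture populations; tissues with
  strong confluence gradients may need a larger `min_texture_ratio` or
  manual window tuning.
* Batch CSV schemas are this package's own and are versioned with it; they
  are not compatible with any other scratch-assay tool's output.
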