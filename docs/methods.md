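# Methods

## Problem setting

A maize field's in-field height variation is mapped two ways: by a dense
laser-scanning-style reference survey, and by lay participants walking
four predefined measurement rows with consumer GPS devices or
smartphones. The package derives both surfaces and quantifies their
agreement. All planar coordinates are meters, elevation rasters are
meters above sea level, and crop heights are centimeters. Rasters use a
lower-left origin with cell centers at origin + (j + ½)·cell; the
nodata sentinel is −9999 (ESRI ASCII convention).

## Reference crop height model (CHMREF)

Inputs are a terrain scan (early season, bare ground visible) and a
canopy scan (full growth), as XYZ point clouds. The derivation:

1. **Ground filter.** Per 50 cm cell, points within `ground_slope_tol`
   (default 10 cm) of the cell's lowest return are kept. This is a
   deliberately simple lowest-point filter: on an early-season scan the
   ground dominates and off-terrain returns sit well above the per-cell
   minimum. (Production terrain filters are more elaborate; the cloud
   simulated here has no vegetation in the terrain scan, so nothing
   stronger is needed.)
2. **DTM by moving planes.** Per cell, a least-squares plane through
   the k = 8 nearest ground points (within a 2 m search radius),
   evaluated at the cell center. Cells with no points in reach are
   nodata.
3. **CSM by percentile.** Per cell, the 99th percentile (linear
   interpolation between order statistics) of member canopy elevations —
   a maximum that is robust to high outliers. Which percentile
   definition to use was an open choice; linear interpolation is
   numpy's default and is what the brute-force oracles implement.
4. **CHM.** (CSM − DTM)·100, in cm; nodata propagates; negative heights
   (noise artifacts) are clamped to 0 and counted.
5. **Local-maximum filters.** A circular kernel of 15 cm diameter
   (plant spacing) and then one of 80 cm (row spacing). Kernel
   membership is by cell-center distance ≤ diameter/2, inclusive;
   boundary cells use truncated kernels. Note that at the default 50 cm
   cell both kernels reduce to the center cell alone, so these stages
   matter on finer grids; they are exercised at sub-cell resolutions in
   the tests.
6. **Row-spacing filter.** Cells where the 80 cm maximum exceeds the
   15 cm maximum by more than 10 cm are assumed to sample lower leaves
   between rows and are removed.
7. **Seamless Gaussian.** A renormalized Gaussian convolution
   (σ = 1 cell by default; the right value was not prescribed anywhere,
   1 cell keeps the surface sharp while closing single-cell gaps):
   weights are renormalized over valid cells only, which smooths and
   fills the removed cells in one pass. The kernel is truncated wide
   enough to span the grid, so every cell reachable from a valid cell
   is filled; outputs stay within [min, max] of the inputs by convexity.
   Whether gap-filling should precede or coincide with the smoothing
   was open; one renormalized pass does both and is order-free.

## Direct measurements

M1 category *k* converts to height as *k*·body_height/10 — equal
intervals with the top category anchored at the participant's body
height, giving class widths of 15–20 cm for realistic bodies. Knee
height is recorded in the data model as an optional alternative anchor
but is not used by the default mapping (no published level-to-height
table exists; the equal-interval choice is the simplest consistent with
"category 10 = body height"). The nearest-category inverse of the same
mapping is what the survey simulator uses, so noiseless round-trips are
exact. Spearman correlations between M1 and M2 use average ranks
(categories are heavily tied).

## Co-registration

GPS positions carry noise plus an unknown datum offset relative to the
reference frame. They are aligned to the known row geometry by a 2-D
similarity transform p′ = s·R(θ)·p + t, fitted by iterative closest
point: project the transformed points onto the row segments
(orthogonal projection clamped to segment ends; ties broken by first
polyline, then first segment), solve a closed-form least-squares
similarity against the projections, repeat (tol 1e-6 m, max 100
iterations). Two hardening measures matter in practice:

* **Exact fixed-assignment step.** Plain projection-ICP crawls
  tangentially along the rows (linear convergence with rate ≈ 1 for
  the along-row modes). Each iteration therefore also computes the
  exact minimizer of the assignment-frozen objective — distance to the
  matched segment's line for interior projections, to the clamped
  vertex otherwise — which is a linear least-squares problem in
  (s·cosθ, s·sinθ, tx, ty). Whichever of the two steps ends lower is
  kept, so the objective stays monotone while converging in a handful
  of iterations.
* **Bounds and multi-start.** Pure row-distance minimization has
  degenerate attractors: shrinking the survey onto the rows, and (for
  the symmetric four-row layout) a 180° flip. GPS datum errors in scale
  and orientation are tiny, so steps with scale outside [0.8, 1.25] or
  |rotation| > 45° are rejected, and the ICP is multi-started from the
  identity and from centroid/principal-axis alignments (with small
  cross-row shifts to escape wrong nearest-row assignments).

A per-row mode (`fit_similarity_per_row`) assigns each point to its
nearest row and fits that subset separately, for surveys where rows
were collected independently; the whole-survey fit is the pipeline
default because the simulator applies a single hidden datum offset.
Note the intrinsic limitation of row-based registration: with parallel
rows, the along-row translation is constrained only by points near the
row ends.

## Interpolation (CHMPS)

Point heights are interpolated by ordinary kriging. The empirical
semivariogram γ(h) = mean of ½(vᵢ−vⱼ)² over distance-binned pairs is
fitted (weighted least squares, weights = pair counts, non-negativity
bounds) with an exponential or spherical model in the effective-range
convention (95% of the sill at h = range). Per cell, the kriging
system over the 32 nearest points is solved in the semivariance
formulation with a Lagrange multiplier, so weights sum to one;
duplicate coordinates are averaged beforehand and near-singular
systems get 1e-8 on the diagonal (logged). Kriging variance is
reported alongside the prediction. Proprietary "automatic" kriging
variants fit ensembles of variograms; this package uses one documented
WLS fit instead — the variogram family and neighborhood are
configurable, and exact parity with any specific commercial
implementation is not claimed.

## Image-based heights

The renderer draws a 200 cm bar (flanks 6 cm wide) whose top 15 cm
carries a distinctly colored, narrower reference band, occludes it from
the bottom with textured green crop pixels up to the requested height,
adds background clutter and sensor noise, and strokes an ellipse
(the participant's touchscreen circle) around the bar. The truth mask
is exact, so render→measure is invertible to the pixel quantum
(0.5 cm at the default 2 px/cm).

Features per pixel and scale σ ∈ {1, 2, 4}: Gaussian-smoothed R, G, B;
gradient magnitude of luminance (edge); local luminance variance
(texture); structure-tensor coherence (orientation). A random forest
(50 trees) is trained on sparsely labeled pixels of 8 of 20 rendered
images (mirroring a ~10% labeling effort by an interactive tool).
Probabilities are thresholded at ≥ 0.5 (ties included), masks are
cleaned by opening (disk 2 px), dilation (disk 5 px), largest
8-connected component, then an equal erosion: the dilation exists to
*connect* fragments, and eroding back prevents it from inflating the
extents whose ratio the height estimate rests on. The bar's visible
extent is measured on the union of marker and reference masks (the
reference band is the top of the bar), clipped to the circle's
bounding box; extents are maximum per-column pixel counts, and
crop = 200 − 15·marker_px/reference_px, clamped to [0, 200] with
clamping flagged. Failures (dark frame below the mean-luminance floor,
no circle, no reference, no marker) come back as status codes so batch
runs always complete. The morphology radii are configurable; the
defaults kill stroke-width specks and bridge the stroke of the dashed
circle. No perspective or camera-tilt correction is attempted —
"vertical" is the image row axis.

## Evaluation

R² is the squared Pearson correlation, computed after excluding pairs
whose absolute height difference exceeds the 95th percentile of all
absolute differences (Pearson is not outlier-robust; below 20 pairs
nothing is excluded, logged). The difference rasters use the
convention ref − ps, so a positive mean says the participatory surface
underestimates; the standard deviation is the population SD by
default, so rmse² = mean² + sd² holds exactly (sample SD is a flag).
Whether the outlier rule should use signed or absolute differences was
ambiguous; absolute is the default and the rule is switchable. The
difference statistics are reported for the whole study area and the
road strip, each for I1-only and I1+I2 (both labellings emitted
explicitly, since "I2 column" conventions vary). Segmentation quality
uses precision = TP/(TP+FP) and recall = TP/(TP+FN) per class, with
undefined denominators reported as missing rather than zero.

The road-strip depression is estimated by fitting, per raster row, a
quadratic x-trend to 7.5 m flanks on both sides of the strip and
averaging (predicted − observed) over the strip core (1 m edge
margin): the quadratic removes the smooth in-field height pattern that
a plain strip-mean comparison confounds with the depression.

## Synthetic study conditions

The generator's defaults are the study conditions, not tuning knobs:
150 m × 30 m field; crop heights rescaled into [30, 180] cm from
Gaussian-smoothed white noise with 10 m correlation length (the real
pattern is only known qualitatively — smooth variation plus distinct
low areas — and one correlation-length knob reproduces it); a 5 m
road strip 40 cm lower (clamped at 0); terrain a 107→109 m planar
gradient plus ~3 cm smooth noise; four straight measurement rows
evenly spaced across the width; crop rows at 80 cm, plants at 15 cm.
The hidden GPS datum offset is scale 1.0, rotation ≤ 2°, translation
≤ 5 m. Surveys walk each participant along a row (round-robin
assignment), recording every ten 0.7 m steps — about 7 m spacing; the
step length is an estimate and stays configurable — including both row
ends (participants enter and leave at the field edges; the end stops
are also what anchors the along-row component of the datum fit).
Additional I2 stops are inserted at segment midpoints where the local
height-gradient magnitude exceeds its field-wide 85th percentile
("plants vary greatly in height" made operational), accepted with
probability `i2_rate`. M2 = true height + N(0, 2 cm); M1 is the
nearest category of true height + N(0, 10 cm); GPS noise is isotropic
Gaussian — σ = 1.2 m (handheld GPS group) and 5 m (smartphone group),
matching the positional-accuracy ordering of the two device classes.

Point clouds: terrain points uniform over the field at 0.5 pts/0.01 m²;
canopy points at jittered plant positions (Gaussian 0.2 m leaf spread,
which also covers the inter-row gap as maize leaves do) with z uniform
in [0.4·h, h] plus 15% bare-ground returns and 1 cm vertical noise at
2 pts/0.01 m². These densities are deliberately far below real
scanner densities (which run to ~80 pts/0.01 m²) to keep the pipeline
seconds-fast; they are set where the CHM error is dominated by model
bias, not sampling noise, so higher densities would not change the
conclusions. The full pipeline (18 000 cells, ~1.1 M points, two
groups) runs in under ten seconds on one CPU.

What the generator does **not** emulate: scanner beam geometry and
occlusion physics, multi-scan registration error, radiometric realism
of photographs (the rendered classes are more color-separable than
real field photos — the measured segmentation scores are upper
bounds), perspective distortion of the marker bar, participant blunders
(transcription errors, wrong-row walks), and multi-temporal growth.
Passing tests therefore demonstrate the correctness and internal
consistency of the processing chain under known ground truth, not
field-grade accuracy of any specific instrument.

## Numerical choices and degenerate inputs

* Percentiles everywhere use linear interpolation between order
  statistics.
* Probability ties at exactly 0.5 are included; class ties are broken
  in the order background < marker < reference < circle.
* Component-size ties in mask cleanup go to the smallest top-left
  bounding corner.
* Empty point clouds, all-nodata grids, coincident point sets,
  zero-variance correlations and mismatched grid geometries raise
  typed errors; per-image estimation failures are status codes, never
  exceptions.
* All generators and fits are deterministic for a fixed seed; CHM
  derivation is invariant to point order.
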