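# Methods

This note documents the models, parameter choices, and numerical decisions
behind `crownscorch`, and what the synthetic benchmarks do and do not show
about real data.

## Data model and preprocessing

Inputs are a height-normalized colored point cloud (planar meters; LAS 1.2
RGB formats or `x y z r g b` text) and a co-registered 3-band orthomosaic
(GeoTIFF). Ground classification is assumed upstream; for clouds arriving
with raw elevations, `normalize_by_grid_minimum` subtracts a bilinearly
interpolated per-tile minimum surface (default 2-m tiles). This is a
deliberately simple normalizer for flat-to-moderate terrain, not a
replacement for a proper ground-classification workflow.

`preprocess` removes points strictly below 2 m above ground. Points exactly
at 2 m are retained (removal is strict-less). The filter is idempotent, and
an empty result is a warning rather than an error: plots with complete crown
consumption are a real outcome.

Grid convention throughout: origin at minimum x/y, row 0 at maximum y,
half-open cells `[x0 + j·cell, x0 + (j+1)·cell)`.

## Crown segmentation

* CHM: maximum point height per 10-cm cell; empty cells are no-data and are
  filled with 0 (ground) before smoothing so the watershed sees a complete
  surface.
* Smoothing: Gaussian with σ given in map units (0.05 m = 0.5 cells at the
  10-cm default), keeping behavior resolution-independent. Both are
  configurable.
* Treetops: a cell is a top when it is the maximum of a circular window of
  radius `max(0.6, 0.05·h + 0.6)` m, a standard crown-allometry window, and
  is at least 2 m tall. Equal-height plateau ties break toward the smaller
  (row, col) — arbitrary but deterministic.
* Crowns: marker-controlled watershed on the inverted smoothed CHM, masked
  to cells ≥ 2 m. Boundary polygons are the dissolved union of member cells
  (shared edge coordinates are bit-identical, so the union is gap-free);
  segment area is measured on the polygon, making the 0.3 m² filter
  resolution-independent. Member points are assigned through the label map,
  which guarantees plan-view containment.
* Matching: greedy one-to-one by ascending apex-to-stem distance, accepting
  a pair when distance ≤ 2.0 m and the apex height is within 30% of the
  field height. The distance default brackets typical GNSS stem-position
  error under canopy (~1.3 m RMSE).

## Burn classification

Per-pixel greenness uses GLI = (2G − R − B)/(2G + R + B), computed on raw
stored band values (no radiometric calibration), defined as 0 when the
denominator vanishes. GLI is invariant to uniform scaling of the bands, so
pure shading changes its value only through quantization and additive noise.

Crown pixels are restricted before scoring: points below the 25th
percentile of the segment's point heights are dropped (the percentile is
linear-interpolation; a fraction-of-maximum reading is available via
`percentile_of_max`), then an isolated-voxels filter removes points whose
0.5-m voxel has no occupied 26-neighbor (a single-voxel crown is exempt —
isolation is meaningless there). At least 3 points must survive (the
smallest hull-able set). The concave hull is an alpha shape whose alpha
adapts to point spacing: starting at 3× the median nearest-neighbor
distance and doubling until the shape contains ≥ 99% of the points, with a
convex-hull fallback. A fixed multiplier cannot serve both the dense crown
rim and the sparse interior of photogrammetric crowns; the adaptive rule is
deterministic and reduces to a detailed outline wherever density supports
it. Pixels are selected by center-in-polygon containment.

The burn call uses the fraction of pixels with GLI strictly greater than 0:
below 50% → burned, at or above → unburned (the boundary maps to unburned;
a pixel at exactly GLI 0 is non-positive).

## Scorch metrics

* Vertical profile: per-point GLI medians in 10-cm slices anchored at the
  lowest point height, so the profile describes the crown rather than a
  fixed datum. Empty slices are marked and excluded from fitting, not
  imputed.
* Spline: a cubic smoothing spline with knots at every slice center. The
  user-facing smoothing parameter lives on the conventional normalized
  [0, 1] scale — λ = r·256^(3·s−1), r = tr(XᵀWX)/tr(Ω) — so s = 0.65, the
  default, reproduces the behavior of the standard statistical-software
  implementation (the test suite cross-checks the fit against R's
  `smooth.spline` to < 0.02 absolute deviation). Slices are weighted by
  their point counts: a sparse slice (a few bole points above a consumed
  crown) cannot swing the trend against fully populated slices. The fit is
  an (n+2)-basis penalized B-spline solve; the penalty integral is exact
  (2-point Gauss–Legendre on the piecewise-linear second derivative).
* Scorch height: with mixed signs, the lowest negative-to-positive crossing
  of the spline, bracketed on a 1-cm grid and bisected to < 1 mm; always
  negative → maximum point height (no surviving foliage); always positive →
  crown base height, flagged `inconsistent-with-classification` (this arises
  only for trees the classifier called burned, the known misclassification
  pathway for crowns scorched only near the base). Scorch height is reported
  as height above ground, matching field protocol.
* Known estimator offset: because living foliage carries a much larger GLI
  magnitude (≈ +0.40) than scorched foliage (≈ −0.05), the smoothed profile
  crosses zero slightly below the true transition — about −0.3 m at the
  default smoothing, nearly constant across crown geometries. The offset is
  absorbed by the regression intercept when estimates are compared to field
  truth (slope ≈ 1.00, R² > 0.99, residual RMSE ≈ 0.04 m on noiseless
  benchmark trees); per-tree absolute estimates inherit it.
* Crown base height: point counts in 25-cm bins, 3-bin moving average
  (normalized at the edges), crown base at the lowest sign change of the
  discrete second difference. Three guards keep the rule on the intended
  histogram feature: when the lowest bins are already dense (≥ half the
  median bin count) the cloud starts inside the crown and the lowest point
  is returned directly; an inflection must exceed twice the local Poisson
  scale √count on both sides; and only inflections at or below the histogram
  peak qualify (the conical taper at the apex is itself a curvature change).
  Degenerate inputs (span < 1 m, < 8 points, no qualifying inflection) fall
  back to the lowest point height, flagged.
* CVS = 100·CLS·(2·CL − CLS)/CL², clipped to [0, 100] against floating-point
  overshoot; CLS is clamped to [0, CL]. The formula assumes a conical crown
  scorched uniformly from below — it is exact for the generator's cones and
  an approximation for real crowns with uneven scorch.

## Synthetic scenes

The generator emulates the statistical structure of a drone photogrammetry
acquisition over an 11.28-m-radius conifer plot: ~640 points/m², ~4.4-cm
orthomosaic, cone-shaped crowns (the same geometric idealization the CVS
formula assumes). Defaults, and why:

* Foliage sampling: height uniform along the crown (thin slices evenly
  populated), radial placement biased to the cone surface (density ∝ r³) —
  nadir photogrammetry reconstructs the visible outer envelope far more
  densely than crown interiors.
* Palette: living (60, 140, 60), scorched (150, 90, 50), bole (40, 34, 30),
  ground (115, 95, 85). The values are conventions chosen so the *sign* of
  GLI encodes the class — strictly positive only for living foliage; an
  exactly-zero class would be sign-ambiguous for the downstream rules. They
  are not a radiometric calibration of real scorched needles.
* Noise model: a 20% random subset of points darkened ×[0.1, 0.4]
  (shadowing), then additive per-band Gaussian noise with sd 10 (8-bit
  counts), then clipping/quantization. Shadowing precedes sensor noise, as
  in a real camera.
* Severity distribution: half the trees burned; of those, half carry
  complete crown scorch (matching the top-heavy severity mix of post-fire
  validation campaigns, where complete scorch dominates) and the rest are
  scorched over the upper 55–100% of the crown. The lower bound keeps the
  damage visible from above: a cone scorched over less than ~half its
  length shows mostly green foliage in nadir view and cannot be detected by
  any top-down method — that failure pathway is real but is not a condition
  the default generator emulates.
* Ground points at z ∈ [0, 0.2] m exercise the 2-m preprocessing filter;
  orthomosaic cells that receive no point borrow the nearest painted cell's
  color (within 3 cells), since a real stitched orthomosaic is gap-free.

What the generator does **not** model: occlusion between neighboring crowns,
multi-layered canopies, photogrammetric dropout over consumed stands,
radiometric drift, off-nadir geometry, non-conical crowns, and within-crown
severity variation. Benchmark numbers on synthetic scenes are therefore an
upper bound on real-data performance: they verify the machinery recovers
truth under its own assumptions, not that those assumptions hold in any
particular stand. Published field campaigns report substantially lower
detection recall (~0.6) and scorch-height R² (~0.8) on real mixed stands.

## Benchmarks and problem sizes

`crownscorch.benchmarks` (used by `scripts/acceptance.py` and the headline
tests) runs: detection on 2 clean 8-tree stands; scorch-height recovery on
120 noiseless single trees with scorch uniform over the crown range;
classification and CVS agreement on 120 trees under default noise and
shadowing. These sizes put binomial standard errors on the reported rates
near 2–4 percentage points while keeping a full run around two minutes on
one CPU.

## Known limitations

* Scorched-vs-consumed portions of a crown are not distinguished; bole char
  is out of scope.
* The classification cannot see scorch hidden under a green upper crown
  (nadir-view geometry), and no shadow removal or radiometric calibration is
  applied.
* The grid-minimum normalizer under-corrects steep terrain.
* Matching is distance/height-threshold based; polygon-containment matching
  is not implemented.
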