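# Methods

`wpbscreen` re-implements, as a tested Python library, a high-content
analysis workflow for Weibel-Palade bodies (WPBs): the rod-shaped,
von-Willebrand-factor (vWF)-storing secretory granules of endothelial
cells. The workflow takes multi-well fluorescence fields (nuclear and vWF
channels), segments every WPB, assigns each to a cell, summarizes each
well by four morphometric statistics, and scores wells across a plate set
the way RNAi screens are scored (B-score normalization, robust Z scores,
Z' assay QC). A synthetic plate generator with exact ground truth makes
every stage testable without microscope data.

## Image analysis

### Part 1 — nuclei and cell territories

1. **Median filter**, circular, radius 2 px. Smooths nuclear contours so
   the later watershed does not cut at small concavities.
2. **Otsu global threshold** on the filtered image, followed by hole
   filling. The thresholding method for the nuclear channel is a design
   choice of this package: Hoechst fields are strongly bimodal, and Otsu
   is parameter-free and deterministic. A constant (empty) image yields an
   empty mask rather than a spurious threshold.
3. **Watershed splitting** of touching nuclei: Euclidean distance
   transform, Gaussian-smoothed (sigma 1 px), regional maxima with at
   least 5 px separation as seeds. The basin boundaries are erased on the
   higher-label side using the full 8-neighborhood, because a 1-px
   4-connected line does not actually separate 8-connected components
   (labels would leak across diagonal steps).
4. **Area gate** 50-2500 um^2: removes debris and unresolvable clumps.
5. **Influence zones**: each pixel is assigned to the nearest surviving
   nucleus centroid (discrete Voronoi tessellation; ties go to the lower
   label), approximating single-cell territories in a confluent
   monolayer. A separating mesh (label 0) is drawn on the higher-label
   side of each boundary, again with 8-neighborhood semantics so the mesh
   is a true separator; it is 1 px wide along straight boundaries. Zone
   labels are grey shades in a 16-bit raster: at most 65535 cells, with 0
   reserved for the mesh (an 8-bit raster would cap at 255 labels beside
   the reserved shade — too few for dense fields).
6. **Nucleus-to-zone assignment** measures the mean of the zone raster
   over each nucleus's pixels. The mean is an exact integer when the
   nucleus sits inside one zone; a nucleus leaning across the mesh is
   flagged and assigned by majority pixel vote.

The Voronoi territory is an approximation, not a membrane segmentation:
it is exact only where real cell boundaries lie on the mid-lines between
nuclei, and it assumes a confluent monolayer.

### Part 2 — WPB segmentation and morphometry

All thresholding happens on a working copy; intensity features are always
measured on the untouched original image.

1. **Background subtraction**: rolling-ball radius 1 px with sliding
   paraboloid correction. Implemented as grey-scale openings with a
   parabolic structuring function (the apex curvature of the
   corresponding ball) applied sequentially along rows, columns and both
   diagonals; the diagonal step is sqrt(2) px long and penalized
   accordingly. The estimated background can never exceed the image, and
   output is clamped at 0.
2. **8-bit conversion**: fixed linear map 0-4095 -> 0-255. A fixed map
   (rather than a display-range stretch) keeps the threshold comparable
   across images and plates and makes the pipeline deterministic.
3. **Bernsen local threshold**: circular window of radius 15 px; per
   pixel, `contrast = max - min` and `midgray = (max + min)/2`; pixels in
   low-contrast windows (`contrast < 15`) are foreground iff
   `midgray >= 128`, otherwise iff `value >= midgray`. Window extrema are
   computed with 8-bit rank filters (windows clipped at image borders).
   The contrast threshold is the single tunable that routinely needs
   adjustment: for weak stains raise it to 30 or 50, otherwise the
   thresholder starts detecting out-of-focus background.
4. **Mesh deletion**: WPB pixels on the Voronoi mesh are removed, so no
   object can straddle two cells. Consequently the per-object mean of the
   zone raster is an exact integer — the pipeline treats any non-integer
   mean as an integrity failure rather than rounding it away.
5. **Labeling and clump filter**: 8-connected components; objects larger
   than 10 um^2 are unresolvable WPB aggregates and are discarded.
6. **Morphometry** (per object, on raw intensities): area; mean/SD/min/
   max/median intensity; centroid; crack-boundary perimeter (count of
   exposed pixel edges, calibrated); best-fit ellipse from second central
   moments (with a 1/12 px^2 pixel-footprint term), scaled so the ellipse
   area equals the object area; circularity `4*pi*A/P^2` capped at 1;
   Feret and MinFeret by rotating calipers over the convex hull of pixel
   corners (centers +- 0.5 px); integrated densities; aspect ratio,
   roundness, solidity. The Feret endpoint reported in `FeretX`/`FeretY`
   is the endpoint of the maximal caliper pair with the smaller y (then
   smaller x) — the convention is documented rather than guessed, since
   "the end" of a diameter is inherently ambiguous. Perimeter is reported
   in um (a squared-length unit for a perimeter would be a typo, not a
   convention).

### Per-well statistics

Four statistics summarize a well, each the mean over its fields of view
(FoVs):

1. `PercentWPBarea` — area fraction contributed by WPBs with Feret
   diameter > 1.5 um;
2. `TotalWPBnrPerCellNR` — WPB count per cell;
3. `TotalWPBrawIntDenPerCellNR` — summed raw integrated density per cell;
4. `TotalFoVpercentWPBnr` — number fraction of WPBs with Feret > 1.5 um.

A FoV with zero WPBs contributes 0/0 to the two length-fraction features
and is excluded from their means (it still contributes a legitimate zero
to WPBs-per-cell); a FoV with zero cells is excluded from the per-cell
features. The bookkeeping field `n_fov_used` records how many FoVs each
feature actually used.

The cell count per FoV defaults to the number of influence zones (all
nuclei). A legacy mode (`cellcount_mode="wpb_cells"`) counts only cells
containing at least one WPB — the count one would get by extracting
unique cell ids from the WPB-to-cell table. Zone count is the default
because the statistics are defined per *total* cells; the legacy mode is
retained for comparability.

### Plate normalization and scoring

* **B score**: per-plate two-way median polish (alternating row/column
  median sweeps, run to numerical convergence — tolerance 1e-9 on the
  total absolute adjustment, capped at 2000 sweeps; random plates
  typically need tens of sweeps but slow geometric cases occur) followed
  by scaling the residuals with `1.4826 * median(|residuals|)`. An
  exactly additive plate leaves zero residuals and zero MAD; the 0/0 is
  defined to give all-zero B scores. Controls are included in the polish
  (no exclusion rule is imposed).
* **Z score**: `(x - median(samples)) / (1.4826 * MAD(samples))`,
  location and scale from sample wells only, computed per replicate
  across the whole screen and averaged over replicates. Per-plate scoring
  is available via configuration.
* **Z' factor**: `1 - 3(sd_pos + sd_neg)/|mean_pos - mean_neg|` with
  sample SDs, computed per replicate from raw control values.
* **Replicate SD**: per-well sample SD of B scores across replicates
  (reproducibility heatmap).
* **Hit list**: sample wells with mean Z strictly above the threshold
  (default 2), ranked descending, optionally gene-annotated.

## Synthetic plates

The generator emulates the screen's imaging conditions: confluent
monolayers at 0.1615 um/px with elliptical nuclei and rod-shaped WPBs
scattered inside each cell's Voronoi territory.

* **Field size** defaults to 1024 x 1376 px (~165 x 222 um). A field this
  size holds the realistic 70-100 nuclei at ~20% area coverage. (A
  half-sized sensor crop cannot: 70-100 nuclei that each must pass the
  50 um^2 gate would need over half the field area, beyond what
  sequential random placement can achieve — the generator raises a
  placement error naming density when asked for impossible packings.)
  Tests use smaller fields with proportionally fewer nuclei.
* **Nuclei**: filled ellipses, axes 11-16 um by 7-10 um (areas ~60-125
  um^2), placed by rejection sampling. Overlap is judged by the
  directional radii of the two ellipses along their center line; 10% of
  placements (configurable) relax the criterion so nuclei touch,
  exercising the watershed. Per-nucleus intensity varies +-15% around
  1500 DN.
* **WPBs**: capsules (rectangles with semicircular caps), end-to-end
  length drawn lognormal (default ln-scale mu 0.18, sigma 0.5: median
  1.2 um, ~33% above the 1.5 um cut), width 0.35 um, minimum length
  0.4 um. Rods are rasterized at 4x supersampling and box-downsampled,
  giving stable sub-pixel lengths near the 1.5 um Feret threshold. Rod
  intensity is uniform over the capsule (no internal texture is modeled;
  WPBs show little at this resolution). Rods keep a >= 2 px margin from
  Voronoi mid-lines — so the drawn cell assignment is exact — and a small
  gap (default 0.15 um) from other rods of the same cell. Rods that
  cannot be placed after 80 attempts are dropped from both image and
  truth, so the ground truth always describes exactly what was rendered.
* **Background and noise**: additive plane (level + row/column slopes)
  plus Gaussian noise clipped to the 12-bit range [0, 4095]. This is the
  simplest model that exercises thresholding robustness.
* **Plates**: 96 wells, default 5 FoV per well. The default screen layout
  places 8 negative-control and 8 positive-control wells on diagonals so
  no plate row or column is dominated by controls — whole-column controls
  would be absorbed into the median-polish column effects and disappear
  from the B scores. Positive controls emulate vWF knockdown (WPB count
  x0.1, intensity x0.2). Per-(well, field) seeds derive deterministically
  from the plate seed, so any well subset reproduces bit-identically.

### What the generator does not emulate

Real acquisitions add optical blur (the generator's rods have crisp
anti-aliased edges, not a measured PSF), uneven illumination beyond a
plane, staining artifacts (vWF-rich non-WPB structures survive real
segmentation as acknowledged artifacts), cell-to-cell intensity
variability, out-of-focus fields, and mitotic/apoptotic nuclei. Passing
the synthetic recovery tests therefore demonstrates that the algorithmic
chain is correct and self-consistent — not that segmentation accuracy on
real micrographs will match the near-perfect synthetic figures.

## Numerical and convention choices

* Pixel centers at integer coordinates, row-major, 0-based; outlines and
  hulls on pixel corners (+- 0.5 px); areas are pixel counts times
  `pixel_size_um^2`.
* Label rasters reserve 0 for background/mesh; labels are assigned in
  raster-scan order of each component's first pixel; exceeding the
  grey-shade capacity (255 for 8-bit, 65535 for 16-bit) raises a capacity
  error instead of wrapping.
* `StdDev` is the population SD of the object's pixels; `Circ.` and
  `Solidity` are clipped at 1 against floating-point round-off.
* Degenerate inputs: empty label maps yield empty tables with full
  headers; a field with zero nuclei is logged and skipped (its well
  statistics use the remaining fields); a plate fails only when every
  field fails.

## Problem sizes used in validation

The bundled validation (test suite and `scripts/acceptance.py`) runs on
512 x 512 px fields with ~18-25 nuclei per field — the generator's
default confluent density scaled to the smaller field — and a simulated
screen of one 96-well plate pair at 1 FoV per well, with oracle batches
of 100 random instances per equivalence check. These sizes were chosen to
keep a full from-scratch validation in the minutes range on a laptop
while leaving every statistical test adequately powered (>= 500 rods for
the length-fraction check, >= 95% precision/recall bars on three fields
totalling >500 objects).

## Known limitations

* The Voronoi territories are a proof-of-concept cell approximation; a
  membrane-stain segmentation would be needed for accurate per-cell
  areas.
* Bernsen window extrema use the circular-window rank filters' border
  behavior (window clipped at image edges); objects touching the border
  are measured on their visible part only.
* The median/rolling-ball edge behavior is defined by this package's
  contracts, not by bit-level replication of any particular desktop tool.
* `Angle`/`FeretAngle` follow the display convention (degrees in
  [0, 180), counter-clockwise with y pointing down-flipped); consumers
  comparing against other tools should check orientation conventions
  first.
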