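# Methods

This note documents the measurement model behind `stalksect`, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not demonstrate.

## Measurement model

The package treats a stained stalk cross-section as a two-region object:
a dark (lignified, stain-retaining) rind annulus and a lighter interior
— pith tissue in pith-filled species (maize, sorghum), or background
showing through the lumen in hollow species (wheat, Arabidopsis,
hemlock). All geometry is measured in image pixel coordinates
(x rightward, y downward, origin at the top-left pixel center) and
converted to millimeters through a single isotropic calibration factor
`px_per_mm`, the number of pixels spanning 1 mm at the acquisition
magnification. Anisotropic pixels are rejected rather than approximated;
microscope calibrations are entered explicitly (CLI flag or config file)
rather than parsed from vendor metadata.

### Binarization

Foreground polarity is fixed package-wide: foreground = dark class.

* **Otsu (hollow sections).** The threshold is chosen over gray levels
  0–255 to minimize the within-class intensity variance, computed from
  the 256-bin histogram with cumulative moments; ties break toward the
  smaller threshold for determinism, and pixels with value ≤ t* become
  foreground. A constant image is a hard error (degenerate histogram).
  The histogram of a hollow section (rind vs background) is cleanly
  bimodal, which is exactly Otsu's regime.
* **Local adaptive (pith-filled sections).** Per-pixel threshold =
  local mean over a square window of side
  `ceil(window_fraction · min(H, W))` (forced odd, reflective padding),
  scaled by a sensitivity factor `0.70 + 0.30·s` (0.85 at the default
  s = 0.5); pixels at or below their scaled local mean are foreground.
  Pith-filled sections have three-plus intensity classes (rind, bundles,
  pith, background), and a relative local threshold separates dark
  structures from their local surround without a global bimodality
  assumption.

  The default `window_fraction` is **0.5**. The window must be wider
  than the thickest single-intensity structure in the image — in
  practice the rind band — because a window lying wholly inside one
  class sees no contrast and the sub-unity sensitivity factor then
  classifies the darker half of its own noise as background, punching
  holes through thick rinds. Half the image side is safely above any
  plausible rind width while still adapting to smooth illumination
  gradients. The sub-unity default factor (0.85) in turn keeps uniform
  regions from splitting on noise alone: a pixel must be ≥ 15 % darker
  than its neighborhood mean to become foreground.

### Segmentation

The largest 8-connected foreground component is taken as the section
(the rind ring); filling its enclosed holes (4-connected background)
yields the whole-section support, and the largest enclosed hole yields
the inner region — the pith support of a pith-filled stem (bundle spots
included, since they are interior to it) or the lumen of a hollow one.
A section whose ring is broken (no enclosed hole) is reported as an
error suggesting threshold review, never silently closed. The
8-connected-foreground / 4-connected-hole pairing is the standard
complementary convention that avoids topological paradoxes.

### Smoothing

Binarization and segmentation reveal small spurious clusters: bright
specks inside the rind (enclosed holes) and dark specks in the pith
(small components). These are cleared by **area gating**: foreground
components of area ≤ `speck_area_frac · |Ω|` are removed and enclosed
holes of area ≤ `hole_area_frac · |Ω|` are filled, with both fractions
defaulting to 0.001 of the whole-section area |Ω|. Gating by area
removes debris without displacing any real boundary. Morphological
opening is available (`opening_radius`, disk structuring element) but
**off by default**: an erosion-based sweep shrinks every boundary by its
radius and would bias diameters and rind thickness by a systematic
pixel offset, which area gating avoids. The gate fractions are
configurable; 0.1 % clears debris one order of magnitude smaller than
the smallest anatomy of interest (a vascular bundle).

The pipeline (remove specks → fill holes → optional opening) is
idempotent: the gates are computed from the filled largest component,
which the operations leave unchanged.

### Morphometry

Boundaries are traced as closed sub-pixel contours (0.5-level marching
squares on the padded mask), canonically oriented counterclockwise.

* **Axis-endpoint diameters**: rays from the whole-mask centroid along
  the four image-axis directions are intersected with the outer
  boundary (outermost crossing per ray); opposite rays pair into a
  horizontal and a vertical chord, and major/minor are assigned by
  magnitude, not axis identity, so arbitrarily oriented sections report
  "major = larger" correctly. Non-star-shaped pathologies (a ray
  missing the boundary) are an error.
* **Feret diameters**: maximum pairwise support distance and minimum
  width over support directions, computed on the convex hull of the
  outer boundary. This is the caliper-measurement convention; it is
  rotation-invariant, and Feret major ≥ axis-endpoint major always.
  The convention is selected per run (`--diameter-convention`).
* **Rind thickness**: for *every* outer-boundary vertex, the shortest
  Euclidean distance to the inner boundary polyline — point-to-segment,
  not point-to-vertex, which removes vertex-density bias — averaged
  over outer vertices. The mean is directed (outer→inner), not a
  symmetric Hausdorff-style mean. Distances are evaluated with
  shapely's vectorized geometry kernel.
* **Areas**: foreground pixel counts divided by `px_per_mm²`.

Angles for the axis convention are anchored at the area centroid (not
the bounding-box center): the centroid is stable under boundary noise
and coincides with the geometric center for the elliptical sections the
method targets.

### Bundle detection and manual edits

Bundles are detected only within the pith: the smoothed foreground is
intersected with the inner mask, labeled 8-connected, and filtered by
area ∈ [`min_area_px` = 25, 2 % of pith area] and circularity
4πA/P² ≥ 0.3. Components above the area cap or below the circularity
gate are returned separately as merged-cluster candidates — touching
bundles are resolved by the user, not by watershed heuristics. The
defaults are package choices (no canonical values exist); all three are
configurable. Hollow sections default to no automatic detection, with
manual points still available.

Manual corrections are a plain-text file (`remove,<id>` /
`add,<x>,<y>`), applied removals-first. The edit operation is
deliberately not idempotent — replaying an edit list against its own
output names the already-removed id — so double application is caught
rather than silently absorbed.

### Geometry export

Boundaries (and auto-bundle outlines) are converted to world mm with
origin at the section centroid and y flipped to point up, matching FE
sketch-plane conventions; the origin choice centers the sketch
conveniently and the y flip converts image-down to world-up. The sketch
script carries, in order: one model-creation statement, a sheet-size
declaration (smallest power of 10 mm exceeding twice the bounding-box
diagonal), one closed-spline command per boundary with coordinates at
fixed 6-decimal precision, and one rename per sketch. The script is
deterministic (byte-identical for identical input) and validated by the
companion parser's exact round trip; executing it inside a commercial
FE package is out of scope. Neutral exports (CSV with full float
precision for exact round trips, GeoJSON, SVG) carry the same splines.
Douglas–Peucker decimation (default tolerance 0.01 mm, applied only to
the FE script) keeps command counts tractable; 0.01 mm is an order of
magnitude below the pixel scale of typical calibrations.

## The phantom generator

Phantoms emulate: a rotated elliptical rind annulus (dark) on a light
background; a lighter pith with dark bundle disks, or a background-lit
lumen; small ellipse-shaped specks of the *opposite* intensity class
inside rind and pith (light in rind, dark in pith), mimicking the
debris that segmentation reveals in real sections; and i.i.d. Gaussian
pixel noise (default σ = 6 gray levels), clipped to [0, 255].

Key properties:

* **Hard edges.** Regions are rasterized without anti-aliasing, so
  pixel membership is exact and recovery tests need no tolerance for
  edge blending. Consequently sub-pixel boundary error in measurements
  comes only from rasterization (±0.5 px), not rendering.
* **Exact ground truth.** Diameters (2a, 2b Feret; axis-endpoint chords
  from the ellipse radius function at the drawn rotation), areas (πab),
  and bundle count/centers are analytic. The true mean rind thickness
  is computed by dense parametric sampling of both ellipses (1024 outer
  probes against a 4096-vertex inner polyline) — exact for concentric
  circles and convergent for ellipses.
* **Well-posed thresholding.** Spec validation requires every pair of
  intensity classes that meet across a boundary to be separated by at
  least 4σ of the noise, so misclassification is a tail event.
* **Placement.** Bundle centers are rejection-sampled inside the pith
  using a Euclidean distance transform for clearance, with pairwise
  separation ≥ `bundle_min_separation` (≥ one bundle diameter) and a
  10,000-attempt cap; failure raises rather than silently placing
  fewer. Specks are placed the same way inside rind and pith, away from
  bundles; a rind too thin to host a speck with clearance sends those
  specks to the pith instead. All randomness flows from one
  `numpy` Generator seeded by the caller, so (spec, seed) → image is a
  pure function, bit-identical across runs.
* **Hollow phantoms carry no bundles** (`n_bundles` must be 0): in the
  measurement workflow hollow species get manual bundle points only.

What phantoms do **not** model: staining variability and color (they
are gray-level), oblique cuts, torn or burnt rinds, texture inside
tissues, vignetting or strong illumination fields, and merged bundle
clusters (bundles are placed non-overlapping; merged-cluster handling
is tested with constructed touching-disk masks instead). Passing the
phantom suite therefore demonstrates geometric and algorithmic
correctness of the pipeline, not robustness to every acquisition
artifact of real microscopy.

## Validation conditions and problem sizes

The standard recovery sweep (used by the test suite and
`scripts/acceptance.py`) draws 50 phantoms: outer diameter uniform on
2–20 mm with the magnification varied so the outer radius spans roughly
100–220 px (as an operator switching between 0.5× and 2× lenses would),
aspect ratio 0.85–1, rind radial fraction 10–35 %, random rotation,
~60 % pith-filled with up to 40 bundles (capped by what physically fits
at the drawn pith size at the enforced separation 2·r_max + 4 px) and
~40 % hollow, 10 specks per phantom, noise σ = 6. Bundle radii scale
with section size so a bundle always sits above the speck-removal gate
and below the per-bundle area cap — the same scale separation real
sections exhibit.

On this sweep the pipeline recovers both diameter conventions with mean
absolute relative error ≈ 0.2 % (R² > 0.999), rind thickness within
≈ 1 % mean (< 0.5 px worst case), and bundle counts exactly; the
smoothing stage clears all planted specks bit-exactly on noiseless
phantoms. These are the numbers `scripts/acceptance.py` recomputes.

## Numerical notes

* Grayscale uses the 0.2989/0.5870/0.1140 luminance weights, rounded
  half-up to 8-bit.
* Otsu is evaluated with vectorized cumulative histogram moments;
  equality of the between-class-variance criterion with the brute-force
  within-class minimizer is asserted test-side over random images.
* 16-bit inputs are rescaled linearly over the full 65535 range;
  grayscale inputs are channel-replicated; alpha channels are dropped.
* Contours from marching squares lie on the half-pixel dual grid, so a
  radius-R disk traces at R ± ~0.5 px; all stated tolerances absorb
  this.
* The px↔mm conversion is an exact bijection up to float round-off
  (< 1e-9 mm round trip); CSV phenotype output prints mm at 4 decimals.
* The measurement pipeline contains no randomness; all randomness in
  the package lives in the phantom generator. Batches process files in
  lexicographic order, and per-image failures are recorded in the run
  manifest without aborting the batch.

## Known limitations

* One section per image; multi-stalk frames are out of scope.
* Broken rind rings (open sections) are an error, not repaired.
* Merged vascular bundles are flagged, never split automatically.
* The adaptive default window (half the image side) assumes the section
  fills a substantial fraction of the frame, as microscope images do;
  for a tiny section in a huge frame, pass a smaller
  `--adaptive-window`.
* The emitted FE script follows the published statement sequence for
  the Abaqus sketch dialect but is validated by round-trip parsing
  only.
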