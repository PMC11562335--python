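# Methods

## Scope and model

`berrymorph` measures separated fruit photographed from directly above on a
uniform stage. Each berry is represented by its binary segmentation mask and
the mask's sub-pixel outer contour; all size and shape metrics derive from
these two objects. Volume and surface area model the berry as a solid of
revolution about its major axis — appropriate for roughly prolate fruit such
as cranberries, and increasingly approximate for lobed or flattened fruit.

## Coordinate and boundary conventions

Image coordinates have the origin at the top-left pixel center, x along
columns, y along rows; angles are measured from +x toward +y. The contour of
a mask is the 0.5-level marching-squares iso-contour, which runs half a
pixel outside the outermost foreground pixel centers. Three consequences are
handled explicitly:

- **Arc length.** The raw iso-contour of a binary mask is a staircase whose
  edge-length sum overestimates a smooth boundary by ~5% (the mean of
  |cos θ| + (√2−1)|sin θ| over directions is 1.055). Arc length is therefore
  measured on the contour after a 5-vertex circular moving average
  (~2.5 px of boundary), which brings a digital circle of radius 100 px
  within 0.4% of 2πr while leaving small shapes sensible (a 10-px square
  measures 36.17). The unsmoothed polygon is retained for extents, convex
  hulls and enclosing circles.
- **Marker diameter.** A marker's pixel diameter is the minimum-enclosing-
  circle diameter of its contour minus 1 px, removing the half-pixel contour
  offset on each side; a rasterized 254-px disk then calibrates to exactly
  100 px/cm for a 2.54 cm marker.
- **Inscribed radius.** The distance-transform maximum measures to the
  nearest background pixel center and is reduced by 0.5 px to refer to the
  mask boundary, consistent with the contour convention.

## Rasterization and grid phase

The synthetic rasterizer marks a pixel foreground iff its center lies inside
the ideal ellipse (no anti-aliasing), so masks are integer-exact and
platform-independent. When the caller does not pin an object's center, the
ellipse is placed at a fixed golden-ratio sub-pixel phase (φ⁻¹, φ⁻²) of the
pixel grid. This matters: if an axis-aligned ellipse is centered exactly on
a pixel row/column (or exactly between two), the per-row width always rounds
the same way along the ellipse's flat equator, and the coherent rounding
residual inflates the solid-of-revolution estimators severalfold (measured:
0.50% volume error for an integer-centered 50×30 px ellipse versus ~0.1–0.2%
at generic phases). A generic phase breaks the lattice resonance; it is a
rasterization convention, not a tuning knob.

## Width profiles and the volume/surface estimators

The width profile samples the mask width orthogonal to the major axis at
every unit step along it. Axis-aligned masks are profiled directly row by
row, width = rightmost − leftmost + 1 (interior holes cannot deflate it;
holes are in any case filled at segmentation). Oblique masks are profiled by
slicing the *exactly rotated* sub-pixel contour at unit spacing:
nearest-neighbor raster rotation was evaluated and rejected because its
jagged integer widths inflate the frustum surface sum by several percent and
break rotation invariance (6% spread across orientations versus ≤1.7% with
contour slicing).

Volume is π Σ (wᵢ/2)² (the π belongs to each cylinder slab's area; summed
over all h slices). Surface area adds unit-height frustum lateral areas plus
the two end-cap disks. Against closed-form spheroid references, on reference
masks with semi-axes 50×30 to 200×80 px at the default grid phase, the
maximum relative errors are **0.20% for volume** and **2.5% for surface
area** (`scripts/acceptance.py` recomputes both).

The volume figure deserves a caveat: per-row widths from a binary mask are
integers, and the resulting quantization error is *correlated* along the
ellipse's flat equator. Across random grid phases the maximum volume error
over these mask sizes has median ≈0.13% and only rarely falls below 0.05%;
a materially smaller error at these resolutions would require sub-pixel
mask information (or much larger masks — the error scales roughly with
size^(−3/2)). The reported 0.20% is the honest value at the package's fixed
generic phase, not a best case selected over phases. Unit tests assert the
measured convergence bound (≤0.5% for semi-axes ≥30 px); the surface
estimator's 5% bound holds with a wide margin.

## Segmentation

Foreground is the union of a colored-object rule (saturation ≥ 0.25, value
within a window, optional hue windows) and a dark-object rule (value ≤ 0.35)
that catches near-black markers, which have no saturation to threshold on.
An `auto` mode infers light/dark background from the border pixels and sets
the value cut by Otsu's method. Cleanup: morphological opening and closing
(disk radius 1), hole filling (specular highlights punch holes; area is
defined on the filled region), removal of components below 256 px, and
removal of components within the morphology radius of the image border
(partial fruit corrupt size metrics; dropped and logged). Components are
markers iff circularity 4πA/P² ≥ 0.85, mean value ≤ 0.20, and area within
[0.25×, 4×] the median candidate-marker area; everything else is a berry.
Classical HSV pipelines of this kind are hand-tuned per imaging setup; all
thresholds here live in `ThresholdConfig` and were fixed on synthetic
fixtures, so they should be revalidated on real stages. Any callable
returning `LabeledMask` objects can replace it (e.g. a neural segmenter).

## Colorimetry

Statistics are computed after eroding a 10-px border (Euclidean disk, via
the distance transform) off the mask; if erosion would empty a small mask,
the full mask is used and the berry is flagged `EROSION_FALLBACK`. Medians
use the lower-median tie rule so 8-bit inputs stay integers. Grayscale
applies Rec.601 weights to the channel *medians*, exactly as the platforms
being emulated report it; per-pixel gray variance accompanies the RGB
variances as the "color variation" measures. CIELAB uses the standard sRGB
decoding under D65 (the sRGB native white; a D50 workflow belongs to
optional color-correction steps outside this package's scope), converting
per pixel and then averaging, rather than converting the mean RGB — the two
differ on shaded fruit. Hue is averaged circularly and reported in degrees.

## Calibration, grid, matching

px/cm is the median corrected marker diameter over the known physical
diameter; markers deviating >20% from the median diameter are excluded
(guards against misclassified round berries). Median aggregation across
markers is a robustness choice. Rows are split where the y-gap between
consecutive centroids exceeds 0.5 × the median mask height — this cleanly
separates gridded stage layouts with jitter up to ~20% of the spacing and
logs a warning when a gap falls near the threshold. Cross-platform matching
pairs berries that are reciprocally each other's nearest centroids, with no
distance cutoff (distances are returned so callers can filter); the
implementation is exact and is tested against a brute-force O(n²) oracle.

## Pipeline and QC

Per image: segment → classify → calibrate → measure (shape on the full
mask, color on the eroded mask) → grid-assign → flag. Runtime QC flags:
`LOW_SOLIDITY` (solidity < 0.95, the signature of a bad segmentation),
`AREA_OUTLIER` (area > 3 SD from the image mean; impossible for single-berry
images), plus `BORDER_TOUCH` and `EROSION_FALLBACK` for conditions that
silently bias metrics. CSV output is RFC 4180 with a fixed header, floats at
4 decimals, rows sorted by (image, row, col, index); both px and cm columns
are always present, cm empty when no markers were found. The pipeline is
deterministic: identical input and configuration give byte-identical CSVs.

## Platform statistics

`rmd` normalizes the mean paired difference by the *smaller* within-platform
range, making effect sizes comparable across traits of different scales;
its sign convention is x (this implementation) minus y (the reference).
Population min/max pool all matched berries. Paired t-tests are reported
unadjusted: with thousands of matched berries, even negligible differences
are significant, so rmd — not p — is the quantity to interpret.

## Synthetic scenes: what they do and do not show

The generator emulates gridded stage photographs: shaded elliptical berries
(radial linear darkening toward the rim, mimicking the specular/shadow
structure that motivates border erosion), optional wedge notches (to
exercise the solidity QC), near-black markers, uniform background, seeded
jitter. Defaults are scaled so a 100-px marker (39.4 px/cm) yields berries
averaging ≈2.0 × 1.7 cm with colors drawn from a dark-red palette —
realistic cranberry values at a test-friendly resolution. Scenes are
rendered without anti-aliasing, compression, lighting gradients, occlusion
or non-target objects, so passing tests demonstrate the correctness of the
measurement pipeline on clean input, not segmentation robustness on real
photographs; the thresholding defaults in particular should be revalidated
on each real imaging setup.

## Known limitations

- The volume estimator's accuracy at small mask sizes is quantization-
  limited (see above); report volumes from masks with minor semi-axis
  ≥ 30 px where possible.
- Solidity can exceed 1 by <1% for convex masks (pixel-count area vs
  sub-pixel hull area); values are left unclipped.
- Overlapping or touching fruit are not separated; grid assignment assumes
  an approximately gridded layout when `grid_mode` is on.
- The classical segmenter assumes a clean, roughly uniform background and
  no non-target objects (no label cards or color charts).
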