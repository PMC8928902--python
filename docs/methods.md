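# Methods

This note documents the measurement model implemented by `fishsizer`, the
conventions behind every tunable parameter, what the synthetic fixture
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Imaging model and coordinates

All processing happens on a grayscale intensity field in [0, 1] on a pixel
grid with 0-based coordinates, x = column, y = row, y increasing downward.
Integer rasters are rescaled by their dtype maximum; RGB images are
reduced to luminance with ITU-R BT.601 weights (0.2989, 0.5870, 0.1140) —
a fixed, documented convention; any other standard would change results
negligibly for the gray-on-gray scenes this tool targets. Rectangle
regions of interest are half-open pixel bounds so that areas are exact
integer products; circle ROIs include a pixel when its center lies within
the radius. Images smaller than 8×8 are rejected outright.

## Segmentation

1. **Preprocess.** Gaussian blur at σ (default 4 px), then unsharp
   masking at the same scale: `out = b + amount · (b − G_σ(b))` with
   `b = G_σ(image)` and gain `amount` = 0.8, clipped to [0, 1]. The blur
   spreads contrast from strong neighboring edges into short low-contrast
   gaps of the outline, and the sharpening restores edge amplitude, so
   faint gaps of a few pixels become detectable. σ = 0 disables the stage.
2. **Edges.** Sobel gradient magnitude, thresholded at
   `threshold_fraction` (default 0.55) of the *maximum* gradient inside
   the ROI. Both the maximum and the returned edges are ROI-restricted; a
   numerically flat ROI (max gradient ≤ 1e−12, the double-precision noise
   floor for unit-range intensities) raises a "no contrast" error rather
   than thresholding noise.
3. **Closure.** Binary dilation with a square element of radius
   `dilation_factor` (default 3; side 2·f+1) followed by erosion with a
   diamond of the same radius. The square dilation bridges diagonal as
   well as axial gaps; the diamond erosion pulls the exaggerated outline
   back without reopening them. Factor 0 is the identity. Dilation pads
   with background and erosion pads with foreground, so structures that
   touch the border keep their border contact — essential for the next
   step to reject them.
4. **Regions.** Background cavities not connected to the border
   (4-connected background) are filled; then every 8-connected component
   touching any border is discarded. Water drops that cross the frame
   produce border-to-border arcs and are eliminated here regardless of
   their contrast.
5. **Selection.** The largest remaining 8-connected component is the
   larva, provided its area reaches `min_area_fraction` (default 0.05%)
   of the ROI pixel count — a floor that keeps artifact residue from
   winning on images without a larva. Centroid and orientation come from
   the region's second central moments: the major-axis angle of the
   moment-equivalent ellipse, reported in degrees from the +x axis,
   counterclockwise positive in a y-up sense, range (−90, 90].

The pipeline is deterministic, translation-equivariant for bodies away
from the border, and the edge-pixel count is monotone in the threshold.

## Morphometry

The mask is rotated by the negative of its orientation about the image
center (nearest-neighbor, enlarged canvas, zero padding), bringing the
body axis within a few degrees of horizontal. Conventions:

- **Head end**: the half of the x-extent with more mask pixels; ties go
  left. This encodes the biological assumption that the anterior half
  (head plus yolk) is heavier. Uniform-depth bodies have no defined head.
- **Midline order rule**: an ordinary least-squares quadratic is fitted
  to the *tail-half* pixels with x shifted so the tail half starts at 0
  (the shift is part of the convention — the thresholds are dimensional).
  If |a₂| > `order_threshold_a2` (default 0.1) or |a₁| >
  `order_threshold_a1` (default 0.5), strictly, an order-3 midline is
  used for the whole body; otherwise order 2. Boundary values keep order
  2. The thresholds are scale-dependent: images at a very different
  magnification than the ~10² px-deep bodies assumed here may need them
  rescaled, which is why they are configurable.
- **Midline fit**: least squares over all mask pixels by default; a
  per-column-centroid variant (`midline_fit="column_centroids"`) is
  available and agrees on vertically symmetric bodies. At least order+1
  distinct columns are required.
- **Length**: arc length of the fitted polynomial over the mask's
  x-extent [x_min, x_max], by adaptive quadrature (relative tolerance
  1e−9, far below the 1e−4 the validation demands). Arc length always
  dominates the chord, so length ≥ x-extent.
- **Depth**: the target column lies `depth_offset_percent` (default 50)
  of the x-extent from the head end; every integer column within
  ±`depth_window_percent` (default 5) of the extent contributes its
  vertical extent, and the median over non-empty columns is reported.
  Column depth is inclusive — max y − min y + 1 — so a one-pixel band
  has depth 1, not 0; `inclusive_depth=False` selects the bare
  difference. Windows at offsets 0 or 100 are clipped to the mask extent
  instead of erroring.

Manual measurements are sums of Euclidean polyline segment lengths, the
same arithmetic used for drawn lines in standard image-analysis tools;
they override the automated value in the exported table without erasing
it, and can be cleared to revert.

## Calibration and export

A calibration is `px_per_mm = |p₂ − p₁| / known_mm` from two points
spanning a known distance; it round-trips through a flat key-value text
file without precision loss, and millimeter values are pixel values
divided by the scale. The CSV schema is fixed: `FileName, Length_px,
LengthAutomated_px, Depth_px, DepthAutomated_px`, plus `Length_mm,
LengthAutomated_mm, Depth_mm, DepthAutomated_mm` when calibrated.
Numeric cells carry 4 decimal places (measurements are tens to hundreds
of pixels, so this preserves at least 6 significant digits in practice);
failed files appear as rows with empty numeric cells; excluded records
are omitted. Batch outlier flags (median ± 3.5 × MAD per dimension,
unscaled MAD, advisory only) stand in for visual inspection of the
per-batch scatter.

## Synthetic fixture generator

The generator is the package's validation instrument: it renders the
scene the segmentation assumes — one elongated, curved, tapered body on a
uniform background — from an analytic description with exact ground
truth.

The body is the set of pixels within a half-depth profile h(u) of a
polynomial midline, with the half-depth measured **vertically**, not
normal to the curve. This choice makes the generator's depth ground truth
identical in definition to the column scan the measurement stage
performs, so depth comparisons are exact rather than approximate; for the
gentle slopes generated by default (|f′| ≲ 0.3) the difference from
normal-depth is under 5%. Three profile families give the head rule a
defined truth: `tapered` (h = h_max · (0.4 + 0.6·(1−u)^e)), `yolk_bulge`
(0.55·h_max plus an anterior Gaussian bulge), and `uniform` (no defined
head side, excluded from head-side assertions). The band is rasterized
horizontally, optionally mirrored, rigidly rotated about the canvas
center (nearest neighbor, fixed canvas), and truncated Gaussian noise is
added last, from the spec's seed. Ground truth (dense-polyline arc
length with 10⁴ segments, windowed-median depth on the pre-rotation
raster, head side) is computed before noise. A spec whose rotated body
would come within 5 px of a border is rejected.

Default ranges emulate a stereomicroscope camera frame: 1200 × 1600 px
canvas; body span 700–950 px; maximum half-depth 60–100 px, i.e. a
depth/length ratio of roughly 0.13–0.22, typical of yolk-sac and
preflexion larvae; body 0.15–0.35 against background 0.70–0.85 intensity
(contrast ≥ 0.35); noise σ up to 0.05; rotation within ±25°; curvature
bounded by |a₂|·span ≤ 0.6 (up to ~140 px of sag — a clearly but
moderately curved larva). Artifacts reproduce the four contaminants seen
on real slides — faint scratches, high-contrast water-drop arcs that
touch a border, scale bars with ticks, and text boxes with glyph-like
strokes — and are placed with a seeded retry loop that keeps them off an
8-px dilation of the body.

**What the generator does not emulate** — and therefore what passing
tests do not establish about real data: body texture, pigmentation and
fin rays; partial transparency and internal edges (gut, otoliths); uneven
illumination; optical blur of the body boundary; artifacts in contact
with the larva. On real images the practical failure modes are exactly
those (the tool's workflow assumes visual QC of every segmentation), so
the synthetic accuracy rates below characterize the geometry pipeline,
not field performance.

## Accuracy characteristics and numerical choices

The segmentation halo is the dominant, well-understood bias: with σ = 4
smoothing, the gradient band around a clean step boundary stays above
0.55 of its peak for roughly ±4 px, and the square-dilate/diamond-erode
pair preserves the band's outer extent, so the mask boundary sits ~4 px
outside the true body everywhere. Length (800–950 px) inherits a ~+1–3%
bias; depth (70–160 px at the midpoint) inherits ~+6–12%. That is why the
validation bands differ: length is checked at ±5% and depth at ±10% of
ground truth, with expected pass rates of ≥89% and ≥70% over 100 seeded
default-range specs — the acceptance script reproduces both from
scratch. Jaccard overlap between mask and truth stays above 0.8 across
the sweep.

Other numerical decisions: rotation uses nearest-neighbor interpolation
(a mask stays binary; pixel counts are preserved within a few percent);
the moment-orientation convention is exactly mirror-antisymmetric, which
makes the whole pipeline mirror-equivariant to the pixel on noiseless
renders; head-count ties and the tail-half boundary (x at the midpoint of
the extent) are fixed, documented tie-breaks; the arc-length quadrature
and the generator's polyline oracle are independent routes that agree to
1e−4 relative on the same polynomial.

Problem sizes in the shipped tests were chosen to keep the whole suite
around a minute: the accuracy sweep uses the full-size default canvas
(100 images, shared across tests via a session fixture), while unit tests
that only need a valid larva render at a 240 × 320 px canvas with
proportionally smaller bodies.

## Known limitations

- Single larva per image; overlapping or multiple animals are out of
  scope.
- The order-rule thresholds (0.1, 0.5) are tied to the pixel scale of the
  default geometry; magnifications far outside it need re-tuning.
- The contrast threshold is relative to the ROI maximum: a high-contrast
  artifact *inside* the ROI raises the threshold and can suppress genuine
  body edges; the ROI exists precisely to exclude such objects.
- Depth at offsets near 0 or 100 depends on a clipped, asymmetric window
  and is less stable than mid-body measurements.
- The halo bias described above means depth is systematically
  overestimated by roughly the edge-band width; comparisons between
  treatments imaged identically are unaffected, absolute values carry
  the bias.
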