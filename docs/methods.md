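# Methods

`phenokit` extracts quantitative plant traits from single photographs using
purely classical image analysis: global and color thresholding, mathematical
morphology, the marker-controlled watershed, robust line fitting,
polynomial axis regression, skeletonization, and 1-D clustering. Everything
is deterministic given an input image, a configuration, and a seed. This
note records the models, the parameter choices that matter, the design
decisions taken where the design was genuinely open, what the synthetic
scenes do and do not emulate, and the known limitations.

## Scale calibration

Two reference objects are supported.

**Coin.** The luminance channel (ITU-R BT.601 weights, rounded to 8 bits)
is binarized at the threshold maximizing between-class variance; for each
connected component the contour circularity 4πA/P² is computed on the
smoothed traced boundary, and the most circular component with circularity
≥ `circularity_min` (default 0.85) and equivalent radius ≥ `min_radius_px`
wins, ties to the larger radius. The scale is `mm_per_px =
coin_diameter_mm / (2 · radius)` with the radius taken as √(A/π) — for a
clean disc this is less sensitive to boundary quantization than a
least-squares circle. The coin's physical diameter is configuration
(default 25.0 mm); no denomination recognition is attempted. Because ripe
fruit can be as circular as a coin, the pipelines first black out pixels
with HSV saturation above `coin_max_saturation` (default 0.30): coins are
metallic grey, fruit and seeds are not. The minimum-radius gate (pipeline
default 40 px) additionally keeps small round seeds from masquerading as
the coin; with a 25 mm coin this assumes the coin spans ≳ 80 px, true for
any sensible close-range capture.

**Rectangular field marker.** Near-white pixels (all channels ≥
`whiteness_threshold`, default 210) are extracted, the largest component's
outer contour reduced to four corners (farthest-pair diagonal plus the
extreme point on each side, refined by total-least-squares line fits to the
four edge segments and corner-point intersection — sub-pixel corners).
Verification requires convexity and all interior angles within
`right_angle_tol_deg` (default 15°) of 90°, an operationalization of marker
verification suitable for near-top-down capture; strongly oblique views
will be rejected rather than mis-measured. Because only the outer contour
is used, filled rectangles and rectangular frames both work; the marker's
real-world size refers to the outer extent of the white border.
Rectification estimates the homography mapping the four corners to an
axis-aligned rectangle whose pixel aspect equals the real aspect and whose
area equals the detected quad's area, then warps the image (bilinear). The
marker calibration is `real_width_m · 1000 / target_width_px`.

Unit conversions are linear in `mm_per_px` for lengths, quadratic for
areas, and `(mm_per_px/1000)⁻²` for count densities (per px² → per m²).
Uncalibrated values are returned flagged rather than raised.

## Segmentation and adhesion splitting

The intensity threshold is the exact argmax of ω₀ω₁(μ₀−μ₁)² over all 256
levels (foreground strictly above the threshold; ties to the lowest level).
An `otsu_effectiveness` score (between-class variance over total variance)
guards region-restricted thresholding: a near-unimodal histogram — a marker
interior containing nothing but sensor noise — scores low (< 0.75 by
default) and yields an empty detection instead of segmented noise.

Color segmentation uses inclusive HSV bounds with wrap-aware hue (the red
tomato band [340°, 20°] crosses 0°). Cleanup is morphological opening with
a disc element followed by removal of components smaller than
`min_area_px`. Connected components use 8-connectivity by default;
4-connectivity would fragment anti-aliased boundaries of real photographs.

**Touching objects.** Instances whose convex-hull solidity falls below
`solidity_threshold` are candidates for splitting: the Euclidean distance
transform (EDT) of the instance is computed, its local maxima at least
`peak_min_distance` apart seed a watershed of the negated EDT, and the
resulting pieces are kept only where the cut crosses a genuine
constriction — adjacent pieces are merged back when the EDT along their
shared ridge exceeds `neck_ratio` (default 0.9) times the smaller of their
peak EDT values. The two-stage design reflects a measurement made during
development: the solidity distributions of fused ellipse pairs (up to
≈ 0.96 at 30% minor-axis penetration) and of single small rasterized
ellipses (down to ≈ 0.92) overlap, so no single solidity threshold can both
trigger on true fusions and spare intact objects. The gate is therefore
generous (default 0.97) and the neck test does the discriminating: a single
ellipse cut along its ridge has neck ≈ peak and is merged back; a true
fusion has a waist. `peak_min_distance` should be set to about half the
expected minor-axis length of one object (6 px suits the default seed
scenes; 10 px suits the larger spikelets). Splitting never loses or gains
foreground pixels and never decreases the instance count.

Known limitation: a pair fused with no waist at all — a small ellipse
absorbed side-on into a larger one, or two near-parallel ellipses merged
into a smooth capsule — has a single EDT basin and cannot be split by any
watershed-on-EDT method. At 30%-of-minor-axis penetration this affects
roughly 1 pair in 100; aggregate count recovery on trays with five touching
pairs per scene stays above 95%.

## Morphometry

Per instance: area is the pixel count; the perimeter is the length of the
marching-squares boundary polygon after a 5-vertex circular moving average
(the raw digital contour zigzags and overestimates a circle's circumference
by ≈ 6%; smoothing brings a disc to within ≈ 1% while rounding corners only
at sub-pixel scale); length and width are the side lengths of the
minimum-area rotated rectangle over the instance's pixel squares (convex
hull of boundary-pixel corners → rotating-calipers rectangle via shapely),
chosen over an ellipse fit for robustness on angular seeds and kernels and
recorded in output metadata so users can compare conventions; aspect ratio
is length/width; compactness is 4πA/P² (1 for a disc); equivalent diameter
is 2√(A/π). Tomato "diameter" is reported as the equivalent diameter and
tomato "width" as the rectangle width, since both appear as separate
traits. The green ratio is the fraction of mask pixels inside a green HSV
band (default hue 60–180°, saturation ≥ 0.15, value ≥ 0.10). The canopy
pipeline measures the largest connected component with interior holes
filled, so area and compactness describe the projected crown region rather
than the leaf-pixel set.

## Axes and angles

The spikelet major axis is fitted by two-point-sample RANSAC (default 200
iterations, seeded, recorded) with a total-least-squares refit on the
best inlier set. On short filled ellipses a thin inlier band wobbles by
several degrees, so the spikelet pipeline widens the band to the instance's
half-width (twice the minor-direction standard deviation of its pixels) —
the refit then sees the whole body and the direction error drops below 1°.

The rachis (ear axis) is a polynomial fitted to the spikelet midpoints in a
PCA-rotated frame (independent coordinate along the principal direction).
Spikelets attach alternately left and right, so midpoints zigzag around the
true axis; the pipeline selects the degree (1 up to `ear_axis_degree`,
default 3) by BIC so a straight rachis is not bent around the zigzag.
Spikelet angles are measured between the spikelet axis and the rachis
tangent at the axis coordinate of the orthogonal projection of the spikelet
center, folded to [0°, 90°] since chirality is not distinguished.

Thinning is the classical two-subpass parallel algorithm (neighbor count
in [2, 6], exactly one 0→1 transition around the ordered neighborhood, and
the two compass-product conditions per subpass) iterated to a fixed point;
the output is always a subset of the input and idempotent. It differs in a
small fraction of pixels from other published variants of the same scheme
(tests assert the properties plus structural agreement with scikit-image's
implementation, not bitwise equality).

The flag-leaf angle takes four keypoints: stem base A, spike tip B, leaf
node C, and a leaf reference L — the keypoint triple alone fixes no leaf
direction, so L (leaf bounding-box center or user-clicked leaf tip) is an
explicit extra input. Two modes are provided, neither asserted as the only
correct reading: `node_stem_leaf` (default) is the angle at C between C→B
and C→L in [0°, 180°]; `stem_axis_leaf` is the angle between the undirected
stem line A→B and C→L, folded to [0°, 90°].

## Kernel rows

Kernel centroids (from the classical yellow-blob backend or an external
detector via CSV) are centered and rotated so the first principal component
— the ear's long axis — becomes x, with the sign convention that the span
ahead of the first point toward +x is maximal. Rows are clusters of the
cross-axis coordinate y: for each candidate row count k in
[`k_min`, `k_max`] (default [4, 24] for maize) a 1-D K-means (k-means++
initialization, 10 restarts, seeded) is fitted and scored by mean
silhouette; the best k wins, ties to the smaller k, and k = 1 is allowed
only when `k_max` = 1. The silhouette is computed exactly with per-cluster
sorted prefix sums in O(n·k·log n) — the generic pairwise computation
dominated the k-scan's runtime — and is verified against the generic
implementation in a test. Only visible-face rows are reported; an optional
`row_multiplier` exists because single-view "row count" semantics are
ambiguous, and no hidden extrapolation is applied.

## Pipelines

All seven pipelines run behind one interface returning calibration, traits,
per-instance records, and a provenance block (package version, SHA-1 of the
configuration, seed, backend name). Detections enter through a minimal
backend contract (a mask or a point set, deterministic per configuration),
so learned detectors can replace the classical defaults without touching
measurement code. Coin pixels are excluded from trait masks (detected
radius + 2 px). Yield for wheat plots is `density · grain weight per head`,
reported in kg/ha only when the user supplies the per-head weight — there
is no defensible hidden default. Running a pipeline twice on the same input
yields byte-identical result JSON.

## Synthetic scenes

Each generator is a pure function of its spec (including the seed) and
emulates one recommended capture setup: top-down seed trays and tomato
scenes on near-black backgrounds with a grey coin; a side-view wheat ear
with spikelet ellipses placed alternately along a mild random cubic at a
fixed angle to its tangent (centers offset ± 8 px to the side opposite
their tilt, as on a real rachis); a kernel lattice with controlled pitch,
jitter, and global rotation; a canopy silhouette (disc, star, or random
blob) textured green/brown at an exact pixel fraction; and a field plot
whose white marker frame is drawn under an exact projective homography with
head-like blobs placed sequentially (dart throwing) at a set density inside
it. Rasterization is analytic — a pixel belongs to a shape iff its center
satisfies the shape inequality — with no anti-aliasing, so ground-truth
masks are exact; background noise is additive Gaussian (σ = 5/255 by
default). Touching seed pairs are placed by bisecting the true tangency
distance of the two oriented ellipses (shapely) and then penetrating by a
drawn fraction (≤ 30%) of the smaller minor semi-axis, so fusion depth is
controlled regardless of tilt.

What the scenes do **not** emulate: anti-aliased and motion-blurred edges,
shadows and specular highlights, uneven illumination, lens distortion,
occlusion by overlapping organs in depth, and natural shape variation
beyond ellipses and blobs. Passing the synthetic suite therefore
demonstrates that the measurement chain is correct and well-calibrated on
its stated model, not that detection is robust to field imagery — robust
detection is exactly what the pluggable learned backends are for.

## Evaluation harness and problem sizes

The soundness harness regenerates, per pipeline, on the order of a hundred
scenes with varied generative parameters (counts 10–80 per tray, tomato
radii 30–55 px, spikelet tangent angles 20–50°, canopy green fractions
0.2–0.85, 8–18 kernel rows, plot densities 25–90 heads/m²), runs the
pipeline, and reports predicted-versus-truth R². Harness scenes use
moderate rasters (roughly 450–850 px on a side) — large enough that
discretization is far below the effect sizes, small enough that a hundred
scenes per pipeline remain cheap; the generators accept larger specs when
fidelity matters more than throughput. Typical results: R² = 1.0 for
counts, ≥ 0.93 for continuous traits (the residual for mean seed length is
rasterization noise on the minimum-area rectangle).

## Numerical choices and degenerate inputs

Ties in the threshold criterion go to the lowest level; ties in row-count
selection to the smaller k. Angle computations clip cosines to [−1, 1].
Coincident points, collinear marker corners, empty masks, too-few centers,
and out-of-domain curve evaluations raise typed errors rather than
returning garbage. The EDT of an instance is computed on a zero-padded
crop so tight bounding boxes do not inflate border distances. All
randomness (RANSAC sampling, K-means restarts, scene generation) flows
from explicit seeds recorded in provenance.
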