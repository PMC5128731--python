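# Methods

This note records the model behind each pipeline stage, the parameters that
matter, what the synthetic phantoms do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Scope and processing model

Segmentation is strictly two-dimensional: each axial slice is processed
independently, and the volume result is the stack of slice results. The one
volume-level quantity is the tilt angle, estimated once from a mid-thoracic
slice and applied to all slices — per-slice alignment would let neighboring
slices rotate by slightly different angles and break inter-slice
consistency. The pipeline is fully deterministic: identical input and
configuration produce bit-identical masks.

## Alignment

Bone voxels (above `bone_threshold`, default +200 HU, the usual cortical
bone cutoff) are collected on the slice and PCA is applied to their (x, y)
coordinates (x = column, y = row). The first principal component μ is
sign-normalized to a non-negative x-projection and the tilt is
φ = arctan(μ_y / μ_x) ∈ (−90°, 90°], the signed angle between the bony
lateral axis and the image x-axis. In a supine patient the rib/spine cloud
is much wider than it is tall, so μ is horizontal and φ ≈ 0; a patient lying
on their side rotates μ with the body.

Rotation is *gated*: only |φ| > `align_gate_deg` (default 15°) triggers the
inverse rotation (bilinear, about the image center). The gate exists because
the diagonal start-point search below tolerates mild tilt, and avoiding
needless resampling preserves the original intensities. On phantoms the
estimate recovers synthetic tilts of 16–45° to within ~0.3°.

## Chest mask

Otsu binarization (foreground above threshold), opening with a disk of
`opening_radius` (default 3 px — removes salt noise and bed-sheet-thin
structures at 0.6–0.7 mm pixels without eroding the chest wall), largest
8-connected component, hole filling (so the lungs lie inside the mask).

One numerical subtlety: on images with few distinct gray levels (phantoms,
8-bit data) the Otsu threshold is computed on the exact value histogram
rather than 256 uniform bins. With coarse uniform bins the returned bin
center can sit just *below* a populated level, silently flipping that level
across the foreground convention (`pixel > threshold`); exact-value bins
make the split unambiguous. Quasi-continuous images fall back to 256 bins.

## Contour initialization

Within the chest, pixels below the slice's Otsu threshold are lung-air 0s;
everything outside the chest mask is forced to 1 so the diagonal scan cannot
trigger on background air. The major diagonal is scanned top-left to
bottom-right; the first run of ≥ 3 consecutive 0s encountered after at
least one 1 is the left-lung entry (the run-length requirement skips
isolated noise pixels; the preceding-tissue requirement makes sure the scan
has entered the body). The minor diagonal finds the right lung. If a
geometric diagonal misses a lung (off-center anatomy), parallel diagonals
offset by ±1, ±2, … px are scanned until a start is found.

Border following is Moore-neighbor tracing: from the current boundary pixel
the 8 neighbors are examined clockwise starting just past the backtrack
position; termination uses the two-point overlap rule (stop when the last
two visited pixels repeat the first two), plus a state-repetition stop
(returning to the start pixel with the starting backtrack) as a safety net.
By default a diagonal move also visits the intervening 4-neighbor region
pixel (`visit_inner_corners`), so the traced set equals exactly the set of
region pixels with a background pixel in their 8-neighborhood — including
pixels whose only background contact is diagonal, which classic Moore
tracing shortcuts past. Inner corners crossed in both directions are
deduplicated afterwards where 8-adjacency allows, keeping the contour free
of repeated points on regular shapes. The classic chain (shortcuts allowed)
remains available via the flag and is the natural representation of a
"staircase" boundary for smoothing studies.

## Left/right separation

A slice whose candidate lung region forms a single 8-connected component is
split in two stages:

* **Erosion + constrained reconstruction** (primary — it is the variant
  specified by explicit morphology): iterate erosion with the 4-neighbor
  diamond B₄ until the component count reaches 2 (budget
  `erosion_max_iters` = 20: at ≤ 0.75 mm/px even a 15 mm junction is far
  thinner than 20 erosions), then grow the parts back inside the original
  mask by conditional dilation that never merges components. The
  reconstruction claims pixels FIFO over the dilation frontier; a pixel
  whose 8-neighborhood touches two different components is permanently
  blocked, which leaves the one-pixel-wide cut. The operation is
  idempotent and preserves the seed's component count by construction.
* **Maximum-cost path** (fallback, used when erosion exhausts its budget or
  vanishes the mask): dynamic programming finds the top-to-bottom path of
  maximal summed intensity — the bright junction tissue — with column moves
  in {−1, 0, +1}, restricted to the central third
  (`dp_band_fraction` = 1/3) of the mask's bounding-box columns, where the
  anterior/posterior junction lies. Ties prefer straight, then left, and
  the leftmost final column, for determinism. The mask is cut along the
  path (diagonal steps widen the cut by one pixel so 8-connectivity cannot
  leak across).

The two largest resulting components are labeled left/right by centroid
column (image convention; a CLI flag swaps to radiological labels).

## Smoothing

The traced pixel chain is resampled with a periodic cubic spline at uniform
arc-length spacing `arc_step` (L = 0.3 px; the point count is
round(perimeter / L), with the actual spacing perimeter/count so the closure
gap is uniform too). Each smoothing pass fits, around every point, degree-n
polynomials x(s), y(s) over the 2k + 1-point window with fixed abscissae
0, L, …, 2kL by least squares, and replaces the point with the fitted value
at the center s = kL. Because the abscissae are uniform, the fit reduces to
a fixed convolution kernel (the center row of the Vandermonde projection),
applied cyclically — data exactly on a straight line or on a degree-n arc
are reproduced exactly, and the normal equations cannot degenerate.
Defaults n = 2, k = 4, M = 12 passes; passes stop early when the perimeter
change drops below `t2_perimeter_tol` (T₂ = 0.01 px).

On staircase-rasterized circles the perimeter decreases monotonically and
converges under T₂ to within 2% of 2πr; full convergence takes ~60–90
passes, while the M = 12 default already lands within ~1.5% and is the
right cost/benefit for production use.

## Concave detection and correction

Thresholding excludes a juxta-pleural nodule from the lung, so the
parenchyma border dips around the nodule: a concave region. Detection
marches the clockwise contour (interior on the right) with the right-hand
rule, implemented as a monotone convex-chain sweep: starting from the
topmost point (always convex), the chord chain extends while the next point
lies to the right of the current direction and pops otherwise; every
stretch skipped between chain anchors is a concave region. Three numerical
refinements matter in practice:

* The chain is built on a copy of the contour low-pass filtered along arc
  length (Gaussian, σ = 2 px). Residual raster ripple (~0.5 px amplitude
  left by finite smoothing passes) otherwise fragments one deep notch into
  shallow pockets with wildly overshooting chords. All *measurements* are
  taken on the unfiltered points.
* On a curved convex boundary the chain contacts land where the boundary
  tangent turns parallel to the chord — beyond the true indentation mouth.
  The mouth is therefore recovered from the depth profile: starting at the
  deepest point, walk outward until the perpendicular depth first falls
  below max(1 px, 10% of depth), then continue down the strict descent to
  the local minimum (the mouth corner, or the tip of the thin parenchyma
  tongue flanking a nodule). Constructed geometry (e.g., a rectangular
  notch of mouth 4 and depth 10) is still measured exactly (W = 4, H = 10,
  η = 2.5).
* Regions spanning fewer than `march_step` contour points (default 5 ≈
  1.5 px of arc) are ignored as sampling noise.

Each region gets its chord width W, maximum perpendicular depth H, and
ratio η = H / W. Regions with η > `t1_ratio` (T₁) are replaced by the
straight chord resampled at spacing L; the detect/replace cycle repeats
until the perimeter changes by less than T₂ (normally 2 iterations). The
enclosed area never decreases — every replaced arc dips inside its chord.

**Choice of T₁ = 0.6.** T₁ trades missed nodules against oversegmentation.
Measured on the phantom family across the full 6–17 mm diameter range, the
notch of a disk-shaped juxta-pleural nodule presents η ≈ 1.0–1.8 after
smoothing — lower than the idealized "deeper than wide by construction"
intuition suggests, because the sub-pixel parenchyma wedge flanking the
nodule is lost to rasterization and the mouth opens wider than the
geometric disk–boundary intersection. Benign features (raster ripple,
separation stubs, wide shallow anatomical bays such as the hilum in real
scans) stay below η ≈ 0.5. T₁ = 0.6 separates the two populations with
margin on both sides; it is exposed in the configuration for data where
the balance differs.

## Rasterization

The corrected closed curve is scan-filled (pixels whose centers fall inside
the polygon; orientation-independent), intersected with the chest mask, and
written into the labeled output (0 background, 1 left, 2 right).

## Evaluation metrics

For automatic mask A and manual reference B with voxel spacing in mm:
VD = (|A| − |B|)·v in cm³; RVD = 100·(|A| − |B|)/|B| (positive =
oversegmentation); VOE = 100·(1 − |A∩B|/|A∪B|). Surface voxels are mask
voxels with a background face-neighbor (outside the array counts as
background). With d(v, S) the shortest Euclidean distance in mm, ASD is
the symmetric mean of d over both surfaces, RMSD the symmetric quadratic
mean, MSD the symmetric maximum (Hausdorff); ASD ≤ RMSD ≤ MSD by the
power-mean inequality. Distances are computed with an exact Euclidean
distance transform (anisotropic sampling) and validated against an
all-pairs brute-force oracle at 1e-9 relative tolerance in the tests. The
cumulative distance distribution is the empirical CDF of d(s, S(B)) over
s ∈ S(A).

## The phantom generator

Each slice is painted analytically: an elliptical body (+40 HU) on air
(−1000), two elliptical lungs (−800), a spine blob and mirror-symmetric rib
pairs (+400) whose lateral spread dominates their vertical spread (so the
bone PCA is exactly horizontal in an untilted scan), optional additive
Gaussian noise (applied last, seeded), and optional in-plane tilt. Tilt is
applied by transforming pixel coordinates through the inverse rotation and
testing membership against the untilted primitives, so truth masks are
exact at every angle and a noise-free image contains exactly the configured
intensity levels. Default geometry: 256×256 px at 0.7 mm/px (inside the
0.625–0.742 mm range typical of thoracic CT).

*Nodules* are disks of diameter 6–17 mm at soft-tissue intensity (+20 HU),
centered inside the lung at depth `depth_frac`·r (default 0.95) from the
pleural boundary along the inward normal — a nodule embedded in the
parenchyma that just breaks the pleural surface, the canonical
juxta-pleural presentation whose thresholding notch is deeper than wide. A
more protruding placement (center at or beyond the boundary) erases the
pleural line over a stretch comparable to the diameter and degenerates the
notch into a wide shallow bay that no aspect-ratio threshold separates
from anatomy.

*Fused-lungs mode* adds a lung-density bar (default 3 px tall) joining the
two lungs near the anterior midline, producing the single-component slices
the separation stage needs; truth left/right masks split the bar at the
midline.

*Volumes* stack per-slice phantoms with lung semi-axes scaled by a
sinusoidal apex-to-base profile (0.75–1.0 by default), nodules rendered on
the central half of slices.

What the phantoms do **not** emulate: airways and vasculature, lung
texture, beam-hardening and partial-volume artifacts, non-elliptical
anatomy, pleural effusion, and irregular or ground-glass nodules. Passing
the phantom studies therefore demonstrates the geometric correctness and
robustness of every stage under noise, tilt, fusion and juxta-pleural
occlusion — not clinical-grade accuracy on hospital scans, which requires
real annotated data.

## Problem sizes used in validation

The validation studies (also run by `scripts/acceptance.py`) use: 100
random bimodal 8-bit images for the Otsu oracle; 200 random grids ≤ 6×6
for the path-search oracle (3^(rows−1) enumeration); 50 random ≤ 20³ mask
pairs for the metrics oracle; 50 random blob fixtures for the tracing
oracle; tilts {16°, 20°, 30°, 45°} plus four within-gate angles for
alignment; 20 seeded fused-lung phantoms for separation; staircase circles
r ∈ {20, 30, 50} px for smoothing; 50 seeded single-nodule phantoms
(diameter uniform in [6, 17] mm) for nodule recovery; and a 20-slice
256×256 phantom volume, run twice, for the end-to-end check.

## Known limitations

* Strictly 2D: no inter-slice regularization; a nodule spanning slices is
  corrected slice by slice.
* The correction bridges *any* sufficiently deep concavity — a deep benign
  indentation (η > T₁) would be filled too; T₁ is the only guard.
* Alignment assumes the bone cloud's principal axis is the lateral axis;
  severe scoliosis or a missing spine would bias φ.
* The diagonal search assumes the lungs straddle the image diagonals after
  alignment; the parallel-offset fallback covers moderate off-centering
  only.
* Moore tracing follows the outer boundary; interior holes (vessels) are
  filled implicitly by the contour representation.
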