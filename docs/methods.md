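# Methods

This note records how each algorithm works, the parameter defaults and
why they were chosen, what the synthetic renderer does and does not
emulate, and the numerical/design decisions taken where more than one
reasonable choice existed.

## Image model and units

All algorithms consume a single-channel raster on the 8-bit [0, 255]
intensity scale. Higher bit depths are linearly rescaled by dtype range
at load time and color frames reduced to BT.601 luminance, because the
pipeline's classic thresholds (e.g. the constant confluence threshold
0.4 × 21.1) are stated in 8-bit units. Coordinates are 0-based
(row, col) with origin at the top-left; circle centers may be
fractional. The default physical scale is 0.467 µm/px — a 598 µm field
of view across a 1,280 px detector row — and is overridable per config;
it only feeds derived defaults (blob-filter sizing, radius ranges), so
the algorithms themselves stay unit-agnostic.

## Confluence segmentation

Attached cells produce high local grayscale variability; culture
background is nearly flat. The segmentation slides a `k × k` kernel
(default `k = 15`) across the image with overlap fraction 0.93 between
successive positions, giving stride `max(1, round(k·(1−overlap))) = 1`.
Each window's **population** standard deviation (population rather than
sample for stability on flat windows) is compared against a threshold:

- adaptive mode: `threshold = 0.35 · σ_image`, where `σ_image` is the
  standard deviation of all analyzed pixels — this makes the
  segmentation invariant to affine intensity rescalings `x → a·x + b`,
  which is the point: dim and bright acquisitions segment alike;
- constant mode: a fixed configured value (default 8.44 = 0.4 × 21.1),
  kept only to demonstrate how fixed thresholds fail on images whose
  contrast differs from the one they were tuned on.

A pixel is foreground when **any** covering window passes (windows
accumulate by maximum). The any-window rule retains regions of
relatively high variability but dilates true regions outward by up to
one kernel; the monolayer renderer's validation accounts for this (see
below). Windows are fully interior — no padding; with stride 1 every
pixel is covered, and at coarser strides the last row/column of windows
is anchored to the image edge and uncovered pixels inherit the nearest
covered value. Window sums use integral images, so window statistics
are exact for integer-valued images. A featureless image (σ = 0) in
adaptive mode reports 0% with a warning instead of an all-foreground
mask. Confluence is `100 · foreground / analyzed pixels`.

**Per-carrier confluence** restricts everything to a detected circle's
interior: σ, the threshold and the percentage are computed over
in-circle pixels only, and only windows lying fully inside the disk
contribute. Without that restriction, windows straddling the carrier's
bright rim or the disk edge read as spurious texture and inflate the
percentage by several points; in-circle pixels within one kernel of the
boundary inherit the nearest covered value instead.

## Carrier detection

Edges are Sobel gradient magnitude above a percentile (default 90th)
taken among pixels with non-negligible gradient (> 2% of the maximum) —
taking the percentile over all pixels lets a mostly-flat field drag the
threshold to ~0 and floods the Hough accumulator with the whole rim
band. Gradient-based edges make detection invariant to constant
intensity offsets. Voting uses the circular Hough transform with
circumference-normalized accumulators over integer radii in the
configured range (default 139–268 px: Cytodex-class carrier diameters
of ~130–250 µm at 0.467 µm/px). Detections above a score floor
(default 0.25, i.e. a quarter of the circumference supported) are
pruned by greedy Euclidean non-maximum suppression with separation
1.2 × min radius, and ties break by (row, col, radius) so results are
deterministic. On rendered carriers, recovery is well within 1 px in
center and radius.

## Cell counting

The detector is a fixed five-step pipeline: (1) convolve with a
mean-corrected, blob-positive Laplacian-of-Gaussian kernel (reflective
borders; the kernel sums to exactly zero, so constant regions give zero
response); (2) zero responses at pixels whose **raw** grayscale is
below `cell_intensity_threshold` — cells are distinguishable by their
relatively high pixel value, and gating the response rather than
pre-thresholding the image avoids manufacturing artificial edges;
(3) binarize responses above a fraction (default 0.2) of the maximum
gated response; (4) label 8-connected components (4-connectivity splits
diagonal blob pixels); (5) keep components whose area lies in
`cell_area_range_px2` with centroid inside the carrier mask.

Sizing defaults derive from the nominal cell radius (10 µm): LoG
`σ = r/√2` (the scale at which a blob of radius r peaks) and kernel
`2·ceil(3σ)+1`. The intensity and area gates are calibration
parameters with no universal value; defaults are scaled from σ and
matched to the renderer's contrast in tests. Overlapping cells merging
into one component are counted once — there is deliberately no
watershed splitting, making undercounts at high confluence a known
limitation. The visible count is doubled (`×2` hemisphere correction)
under the assumption that only the camera-facing hemisphere is
counted; the renderer's hemisphere mode places cells only on the upper
half-disk so the correction is exact by construction there.

## Aggregate detection

Binarize at a threshold (Otsu per image by default — no fixed value
generalizes across illumination), dilate with a disk (default radius
5 px, enough to agglomerate a carrier's bright regions without
bridging separated carriers), label 8-connected, and keep components
whose area lies within carrier bounds and whose equivalent-ellipse
eccentricity (from second-order central moments) is ≤ 0.8. An image is
flagged when **more than two** such objects appear — the strict > 2
reading; `eccentricity_max = 1.0` passed directly to the filter
disables the shape gate (useful for pure labeling comparisons, since
collinear pixel runs have eccentricity exactly 1). Rates are
`50 · flagged / total` per group. Physically fused clumps can merge
into one oversized component and evade the count rule; an optional
extension (off by default, preserving the exact classic behaviour)
also flags any raw component larger than a configurable multiple
(suggested 1.8×) of the carrier-area maximum.

## Growth statistics

`running_mean` is the prefix mean in acquisition order. The
convergence index is the smallest 1-based k such that every partial
mean from k onward lies within a relative tolerance (default 0.05) of
the final mean — the visual "has the average settled" judgment made
explicit; with a zero final mean the band degenerates to an absolute
one. For i.i.d. Poisson(30) counts the index is typically a few tens
of carriers, which is what sets the images-per-timepoint budget.
Colonization histograms use bins of width 5 covering [0, max count]
and are normalized to the day's fullest bin (max-bin = 1.0), which
compares the *shape* of colonization across days regardless of how
many carriers each day yielded. Growth profiles average corrected
counts per day (ascending); days with no analyzable carriers are
reported missing, not zero, because heavy aggregation makes carriers
undetectable rather than empty.

## Synthetic scenes

The renderer targets algorithm testability, not photorealism: no
optics are simulated. Carriers are flat mid-gray disks (default body
90) with a Gaussian-profile bright rim (default 150, width 5% of the
radius) on dark background (30); cells are additive Gaussian blobs
(default σ 2.5 px, amplitude 130) clamped to [0, 255]; optional
confluent texture fills an exact-area chord segment of a disk with
zero-mean speckle; i.i.d. Gaussian sensor noise is added last. All
randomness flows through numpy's PCG64 generator seeded per scene, so
scenes are bit-reproducible across platforms. Truth records circles,
cell centroids, half-amplitude footprint areas, realized foreground
fraction and the aggregate flag.

Monolayers are rendered as a wavy, randomly oriented near-axis band of
speckle texture (std 45 around background 110) thresholded at the
exact pixel quantile, so the realized coverage equals the target to
within one pixel and is recorded exactly. The boundary is kept short
(near-axis orientation, bounded waviness) deliberately: the any-window
labeling rule dilates textured regions outward by up to one kernel, so
the measured-minus-true bias scales with boundary length; with this
geometry it stays around +2 percentage points at 768×768 regardless of
the target fraction. Aggregate-suite scenes place 3–4 carriers in
close proximity but **non-touching** (gaps wider than twice the
dilation radius), so object counting under the > 2 rule is exact;
fused-clump geometry is the oversize-flag extension's territory.

What the renderer does not emulate — and hence what passing tests do
not show about real data: uneven illumination, defocus and depth
effects on a curved surface, cell morphology (blobs are isotropic),
carriers occluding one another, motion blur, and realistic texture
statistics of confluent layers. Detection thresholds proven on these
scenes still need per-instrument calibration on real images.

## Problem sizes and numerical choices

Validation suites use 768×768 monolayers (10 seeds × coverages 0.10 /
0.50 / 0.90), 20 single-carrier scenes at 320×320 with radii 60–100 px,
cell loads of 5–40 on 80–100 px carriers (20 noisy seeds each at noise
std 5), and 30 aggregate-suite scenes at 560×560 — sizes at which every
recovery property is measurable in seconds per suite. Window statistics
use exact integral images; LoG kernels are mean-corrected so flat
fields respond exactly zero; variances are clipped at zero before the
square root; Hough ties and detection order are deterministic by
construction. Degenerate inputs (featureless images, empty masks,
empty detection sets) return defined results or named errors rather
than propagating NaNs.
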