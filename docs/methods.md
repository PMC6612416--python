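# Methods

## Pipeline model

The package treats co-localization analysis as three composable stages.

**1. Image model.** An image is a `(height, width, n_channels)` array of
intensities in [0, 1], produced by dividing integer pixel values by the
dtype maximum (255 for 8-bit, 65535 for 16-bit) — never by min–max
stretching, which would rescale each image differently and break the
proportionality that PCC and MOC quantify.  Alpha channels are dropped (a
warning is logged); 3D stacks and multi-frame files are rejected.  Channel
indices are 1-based in the public API, matching microscopy convention;
coordinates are 0-based row-major internally.  Multi-frame detection uses
the stacked-array shape heuristic (a trailing axis larger than 4 cannot be
a channel axis); a pathological stack of images at most 4 pixels wide would
evade it.

**2. ROI selection.** Cells are segmented from the *grayscale projection*
of the merge image — the unweighted per-pixel mean of all channels.
Broadcast-video luma weights were deliberately not used: fluorescence
channels carry no luminance semantics and should enter symmetrically.
Selection then proceeds: percentile threshold → shrink (erosion) → grow
(dilation) → fill (closing) → clean (opening) → 4-connected labeling →
keep the `n` largest components.  Fixed choices, each of which affects
pixel-level results and is therefore pinned down:

- *Threshold* is a percentile of all grayscale pixel values, computed by
  linear interpolation between order statistics, with a strict `>`
  comparison — so a constant image selects nothing, and `threshold=90`
  keeps the brightest ~10% of pixels.
- *Structuring element* is a `size × size` square; `size` 0 or 1 is the
  identity.  For even sizes the window convention follows the
  erosion/dilation adjoint pair (erosion offsets `-(s//2) .. s-1-s//2`,
  dilation the reflection), which keeps opening and closing idempotent.
- *Borders*: out-of-image pixels count as background for both erosion and
  dilation.  This prevents phantom growth at image edges, at a known cost:
  closing is not extensive for foreground touching the border (the
  property holds on the background-padded domain, and is tested there).
- *Connectivity* is 4-neighbor: structures touching only diagonally are
  distinct regions — the conservative reading of "contiguous".
- *Ranking and ties*: regions are labeled by descending pixel count; equal
  sizes are ordered by the first pixel in row-major scan order, so output
  is fully deterministic.
- An empty post-morphology mask yields all-zero labels plus a logged
  warning, not an exception, so one badly parameterized image cannot abort
  a batch.

**3. Statistics.** PCC and MOC are computed per region from positionally
aligned channel intensities, exactly as the formulas read (MOC sums over
*all* region pixels; no background cut is applied, the formula being the
contract even where prose descriptions of MOC mention "above background"
pixels).  Undefined cases — zero variance for PCC (e.g. a saturated or
single-pixel region), an all-zero channel for MOC — return `nan` with a
logged warning so result tables stay rectangular.  The summary row is the
unweighted mean over regions with defined values, not a pixel-pooled
statistic: regions are the experimental unit.  Full precision is kept
internally; rounding (2 decimals in the CLI display) is presentation only.

## Diagnostics

`render_roi_overview` draws the merge image, the binary pixel set of the
selection, and each channel in grayscale with region boundaries overlaid
(a boundary pixel is a foreground pixel with a 4-neighbor outside its
region).  The pixel set is rendered at full resolution.
`render_intensity_check` scatters channel-1 against channel-2 intensities
colored by region, and shows per-channel Gaussian-kernel density estimates
(Silverman bandwidth — the estimator is a free choice; any reasonable
kernel/bandwidth serves the visual check) pooled over all regions.  Both
functions return the panel data they plotted, so the figures are testable
without pixel-comparing rendered output.

## Synthetic data generator

The generator emulates the study input: blob-like cells of near-uniform
brightness on a dark, weakly noisy background, two channels, known true
correlation.  Construction, per channel:

    value = clip( background + profile · (1 + texture · t) + noise, 0, 1 )

- *Profile*: flat-top disks (default three, radii 30/25/19 px in a 256×256
  frame, peaks 0.75/0.70/0.65, background 0.05), optionally with a Gaussian
  edge skirt (`edge_sigma`, default 0 = sharp).  Flat cores are a
  deliberate modeling choice with two consequences.  First, the true mask
  is well defined: a percentile threshold on a soft-edged blob necessarily
  includes an arbitrary skirt ring, making "ground truth" ambiguous and
  capping achievable Jaccard agreement.  Second, within a flat core the
  deterministic profile contributes no variance, so the realized Pearson
  correlation is governed entirely by the stochastic texture below.
- *Texture*: zero-mean Gaussian fields `t₁` and `t₂ = ρ·t₁ + √(1−ρ²)·t₂'`
  (relative sd `texture`, default 0.1) modulate the profile
  multiplicatively.  Imposing ρ on the texture makes the pre-noise
  within-blob PCC exactly ρ; sharing the deterministic profile between
  channels instead would drive the foreground PCC toward 1 regardless of ρ.
- *Noise*: independent per-channel Gaussian read-out noise (`noise_sd`,
  default 0.01), then clipping to [0, 1].  Noise attenuates the realized
  PCC by the factor `(τ·p)²/((τ·p)² + σ²)` (≈ 0.98 at the defaults, e.g.
  ρ = 0.8 → ≈ 0.79), and clipping adds a mild bias where intensities
  approach the bounds.  Recovery tolerances in the tests account for both.

Defaults were set to a realistic regime — cells covering ~9% of the frame,
~15:1 peak-to-background ratio, sub-percent read-out noise — and the same
seeded spec is used everywhere a "clean three-blob fixture" appears.  What
the generator does **not** emulate: point-spread-function blur,
photobleaching, chromatic shift, uneven illumination, or textured
(non-blob) sub-cellular structure.  Tests passing on these fixtures
therefore validate the pipeline's operations and statistics, not its
robustness to those real-data artifacts; on real images the selection
parameters still require the user's visual judgment via the diagnostics.

## Batch processing

A batch is a list of images with either one shared parameter set or a
per-image list (length-checked before any work).  Images are processed in
input order with no shared state; each failure is logged and recorded as a
result row, never re-raised.  Every parameter actually used is logged per
image at info level, and identical configurations reproduce identical
output files, which is the reproducibility point of scripting this
workflow at all.

## Problem sizes used in the validation suite

Morphology is verified against brute-force sliding-window oracles
exhaustively on all 65,536 4×4 masks (element sizes 2 and 3) and on 500
random 16×16 masks against an independent pure-Python loop; labeling
against a flood-fill oracle on 500 random 20×20 masks; the statistic
kernels against double-loop formula evaluation on 1,000 random vector
pairs (lengths 2–500) at 1e−12 relative tolerance.  Correlation recovery
uses a single-disk spec (radius 60, ≥ 10⁴ foreground pixels) over 20 seeds
per ρ ∈ {0, 0.4, 0.8} with a ±0.05 band on the mean; segmentation recovery
requires per-blob Jaccard ≥ 0.95 on the seeded three-blob fixture
(threshold 90, clean 3, n 3).

## Known limitations

- Only global percentile thresholding; no watershed, adaptive or learned
  segmentation, and no manual polygon ROIs.
- MOC variants (split M1/M2 coefficients), Costes automatic thresholding,
  Li's ICQ, chromatic-shift correction and formal significance testing are
  out of scope; for significance, compare measurements across conditions
  with standard tests on the per-region values.
- 2D single-frame images only; proprietary microscope formats are not
  read.
- Exact pixel-level parity with other implementations of this workflow can
  differ through their grayscale projection, percentile definition and
  structuring-element shape; those conventions are fixed and documented
  here so results are reproducible within this package.
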