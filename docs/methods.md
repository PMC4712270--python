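# Methods

This note documents the models, conventions and numerical choices behind
`tjquant`, and what the synthetic-data validation does and does not show
about real micrographs.

## Image model and conventions

All analysis operates on calibrated 8-bit grayscale images
(`GrayImage`: integer intensities in [0, 255], µm-per-pixel > 0).
Coordinates are row-major `(row, col)`, 0-based, origin top-left,
everywhere — including ROI placement and object centroids. Color inputs
are converted with BT.601 luminance weights (0.299/0.587/0.114, rounded);
single-marker fluorescence channels are effectively monochrome, so the
weight choice is immaterial and fixed only for reproducibility. 16-bit
TIFFs are rescaled by the fixed factor 255/65535 (full-range, not
min–max, so absolute intensities remain comparable across images).
Missing calibration defaults to 1 µm/pixel with a logged warning so
pure-pixel workflows still run.

Binarization uses Otsu's criterion by default (pixels strictly above the
threshold are foreground; the threshold is recorded in the mask's
provenance); a fixed threshold is available everywhere Otsu is. A constant
image has no two classes and is rejected rather than silently thresholded.

## ROI intensity procedure

Ten foreground and five background rectangles, 7×7 px each (both counts
and the size configurable), are placed uniformly at random over eligible
top-left positions: foreground rectangles fully inside the foreground
mask, background rectangles fully outside a dilated copy of it
(default exclusion 2 px) so background samples never graze labeled
structures. Rectangles of one class may not overlap each other, which
avoids double-counting pixels. The reported value is
`corrected = mean(per-rectangle mean, fg) − mean(per-rectangle mean, bg)`;
negative values pass through but are flagged. Where the historical
workflow placed rectangles by eye, placement here is algorithmic — from a
user-supplied mask, or from `auto_foreground_mask`, which thresholds at an
intensity quantile (default 0.95), optionally after Gaussian smoothing
(noisy images need it: the raw upper decile is speckle, not structure) and
with small-blob removal. If fewer rectangles fit than requested, the
procedure fails loudly, reporting how many fit.

On noise-free two-level fields the estimator recovers the true contrast
exactly; on noisy fields it is unbiased (checked at 100 seeds against the
generator's true means, bias < 2 SE).

## Junction morphometry

The thresholded strand network is thinned to a one-pixel skeleton
(topology-preserving medial-axis thinning). Three conventions matter and
are fixed as follows:

* **Spur pruning.** Re-thinning a dilated strand leaves occasional 1–3 px
  spurs at junctions and line ends that the underlying centerline does not
  have. Terminal branches are therefore traced from their endpoints —
  identified by crossing number ≤ 1, which also catches one-pixel corner
  stubs glued to a through-line — and deleted only if the whole branch
  reaches a junction (or dead-ends) within 4 px. Longer arms keep their
  full length; loops and through-paths are never broken. Pruning iterates
  to a fixpoint because removing a spur can expose a new sub-resolution
  stub at the junction it hung from.
* **Branch points.** A junction candidate is a skeleton pixel with
  crossing number ≥ 3 (three distinct strands meet there). A raw
  8-neighbor count was rejected because it fires on the corner pixels of
  rasterized sharp turns. Candidates are clustered by single linkage at
  4 px — a rasterized crossing can split into two Y-vertices a few pixels
  apart — and each cluster counts once, with its centroid as the junction
  coordinate.
* **Length.** Orthogonally adjacent skeleton pairs contribute 1, diagonal
  pairs √2; a diagonal pair is skipped when the two pixels share an
  orthogonal skeleton neighbor (otherwise staircase corners double-count).
  A raw pixel count is available (`length_metric="count"`) for strict
  particle-counter-style reproduction.

`complexity index = branch points / length`; NaN (flagged) on an empty
skeleton so batch runs can carry the flag into reports. Mean object size
is computed on the thresholded mask (8-connectivity by default) in pixels²,
with µm² available through the calibration.

Image entropy is `−Σ_{p>0} p log₂ p` over a 256-bin histogram of the full
[0, 255] range, computed on the *grayscale* image, never a mask.
Zero-probability bins contribute 0 (the standard limit). Although the
source procedure mentions a Markov model, the formula it states — and the
one implemented — is the zeroth-order Shannon entropy of the gray-level
histogram; the two coincide only at order zero, and the histogram version
is what `entropy`/`imhist`-style tooling computes. Entropy is invariant
under spatial shuffling and bounded by log₂ of the number of occupied
bins, both asserted in tests.

Complexity is computed per image (not per vessel), matching the per-image
statistical design of the downstream comparisons.

## Cell-density procedure

Particles are 8-connected components of the thresholded image. Area is
pixel count × calibration²; perimeter is the weighted boundary-chain
estimator of `skimage.measure.regionprops` (the dominant convention in
particle-analysis tools; circularity depends on the estimator, so it is
fixed and recorded). Circularity `4πA/P²` can exceed 1 slightly for tiny
rasterized objects and is clamped to 1 before filtering. Filters keep
particles with area strictly greater than 50 µm² (the strict reading of
"larger than"; configurable) and circularity within [0, 1] inclusive — a
window that excludes nothing after clamping but is implemented because the
procedure names it. Density is `n / roi_area × 1000` (cells per
1000 µm²); a particle belongs to the region of interest if its centroid
lies inside (boundary inclusive), which avoids double-counting across
adjacent fields. The region defaults to the full frame; an arbitrary
polygon (pixel vertices) is accepted.

## Ultrastructure tally

Annotations are one categorical judgement per feature per image, with a
fixed vocabulary (luminal membrane: smooth/protrusions; tight junction:
intact/discontinuous; basal membrane: intact/increased thickness/
detachment; astroglia: intact/edematous). Records are validated
(vocabulary, completeness, uniqueness of region–group–capillary–image) and
aggregated per region × group. The percentage denominator is the number
of annotated images by default; a capillary-level mode collapses each
capillary to its modal category first. Exact fractions always sum to 1
per feature; reports round to integer percent. The report table carries
capillary and image counts above the per-category percentage rows.

## Statistics layer

Each group's values are screened with the Lilliefors-corrected
Kolmogorov–Smirnov test (the Gaussian parameters are estimated from the
data, so the uncorrected KS null is wrong; Shapiro–Wilk is available via
config). The gate is conservative: any group rejecting at α = 0.05 sends
the whole metric to the rank branch, as do groups that cannot be tested
(n < 4, the Lilliefors table minimum, or zero variance — both warned).

Parametric branch: one-way ANOVA; all-pairs pooled-variance t-tests with
Bonferroni adjustment (`p_adj = min(1, p · C(k,2))`). Rank branch:
Kruskal–Wallis with mid-rank tie correction (identical pooled samples
short-circuit to H = 0, p = 1); Dunn's all-pairs z-tests on pooled
mid-ranks,

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_i + 1/n_j)),

with the same Bonferroni-style adjustment (Dunn's test is implemented
in-package; tests cross-check it against brute-force rank computation and
the monotone-transform invariance of the rank branch). Significance is
α = 0.05 on adjusted p, with star grades *, **, *** at 0.05/0.01/0.001 for
figure-style reports. Reports show mean ± SEM per group in percent of the
control-group mean (control ≡ 100%). On two groups the parametric branch
reduces exactly to a two-sample t-test (F = t², asserted to 1e−10);
familywise error of the 4-group, n = 10 null design is ≤ 0.06 in a
2000-replicate simulation.

The seemingly contradictory phrasing "ANOVA followed by Kruskal–Wallis" in
some figure-legend conventions is resolved as Kruskal–Wallis *replacing*
ANOVA on the rank branch.

## Synthetic data: what it emulates and what it does not

All generators take an explicit seed, use one local RNG, and are
bit-reproducible. Intensities compose as two levels (foreground over
background) plus additive Gaussian noise, clipped to [0, 255] and rounded;
recorded true means are pre-noise/pre-clipping, and default levels
(180/30, σ = 5) sit far from the clip boundaries.

**Junction networks.** Strands grow as direction-persistent random walks
(per-step heading jitter SD 6°) that fork with probability `branch_prob`
per step at 60–90° off the parent, on a 512×512 frame (the nominal
acquisition size). Geometric guarantees make centerline topology
recoverable from the rendered image: distinct strands keep ≥ 8 px
clearance (walkers die on approach); forks on one walker are ≥ 10 steps
apart; walkers shorter than 20 px are discarded; sub-resolution holes and
stubs (< (2w+1)² px and < 8 px respectively, w = dilation radius) are
removed from the canonical centerline, since the rendering at strand
width w cannot represent them. A child strand is exempt from collision
with its parent only while leaving the spawn neighborhood, so dilation
never fuses parallel runs. Fragmentation deletes the stated fraction of
each strand's pixels in contiguous runs of 3–9 px — gaps, not
salt-and-pepper — emulating staining discontinuity; `fragmentation = 1`
empties the image. Ground truth (branch points by the crossing-number
rule, geodesic length) is computed on the post-fragmentation centerline,
i.e. on exactly the structure present in the image. Defaults
(`branch_prob = 0.05`, width 1, 4 seed strands) render a moderately
branched control-like network of ~100–150 junctions.

**Cell fields.** Non-overlapping filled ellipses with areas uniform in
60–120 µm² and axis ratios in 1.0–1.8, uniform orientation, at
half-integer centers (which makes the rasterized area a deterministic
function of the sampled axes — the oracle used in tests). Placement
enforces centroid separation ≥ sum of major semi-axes + 3 px, guaranteeing
non-overlap; exhausting the attempt budget raises an error reporting the
achieved count.

**Intensity fields.** A Gaussian-smoothed random field thresholded at a
quantile gives smooth blobs covering a target fraction of the frame —
large enough to admit 7×7 ROIs.

What passing these tests shows: the measurement chain (threshold →
skeletonize → prune → count/measure; label → filter → count; ROI placement
→ subtraction) is internally consistent, unbiased where it should be, and
responds monotonically to the phenotype dials. What it does not show: the
generators have no optics (no PSF, no out-of-focus light), no illumination
gradients, no autofluorescence, no touching cells, and two-level rather
than textured staining — so absolute values on real micrographs depend on
acquisition and thresholding choices that these tests cannot certify.

## Pipeline and reproducibility

A run is one config (YAML or `RunConfig`): simulate or load images,
compute the metric panel per image, then per metric gate → omnibus →
post hoc → percent-of-control report. Child seeds are
`crc32("master|group|image_id") & 0x7FFFFFFF`, so adding images never
perturbs existing ones. Per-image failures (unreadable file, degenerate
image) are recorded in `errors.csv` and skipped; a run aborts only when no
image survives. Reruns of an identical config are byte-identical across
all CSV outputs; `provenance.json` records every parameter and derived
seed. Problem sizes in tests and the acceptance script (256-px frames for
bulk simulations, 20 seeds per monotonicity level, 100 seeds for estimator
bias, 2000 null replicates) were chosen to give stable statistics at
interactive runtimes.

## Known limitations

* The length estimator over-counts on skeletons thicker than one pixel;
  inputs are thinned first, so this matters only for hand-built masks.
* Perimeter (hence circularity) is estimator-dependent; comparisons across
  tools must match the boundary-chain convention.
* The intensity procedure requires foreground regions that admit the ROI
  size; thin-strand stainings (junction networks) need either a smaller
  ROI or a dilated mask — the pipeline's intensity panel targets
  transporter/glial-style staining.
* Animal-level clustering is not modeled; values are treated per image, as
  in the downstream statistical design.
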