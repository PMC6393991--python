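# Methods

## Pipeline

Each ROI image passes through five stages, all deterministic given the run
configuration:

1. **Tissue masking.** A pixel is tissue-free (glass background, tears,
   unfilled spaces) when it is near-white: `min(R,G,B) ≥ 220` and
   `max(R,G,B) − min(R,G,B) ≤ 30` (both configurable). Everything else is
   tissue. No smoothing is applied by default; a 3×3 morphological closing is
   available behind `close_holes`. All masks use a single coordinate
   convention: 0-based, row-major, origin top-left, pixel-aligned with the
   source image.
2. **Collagen segmentation.** Sirius red stains fibrillar collagen
   red/magenta. The default rule classifies a tissue pixel as collagen when
   its HSV hue lies in the wrapping band [330°, 25°], saturation ≥ 0.25 and
   value ≥ 0.20. Hue-based rules are largely insensitive to brightness and
   express "red stain" compactly; a pure-RGB dominance rule
   (`R > G + 30 and R > B + 30`) is available via `rule = "rgb"`. Thresholds
   are global per run — never adapted per image — so intensities are
   comparable across a cohort. The collagen mask is a subset of the tissue
   mask by construction.
3. **Islets and ECM surface.** Connected components of the collagen mask
   (8-connectivity by default, `min_islet_pixels = 0`, i.e. no despeckling —
   the least destructive defaults) are the collagen islets. The ECM surface
   is `100 · Σ islet areas / tissue area`, in percent of the tissue surface.
   All areas are pixel-based; no physical calibration (µm/pixel) is modelled,
   since none is required for percentages, dimensions or cycle counts.
4. **Box-counting fractal dimension.** For each box side ε in a ladder, the
   frame is partitioned into an axis-aligned grid of ε×ε boxes anchored at
   the top-left corner and N(ε) counts boxes containing ≥ 1 collagen pixel.
   D is the slope of log N(ε) vs log (1/ε): the most linear contiguous
   segment of ≥ `min_points` ladder points is selected by exhaustive OLS-R²
   enumeration (ties: longer window, then the window toward smaller ε), and
   the slope on that segment is Tukey's three-group resistant line, iterated
   on residuals until the slope correction falls below `tol = 1e-6` or
   `max_iter = 10`. D is computed on the whole-ROI collagen mask, one value
   per ROI, and is clipped into [0, 2] (the admissible range for planar
   sets; the raw slope is preserved in the audit record).
5. **Degradation simulation.** Iterated binary erosion with a 3×3 all-ones
   structuring element (default `square3`; the 4-neighbour `cross3` is
   selectable for sensitivity analysis). The square element simultaneously
   peels islet boundaries and removes isolated pixels in one cycle. The
   frame boundary counts as background, so collagen touching the ROI edge
   erodes from that side. The surface trace is measured against the *fixed*
   initial tissue area; the denominator never changes during a run. The
   number of cycles is the count of erosions until the surface is exactly
   0 %, and the velocity is the quotient `initial surface % / cycles`,
   implemented exactly as that quotient (it coincides with the mean
   per-cycle decrement only because every trace ends at 0). Termination is
   guaranteed: the topmost-leftmost foreground pixel always erodes, so each
   cycle strictly shrinks the mask.

## Statistical comparison

ROIs are pooled per group and treated as independent observations; group
summaries report mean, sample SD (n−1) and SE. Pairs of groups are compared
per metric with the classical pooled-variance two-sided Student t-test
(`df = n_a + n_b − 2`); Welch's form is available behind a flag. α = 0.05,
no multiple-testing correction. Degenerate zero-pooled-variance inputs
follow a stated convention (equal means → p = 1, unequal → p = 0). The
case-level nesting of ROIs within patients is a known limitation of the
pooled design and is documented rather than corrected; a mixed-effects model
is out of scope.

## Box-size ladders and small frames

The default ladder is dyadic: powers of 2 from 2 up to `floor(min(H,W)/4)`,
descending, giving ≥ 5 points on frames of 128² and larger, with the grid
anchored at a single deterministic offset. The ladder is a config field
because the right calibration grid depends on the object: on a triadic
construction such as the level-4 Sierpinski carpet (81×81), dyadic boxes
misalign with the self-similar holes and understate D (≈ 1.74–1.78 measured),
whereas the base-3 ladder (1, 3, 9, 27, 81) reproduces the exact relation
N(3^j) = 8^(4−j) and hence D = log 8 / log 3 ≈ 1.8928. Calibration tests use
the base-3 ladder for the carpet and the dyadic default everywhere else.
When a ladder yields fewer points than `min_points` (default 5), the
requirement is clamped to the available count, but never below 4; frames too
small for 4 ladder points are rejected.

## Synthetic fixtures

The generator emulates the features the measurements depend on, not
histology per se: a near-white background region (a ragged band whose pixel
count equals the requested white-space fraction exactly), pale-yellow
tissue, and `n_islets` collagen blobs drawn as radial-noise polygons
r(θ) = r₀·(1 + 0.9·irregularity·g(θ)), with g a seeded sum of low-order
harmonics normalized to max |g| = 1. Blob radii are scaled by bisection
until the collagen fraction of the tissue area is within one percentage
point of target (polygons over thresholded random fields: the area is
directly controllable and the ground truth exact). Default palette: collagen
(180, 30, 60), tissue (235, 220, 170), background (255, 255, 255), plus
per-pixel Gaussian noise (σ = 3) that leaves the default colour rules'
margins intact. Everything is a pure function of (spec, seed).

What the fixtures do **not** emulate — stain variability across scanners,
nuclei and glandular texture, partial-volume pixels at fibre boundaries,
out-of-focus blur — bounds what passing tests show: they validate the
measurement chain (segmentation → morphometry → simulation → statistics) on
fields whose ground truth is known, not the colour rule's robustness on real
slides, where thresholds may need tuning per staining protocol.

Cohort-level samples draw each metric independently per ROI from
Normal(mean, SD). The published group statistics used as default parameters
print "mean ± x" with x interpretable either as SD or as SE of the group
mean; both interpretations are exposed (`dispersion_kind`, per-ROI SD =
x·√n under `"se"`). Negative draws of nonnegative metrics are truncated at 0
and fractal dimensions capped at 2 — a slight bias, negligible at the
default parameter ranges. Cycle counts are drawn as continuous values, not
rounded to integers, to keep the sampling distributions exactly normal.

## Problem sizes

Calibration shapes are 81²–1024²; synthetic ROIs default to 256², a size at
which segmentation, fractal fitting and full degradation of a 15 % collagen
field complete in well under a second each. Statistical reproduction uses
two-group cohorts of 50–70 ROIs and 50 seeded replicates per comparison,
summarized by the median p-value.

## Known limitations

- Cycle counts track the maximal inscribed thickness of islets more than
  boundary irregularity: a thin, highly irregular fibre erodes in one cycle.
  The simulation reproduces the erosion procedure as defined; the
  interpretation of cycles as an irregularity marker is not asserted as a
  property anywhere in the package.
- Segmentation thresholds are defaults for the synthetic palette and typical
  Sirius-red fields, not universal constants.
- Whole-slide formats, stain normalization, colour deconvolution,
  polarized-light analysis and physical degradation kinetics are out of
  scope.
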