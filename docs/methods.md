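# Methods

## Elongation-ratio morphometrics

Deformability is scored per cell from a single sheared frame. A field is
thresholded (Otsu by default; a fixed fraction-of-maximum threshold is used
for desk examples where the half-maximum contour is the natural outline),
labelled with 4-connectivity (diagonal chaining at thresholds is a common
segmentation artifact, so 8-connectivity is deliberately avoided), and each
labelled region is reduced to its equivalent ellipse: with area-normalised
central second moments μxx, μyy, μxy and eigenvalues λ₁ ≥ λ₂ of the moment
matrix, a = 4√λ₁, b = 4√λ₂, ER = a/b = √(λ₁/λ₂). The moment definition is
exact under rotation and translation of the underlying shape, which a
bounding-box estimate is not; the ×4 constant cancels in ER. Axes are
measured on the binary mask, not the grayscale blob — the mask convention
is a package decision, made for robustness to illumination.

Quality control marks records rather than repairing them: `border` (region
touches the frame edge), `too_small`/`too_large` (area limits 50/5000 px),
and `low_solidity` (< 0.9), which catches merged blobs. Flagged records
never enter deformability statistics. Merged blobs are excluded rather than
split by default because a blind split biases ER; a distance-transform
watershed (`split_touching`) is available when touching cells are expected.

**Pixelation limit.** On analytically rasterized ellipses the measured ER
deviates from truth with median ≈ 1% for minor axes of 10–20 px, but the
worst case over orientations and subpixel offsets is 3–6% at those sizes,
falling below 2% only for minor axes ≳ 32 px. Single-cell ER at typical
cell sizes therefore carries a few percent of quantization noise; because
the error is approximately centred, it averages out of the pooled AER
(end-to-end recovery is accurate to ~0.002 at 10⁴ cells). Tests assert the
median accuracy at small sizes and strict bounds at large sizes.

## Pooled statistics

AER is the arithmetic mean ER over all unflagged cells pooled across
fields — not a mean of per-field means — so fields with more cells weigh
more. The non-deformable fraction counts cells with ER below `nd_cutoff`,
default 1.05: a perfectly round cell cannot measure exactly 1.0 on a pixel
grid, and 1.05 absorbs that discretization while staying below essentially
all genuinely deformed cells. The cutoff is recorded in every summary, and
pooling refuses to mix summaries computed with different cutoffs.
Summaries retain their per-cell values so pooling is lossless (the median
is not mergeable from moments alone).

## Synthetic field renderer

The renderer emulates a bright-cells-on-dark-background flow-chamber frame.
Each cell is a flat-top elliptical intensity blob whose edge tapers to zero
over the outer 30% of the normalised elliptical radius (a hard edge
aliases; a full cosine dome would put the half-maximum contour at half the
true axes). Level sets of the profile are concentric ellipses with the
cell's exact axis ratio, so any sensible threshold recovers the true ER up
to pixelation. Cells are placed by random sequential adsorption with
non-overlapping circumscribed circles (3 px clearance); orientation is
flow-aligned with Gaussian jitter (default SD 8°), area jitters by 8%
around the mean (default 250 px²), and background level 0.15, linear
along-flow gradient (default 0.05) and additive Gaussian noise (default
SD 0.01 of dynamic range) are applied last. Defaults give 400 cells on a
1280×960 field, so 25 fields yield the ~10⁴ cells a donor sample pools.

Per-cell ER is drawn from a point mass at 1 (non-deformable fraction,
default 2%) plus 1 + lognormal for the deformable component, re-centred so
the population mean equals `aer_target` exactly; the lognormal's SD
(`spread`, default 0.25) sets the right tail, which reaches the ER ≈ 2.3
highly deformable exemplar. The renderer does not model biconcave optics,
partial focus, or cell-cell adhesion — passing recovery tests shows the
measurement chain is unbiased on well-separated convex cells, not that it
would survive confluent or out-of-focus fields.

## Synthetic LFQ + AER cohorts

A cohort is one draw of an (n × 7) matrix from a multivariate Gaussian:
six Ln(LFQ) subunit coordinates plus a latent coordinate that is shifted
and scaled into AER. Means and SDs are the published cohort summaries; the
correlation target assembles the printed inter-subunit matrix and the
subunit–AER correlations (non-significant subunits set to 0). The printed
matrix is not positive semidefinite (smallest eigenvalue ≈ −0.05, a common
artifact of rounding and pairwise-complete estimation), so preset targets
are projected to the nearest correlation matrix (Higham alternating
projections); the projection moves no entry by more than 0.028. With
`psd_repair` off, a non-PSD target is an error reporting the smallest
eigenvalue.

Stored-unit samples receive an additive shift of the γ (HBG2) mean
(default +2.3 Ln units), the one storage effect the design carries. The
study preset's γ SD is the within-group value (0.65, between the printed
group SDs); the pooled printed SD (1.6) is inflated by the shift itself and
would destroy the power of the storage contrast if used as within-group
spread. AER is not group-shifted (the two groups' deformability did not
differ). Three presets ship as YAML data files: `study` (9 fresh + 6
stored, the default), `fresh-donor`, `stored-unit`.

## Statistical layer

Pearson r is computed on pairwise-complete rows, with per-cell n reported
(published screens of this kind are consistent with unequal per-pair n);
p is two-sided from t = r√(n−2)/√(1−r²) on n−2 df. Significance tiers:
`*` p < 0.05, `**` p ≤ 0.001. The fresh-vs-stored contrast uses Welch's
unequal-variance t by default with a Mann–Whitney alternative; the test
name is always emitted with the result because such tables rarely state
it. No multiple-testing correction is applied by default, matching
conventional presentation; Holm is available (`holm=True` / `--holm`).
Normality uses Shapiro–Wilk (scipy), valid for 3 ≤ n ≤ 2000. The δ/α
ratio is computed per sample on the intensity scale, exp(Lnδ − Lnα), then
averaged — note that under log-normality the mean ratio is
exp(μd + σd²/2), not exp(μd), so intensity-scale means exceed the
exponentiated mean log-difference.

Natural logarithms are used throughout; `ln_transform` refuses input whose
values are all below 100, which on raw MS intensity scales can only mean
the table was already log-transformed.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and draws from its own
`numpy` Generator; no global RNG state is touched, and identical seeds give
bit-identical images, cohorts and CSVs. Test and reference computations
use the study's own scales where feasible — 25 fields × 400 cells for AER
recovery, n = 15 cohorts for operating-characteristic checks (1000
replicates for confidence-interval coverage, 10⁴ for type-I calibration of
the screen, with the replicated screen calibration run at 300 cohorts) —
and n = 2000 cohorts where a spot check of a single draw against a
population target needs small sampling error.

## Known limitations

- Single-shear-stress design: the 3.0 Pa wall shear stress is metadata;
  no ER–stress curve is modelled.
- The renderer's photometry is schematic; segmentation robustness to real
  microscopy artifacts (debris, uneven focus, overlapping cells) is out of
  scope.
- The cohort generator reproduces first- and second-moment structure only;
  real LFQ data carry missingness, batch effects and heavy tails it does
  not emulate.
- Published group contrasts of this kind are not always reproducible from
  printed summary statistics alone; this package always recomputes p from
  the data and names the test.
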