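# Methods

This note documents the quantification models implemented by `c9quant`,
the defaults and conventions chosen where the procedures are genuinely
underdetermined, what the synthetic generators do and do not emulate, and
the known numerical biases.

## Conventions

All coordinates are (row, col), 0-based. Physical units are micrometres
throughout; every public operation converts through the `pixel_size`
carried by `ChannelImage`/`BinaryMask`. Threshold methods share one
grammar: `otsu`, `quantile:q`, `fixed:v`, `mad:k` (background median +
k·1.4826·MAD), plus `otsu_foreground` for the microtubule high threshold.
Foreground labeling defaults to 8-connectivity so one-pixel-wide diagonal
neurites stay single objects. Region perimeters use the Crofton
4-direction line-intercept estimator (`skimage.measure.regionprops
.perimeter_crofton`), which keeps the circularity of a rasterized disc
within 0.1 of 1; a single-pixel region is defined maximally compact
(circularity 1.0) to avoid a zero-perimeter division.

## Microtubule depolymerization and neurite density

Model: depolymerized tubulin forms bright, compact aggregates; polymerized
tubulin forms dim, elongated filaments. Segmentation is dual-threshold:

1. *Low threshold* — default `mad:5`. A robust background cut was chosen
   over plain Otsu because the image is a three-class mixture (background,
   dim filaments, bright aggregates) in which global Otsu collapses onto
   the background/aggregate split once aggregates are abundant, discarding
   the filaments entirely. The median + 5·MAD cut depends only on the
   background statistics and is insensitive to the aggregate fraction.
2. *High threshold* — default `otsu_foreground`: Otsu restricted to the
   pixels inside the low mask. This separates the filament and aggregate
   intensity modes wherever both are present, regardless of their relative
   abundance; a fixed foreground percentile would instead pin the
   aggregate area at a constant fraction of the signal.
3. *Specificity refinement* — aggregate candidates must have circularity
   ≥ 0.5 **and** area ≥ 0.1 µm². The area floor matters: shot-noise
   speckle along filaments produces near-single-pixel candidates that are
   maximally compact by definition and would otherwise register as
   aggregates on aggregate-free fields.

The polymerized mask is the low mask minus the refined aggregate mask, so
the two always partition the low mask exactly. Pre-smoothing is available
(`smooth_sigma_px`) but defaults to off: blurring widens 1–2 px filaments
severalfold, which biases the area-ratio index; the thresholds are stable
without it at the noise levels the assay operates at.

Skeletonization applies to the polymerized mask only, after a binary
closing with a 3×3 element (`close_radius_px = 1`) that bridges
single-pixel chain breaks introduced by noise thresholding. Skeleton
length is the sum over undirected adjacent skeleton-pixel pairs of
`pixel_size` (orthogonal) or `√2·pixel_size` (diagonal). Known bias:
residual chain breaks and end pruning make the skeleton length
underestimate the true filament length by ~6–8% at the default synthetic
noise level; this is well inside the 10% recovery band and is reported,
not corrected. Fields with no NeuN nuclei keep their row with the density
flagged undefined; fields with no tubulin signal are flagged degenerate.
The per-field (FOV) result is the unit of output; well or genotype
averaging is left to downstream tables.

## NPC mislocalization

Nuclei: DAPI is median-filtered (default radius 0.2 µm), thresholded
(Otsu), hole-filled, and size-filtered (default 5 µm²). Foci: local
maxima with a physical suppression radius (default 0.2 µm) and a
prominence floor relative to the neighbourhood minimum; plateaus of equal
maxima yield one detection at the plateau centroid, and surviving
candidates are greedily suppressed brightest-first with (row, col)
tie-breaking, so detection is deterministic.

The annular band is measured **inward** from the nuclear boundary: the
Euclidean distance transform of the nucleus mask gives each interior
pixel's depth, and the band is the half-open interval [0.7, 1.2) µm.
Rationale: pores normally tile the envelope, so "mislocalized within the
nucleus" reads as displacement into the interior, and the half-open
interval partitions depths deterministically. An outward variant (band in
the background just outside the boundary) is exposed on
`nuclear_annulus(direction=...)` for sensitivity analyses. Foci deeper
than the outer bound count in the per-nucleus total but not in the band.
A focus is assigned to the nucleus whose label covers its nearest pixel;
nuclei with zero foci are flagged and excluded from summaries. Nuclei too
small to reach the inner depth return an empty, flagged annulus.

## PI uptake

Counting: top-hat subtraction with a 10 µm disc, then connected objects
at least 0.5 RCU above background. "Background" is not numerically defined
by the assay, so it defaults to the per-frame median after top-hat (the
residual flat level), overridable. RCU is taken as the native intensity
unit of the input frame. Curves: counts are normalized to the post-lysis
maximal count (values above 100% are retained with a warning), the
baseline (first) timestamp is subtracted literally — negative values are
kept unless `clip_negative` is set — and the AUC is the trapezoid over the
recorded timestamps up to 168 h, truncating at the last available frame.
Multiple images per well and timestamp are summed before normalization,
producing one curve per well.

## Survival, STING, holding impulse

BFP⁺ nuclei are thresholded bright regions above a size floor; per-day
counts are divided by the day-4 baseline (missing or zero baseline is an
error; growth above 1.0 is permitted). STING is the mean intensity over
the TUJ1⁺ mask, expressed as fold change over the control-line mean.
Holding impulse is the exact product
`weight_g × 0.00980665 N/g × time_s`.

## Transcriptomic rescue

Differential-expression statistics are consumed, not computed: the inputs
are per-contrast tables of `log2fc` and `padj` (a BH helper is provided
for tables that ship raw p-values). DE calls use strict inequalities
(|log2fc| > 0.5, padj < 0.05); boundary values and missing padj are not
significant. The rescue rule, evaluated only for DE genes of the disease
contrast, is clause 1 (significant change in the editing contrast) OR
clause 2 (edited line indistinguishable from control, padj > 0.05);
clause 1 is checked first and recorded. No direction constraint is imposed
by default — the rule is a literal disjunction — but
`require_opposite_direction=True` additionally demands that the editing
shift oppose the disease shift. Missing padj counts as not significant in
clause 1 and as failing clause 2 (the gene is flagged); genes absent from
any table are flagged and excluded from summaries.

The expressed-gene cutoff assumes the distribution of mean
log10(TPM + 0.01) is a two-mode mixture (silent vs expressed genes): a
Gaussian KDE with Scott's-rule bandwidth is scanned for modes and the
cutoff is the density minimum between the two largest; if no second mode
exists the cutoff falls back to 1 TPM with a warning. The pseudocount
(0.01) and grid size (512) are exposed. Because the cutoff lives in log
space on a data-spanning grid, multiplying all TPM by a common factor
moves the cutoff by the same factor up to grid resolution and the
pseudocount's influence.

## Synthetic data

Every generator is a pure function of `(seed, params)`; a top-level seed
fans out to fixed per-dataset streams via
`SeedSequence(seed, spawn_key=(stream,))`, so datasets are independent but
jointly reproducible and bit-identical on regeneration.

* **Neurite fields** (512², 0.1 µm/px): filaments are self-avoiding
  persistent lattice walks (turn probability 0.05, ±45° per step) whose
  chains never touch, so the planted edge-weighted length is exact;
  aggregates are discs sized to a requested fraction of total signal
  pixels (±0.01) and kept clear of filaments; NeuN nuclei are
  non-overlapping discs. Noise is Poisson shot noise plus Gaussian read
  noise with σ = filament amplitude / SNR (default SNR 10). Default
  conditions: 8 filaments totalling 400 µm, 8 nuclei, background 10,
  filament +40, aggregate +120.
* **NPC fields** (512², 0.02 µm/px — STED scale): circular nuclei;
  each focus is placed on a pixel whose distance-transform depth matches
  the requested depth (within 0.1 µm) and the *achieved* depth is
  recorded, so planted band fractions are recovered exactly in the
  noiseless case. Default: one 3–4 µm nucleus per field, 20 foci, 30% at
  0.9 µm depth.
* **PI series**: expected counts follow a logistic uptake curve
  (default: baseline 5%, plateau 60%, rate 0.06 /h, midpoint 84 h,
  sampled every 12 h to 168 h) with Poisson draws; the lysis frame counts
  all cells. The ground truth records both the analytic integral of the
  noiseless normalized curve (softplus closed form) and an independently
  accumulated trapezoid of the sampled curve.
* **Survival fields** (512², 0.65 µm/px — 10X whole-well scale, where
  3 µm nuclei pack at the required densities): exactly the requested
  number of non-overlapping bright nuclei per day (default 100/80/50 on
  days 4/7/11).
* **DE tables**: 5000 genes, 200 affected with |log2fc| ≥ 2 and tiny
  padj; each affected gene is independently rescued with the requested
  probability, satisfying exactly one planted rescue clause (chosen at
  random); non-rescued genes satisfy neither; unaffected genes draw
  |log2fc| < 0.25 and uniform padj. An effect size at or below the DE
  threshold is rejected as ambiguous.

What the generators do **not** emulate: point-spread functions,
bleaching, uneven illumination, filament crossing and fasciculation, cell
clumping, segmentation-confounding debris, batch effects, or correlated
DE statistics. Passing recovery tests therefore demonstrates the
correctness of the measurement chain on well-posed inputs, not robustness
to every real-microscopy artifact; the threshold and size defaults remain
config-exposed for that reason.

## Numerical choices and degenerate inputs

Constant images under Otsu return an empty mask plus a degenerate flag
rather than raising. Thresholds are strict (`>`). The distance transform
is the exact Euclidean transform. Ties in maxima detection are broken by
intensity then (row, col). Undefined ratios (0/0 index, zero-foci
nucleus, zero DE genes) return NaN with an explicit flag and a warning,
and flagged records are excluded from summaries but retained in outputs.
Problem sizes in the test-suite recovery studies (20 fields per planted
fraction, 16 wells, 200 affected genes, 10,000 truth-table records) were
chosen to make the statistical tolerances meaningful at desk scale.

## Limitations

Exact numerical replication of the source assays' published figures is
not claimed: the original image-analysis macros used empirically tuned
thresholds that are not public, and the study's sequencing data are under
restricted access. The package instead fixes documented, reproducible
defaults and verifies them against planted ground truth. 3D stacks,
stitching, deconvolution and flat-field correction are out of scope;
z-stacks must be reduced per-plane upstream.
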