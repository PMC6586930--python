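# Methods

## Problem and model

Given a two-channel fluorescence image — a *marker* channel identifying a
class of endomembrane compartments and a *protein* channel carrying the
signal to quantify — the package estimates the fraction of compartments
genuinely carrying the protein, corrected for colocalization occurring
by chance. The estimand is object-based, not pixel-correlation-based: it
is robust to unequal channel gain and to non-proportional probe
intensities, which defeat Pearson/Manders-style coefficients.

The decision rule for a single compartment *i* with mean protein
intensity *m_i* is

&nbsp;&nbsp;&nbsp;&nbsp;positive(i) ⇔ *m_i* > *μ* + *k·σ*

with *μ*, *σ* the mean and population SD of the protein channel over the
whole ROI and *k* = 1 by default. The chance level is estimated by
applying the identical rule to *n* disks of compartment-like area placed
uniformly at random in the ROI; the per-region mean intensities of real
and random regions are compared with a two-sided Mann–Whitney U test.
The protein is called present at the compartment class only when the
real distribution is significantly shifted above the null.

## Pipeline and parameters

**ROI.** Axis-aligned rectangle, 0-based (row, col), half-open extents;
default 300 × 300 px. Pixel calibration (µm/px) is supplied by the user;
TIFF resolution metadata is only sanity-checked against it (warning on
conflict), never trusted silently.

**Segmentation** (marker channel): Gaussian blur (σ = 1 px default; the
blur scale is an analysis choice, not a measured quantity) → threshold
(Otsu on the smoothed ROI by default; a fixed-value override exists;
foreground is *strictly above* the threshold) → morphological closing
with a disk (radius 1 px default) → hole filling → 8-connected labeling →
removal of objects with area < `min_area_px` (default 4 px; small and
deliberately prominent in the configuration) → relabeling to consecutive
ids 1..K. Closing precedes hole filling because closing first bridges
boundary gaps, turning enclosed background into fillable holes; the
reverse order is not offered. Compartments touching the ROI border are
kept. A constant image under Otsu yields zero compartments, not an
error.

**Null model.** Disk shape: compartment cross-sections are near-circular
and a disk makes the area exact up to rasterization. Radius
= round(√(area_px/π)) with area_px = area_µm²/pixel_size². A rasterized
disk contains every pixel whose centre lies within the radius
(Euclidean, inclusive); for the endosome default (1.2 µm² at 0.1 µm/px,
radius 6 px) the realized area is 113 px against 120 requested, a 5.8%
rasterization error, bounded by 15% for all radii ≥ 3 px. Centres are
drawn uniformly over all positions keeping the disk fully inside the
ROI, from numpy's PCG64 generator with a recorded seed. Disks may
overlap each other and real compartments by default — an unconstrained
placement is what "by chance" means; a rejection-sampled non-overlap
mode exists for sensitivity analysis only. Defaults: n = 1000 disks of
1.2 µm² (endosome/autophagosome scale), n = 10 disks of 9.2 µm²
(trans-Golgi scale).

**Positivity and statistics.** All SDs are population SDs (÷N), matching
common image-measurement semantics; the sample-SD alternative would be a
one-line change. The threshold comparison is strict. The threshold
baseline is the *entire-ROI* protein statistics by default; an
alternative `compartments` baseline (mean and SD taken over the
per-compartment mean intensities) is selectable, since the operational
definition admits both readings. With zero compartments the percent
positive is reported as missing, never as 0, to avoid biasing
aggregates. The Mann–Whitney test uses the exact null distribution for
tie-free samples with n₁+n₂ ≤ 12 and the normal approximation with tie
correction otherwise; samples in which every observation is identical
return U = n₁n₂/2 and p = 1 by convention. No multiple-testing
correction is applied within a run.

**FRET.** Per-channel background subtraction (mean of a user region
outside the cell; negative results are kept, not clamped), optional
block binning (2×2 or 3×3 operating points; block mean, trailing
rows/cols dropped, pixel size scaled, boolean masks binned by block
majority), then the per-pixel YFP/CFP ratio. Pixels outside the cell
mask or with CFP ≤ ε (ε = 10⁻⁶ of the subtracted-CFP maximum) are
invalid and excluded from every summary. Ratio first, average second:
summaries are means of per-pixel ratios, not ratios of means — the
per-pixel form is what a ratiometric image displays. The cell-edge band
is the cell mask minus its erosion by a disk of radius
round(band_µm/pixel_size) (default band 1.67 µm); the disk structuring
element gives an isotropic distance from the periphery, and band plus
eroded interior reconstitute the mask exactly. A band width rounding to
0 px is rejected rather than silently returning an empty band. No
bleed-through/cross-talk correction is applied.

## Synthetic data: what it emulates, what it does not

The generator emulates a confocal cross-section of one cell interior:
hard-edged disks (radius drawn uniformly from 0.55–0.70 µm, i.e.
~0.95–1.5 µm² at the endosome scale) at marker intensity 200 over
background 10, placed by rejection sampling with ≥ 5 px clearance so
ground-truth objects never merge; a Gaussian point-spread proxy
(σ = 1 px) applied to the noise-free image; then additive Gaussian noise
(sd 2 by default) or Poisson noise on the expected counts (Gaussian is
the default because its effect on region means is analytically
transparent). The protein channel is flat background 50, multiplied by
the enrichment factor *e* inside round(f·n) randomly chosen disks. The
default field holds 50 compartments in a 300 × 300 px ROI at 0.1 µm/px —
roughly the compartment density the workflow targets. The
self-colocalization fixture (protein = blurred marker + Gaussian noise
of sd 5% of the foreground) mimics imaging the same compartment class
with two markers.

Real images differ in ways the generator deliberately omits: tubular and
irregular organelle shapes, intensity heterogeneity within compartments,
spatially varying background, camera gain/offset, z-structure, and
multiple cells per field. Passing tests therefore certify the
*algorithmic* behaviour of the pipeline — thresholding, null
calibration, fraction recovery under the stated generative model — not
performance on any particular microscope's data.

## Numerical choices and degenerate inputs

- Strict inequalities at the segmentation threshold and positivity
  threshold; ties go to background/negative.
- ROI cropping refuses out-of-bounds regions instead of clipping.
- Loading enforces non-negative intensities; background-subtracted
  images are the one place negatives appear, and they are handled by the
  validity mask rather than by clamping.
- Report CSVs format numbers to 6 significant digits so identical
  reports are byte-identical.
- All randomness flows through seeded numpy `default_rng` instances; a
  fixture or null draw is a pure function of (parameters, seed).

## Evaluation protocol

The acceptance script and suite run the pipeline at the default study
conditions: 20 self-colocalization runs, 200 null-calibration runs (one
fixture and one independent null seed per run, all spawned from a single
base seed via `SeedSequence`), 20 runs per enriched fraction in
{0, 0.25, 0.5, 0.75, 1} at e = 10, plus exhaustive oracle comparisons
(flood-fill labeling on 64 × 64 fields, full rank-assignment enumeration
of the Mann–Whitney test for n₁, n₂ ≤ 5, pixel-enumerated disks). These
problem sizes keep a full evaluation under a minute on one core while
leaving each property overdetermined.

Under independent protein noise the rank-sum p-values are approximately
uniform but not perfectly so: pseudo-disks share pixels with real
compartments (the unconstrained null placement guarantees this), and
segmented areas differ slightly from the disk area, so the two samples
are weakly dependent with unequal variances. The measured
Kolmogorov–Smirnov distance from uniformity stays well inside the 0.1
band the evaluation asserts.

## Known limitations

- No watershed splitting: touching compartments count as one object.
- Per-image analysis only; aggregation across cells/fields is left to
  downstream tooling.
- The null is purely geometric (uniform placement); intensity-matched or
  marker-avoiding nulls are out of scope.
- The FRET module assumes negligible spectral bleed-through and a
  user-supplied cell mask; it performs no automatic cell detection.
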