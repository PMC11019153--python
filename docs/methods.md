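# Methods

This note documents the models, parameter choices and numerical
conventions behind `senotex`, and what the synthetic benchmark does and
does not establish about real data.

## Synthetic scene model

The generator's task is *ordinal* fidelity: downstream texture statistics
must respond smoothly and in the right direction to biologically motivated
parameter changes (senescent nuclei larger, chromatin smoother and less
punctate).  It does not attempt photorealism, PSF physics or calibrated
photon statistics.

**Nucleus geometry.** Each nucleus is a rotated ellipse whose area is
drawn from a per-condition normal distribution and whose minor/major axis
ratio is uniform on [0.75, 1] (configurable; tests that need exact circles
set it to (1, 1)).  The ground-truth mask is exactly the rasterized
ellipse.

**Chromatin texture.** The interior intensity is a unit baseline plus a
band-limited Gaussian random field — white noise smoothed with a Gaussian
of width `texture_corr_len_px` and rescaled to sd 0.25 — plus hard disks
of radius 3 px ("foci") at Poisson-distributed density (per µm²) with
additive contrast `foci_contrast`.  GLCM statistics vary monotonically in
both the correlation length (homogeneity rises) and the foci contrast
(contrast rises), which the property tests assert over ≥ 50 seeds.  An
infinite correlation length with zero noise and zero foci yields an
exactly constant interior — the analytic limit in which GLCM contrast is
exactly 0 and energy exactly 1.

**Noise.** "Poisson-like" noise is implemented as Gaussian noise with
signal-proportional variance (sd = `noise_sd`·√intensity, so the sd at
the unit-intensity interior equals `noise_sd`).

**Condition defaults.** Proliferating: area 7 000 ± 800 px², correlation
length 1.5 px, 4.0 foci/µm² at contrast 0.35.  Senescent: 12 000 ±
1 100 px² (≈1.7× larger), correlation length 3.0 px, 1.5 foci/µm² at
contrast 0.15.  Three-day treatment takes the arithmetic midpoint of every
parameter; 6- and 9-day treatment share the senescent parameters.  The
published observations fix only the orderings (senescent larger and more
homogeneous; late treatment senescent-like; early treatment intermediate),
not absolute values; the absolute numbers are conventions chosen to be
realistic at a 25 nm detail pixel size and are config-exposed.

**Bad images.** Five labeled failure modes of unattended acquisition:
out-of-focus (σ = 8 px blur of a good image), truncated (nucleus centre
moved to the frame edge so roughly half the nucleus is outside — the mask
always touches the border), blank rows (≥ 10% of rows set exactly to 0,
as when scanning outside the field of view), empty frames, and doublets
(two nuclei, major axes perpendicular to their separation; residual
overlap is carved from the second mask so ground-truth masks stay
disjoint).  In mixed populations `bad_fraction` is the fraction of the
*total* population that is bad.

**Overview scenes.** One global 3-plane stack is built per scene: a sharp
mid-plane and two defocused neighbours (σ = 4 px blur, attenuated to
0.5), each with its own noise draw.  Tiles are crops of this global stack
on a spiral-ordered grid with 20% overlap, and the reference 2-D scene is
the global max-projection — since maximum commutes with cropping, the
per-tile max-projections are exactly crops of the reference scene, and
stage-coordinate fusion (per-pixel mean in overlaps) reproduces it
bit-exactly.  Stage coordinates are emitted in nm with x → columns,
y → rows.

**Reproducibility.** Every generator output is a pure function of
(parameters, seed).  Sub-streams derive from one integer seed through
`SeedSequence` spawn keys (strings hashed by CRC-32), so each image in a
population is independently reproducible.

## Segmentation

**Detail (STED-like) foreground.** Intensities are normalized to the
(0.025, 0.995) quantiles and clipped to [0, 1]; the mask is the Li
(minimum cross-entropy) threshold of a σ = 16 px Gaussian-blurred copy,
followed by removal of 8-connected objects of area < 512 px and filling
of holes < 512 px ("< 512" is strict; object removal precedes hole
filling, both order-configurable).  Quantile normalization makes the mask
exactly invariant under multiplication of the image by any positive gain.
Two degenerate-input guards return an empty mask with a flag: a constant
image (undefined normalization), and a blurred dynamic range below 0.15 —
quantile-stretching a *signal-free* noise frame would otherwise hand Li a
unimodal histogram and mark roughly half the frame foreground.  The 0.15
bound sits far from both sides: blurred noise fields span ≲ 0.04 of the
normalized range while blurred nuclei span ≳ 0.6.

The σ = 16 px blur inflates the Li mask outward by a few pixels, so
boundary accuracy (IoU against ground truth) depends on nucleus scale:
radius-100 px circular nuclei in a 224 px frame segment at IoU ≈ 0.93–0.96,
which is the regime the accuracy tests use; much smaller nuclei segment
with proportionally larger relative bias.  This bias is inherent to the
blurred-threshold recipe, not to the implementation.

**Overview detection.** Per-pixel features (raw intensity, σ = 2 px
Gaussian response, Sobel gradient magnitude) are z-scored and clustered
with k-means (k = 2 by default, 10 restarts, fixed seed); the cluster with
the highest mean raw intensity is foreground, eroded with a radius-3 disk,
and 8-connected components are labelled.  Two robustness guards extend the
bare recipe: (i) foreground is accepted only when the top cluster's raw
mean exceeds the next cluster's by ≥ 4 pooled within-cluster standard
deviations — splitting unimodal noise yields ≈ 2.7, real nuclei ≫ 4 — so
blank, constant and noise-only images return zero detections; (ii)
components smaller than 64 px are dropped, because erosion occasionally
pinches 1–10 px crumbs off the rim of a genuine nucleus.

## Texture features

A masked GLCM counts ordered level pairs at offset (0, +d) for θ = 0 and
(+d, 0) for θ = π/2, *both* endpoints inside the mask (the strictest
reading of "within the foreground"); counts are symmetrized (transpose
added) and normalized per (d, θ) slice.  Implementation detail: pixels
outside the mask are assigned a sentinel level and the sentinel row/column
is sliced away from the co-occurrence table, which is equivalent to pair-
level masking; the test suite verifies equivalence against a naive
double-loop enumeration to 1e-12.

Quantization uses 64 levels (`level = floor(v·64)`, v = 1 mapping to 63).
The σ = 0.5 px pre-blur is applied as a *masked normalized convolution*
(Gaussian of image×mask divided by Gaussian of mask) rather than a whole-
image blur: this keeps boundary pixels free of background contamination,
makes the texture block exactly invariant to pixels outside the mask (at
fixed normalization bounds), and preserves the constant-interior limit
exactly.  Degenerate slices (no valid pair at some offset, e.g. d = 16 on
a 16-px image) carry NaN sentinels, never silent zeros; models median-
impute them from training data.  For a constant slice, correlation is
defined as 1.

The detail profile produces 60 GLCM values (6 stats × 5 distances × 2
angles) plus 10 scalars: mean foreground intensity in raw and normalized
units, foreground sd (raw), segmented area, the two normalization
quantile values, image width/height and the number of all-zero rows and
columns (counted on the raw image).  Width, height and blank-row/column
counts are flagged auxiliary: the QC classifier uses them, embedding and
phenotype classification exclude them.  The confocal profile uses
distances {2, 4, 8, 16}, quantiles (0.025, 0.998), and replaces the scalar
block with area, eccentricity and mean intensity (51 values).

## Models

**QC.** A 500-tree random forest on median-imputed, z-scored full feature
vectors.  Out-of-fold good-class probabilities from stratified five-fold
CV (all preprocessing refit within each fold) feed threshold calibration:
the smallest threshold whose out-of-fold precision — TP/(TP+FP) for the
good class — reaches the 95% target, considering only operating points
that keep at least 5% of the records (otherwise an uninformative scorer
could "calibrate" on a handful of lucky top-ranked points).  If no
operating point qualifies, a reject-all sentinel threshold (> 1) is stored
and a warning raised.  Held-out precision at the calibrated threshold is
the package's headline number (`scripts/acceptance.py`).

**Phenotyping.** Non-auxiliary features are standardized with statistics
fit on the training conditions only; the classifier is an RBF-kernel SVM
with C = 1.  Treated samples never enter training.  Per treated group the
summary reports the fraction classified as each phenotype (summing to 1);
a group is called "ambiguous" when neither fraction reaches 0.7 — a
convention, as no numeric rule is published.  t-SNE (perplexity 30, fixed
seed, deterministic) is provided for visual inspection only and never
feeds classification.

## What the benchmark shows — and does not

Passing tests establish that the pipeline's machinery is correct (exact
GLCM arithmetic, calibrated thresholding without test-set leakage,
bit-reproducible orchestration) and that it recovers planted, well-
separated condition differences through the entire chain at ≥ 95%
held-out accuracy.  They do not establish performance on real chromatin:
the texture model is a smooth random field, condition separability is
enforced by construction, staining/replicate batch effects (which
dominated the published fine-scale analysis) are not simulated, and
touching nuclei, 3-D segmentation and stage-coordinate refinement are out
of scope.

## Problem sizes and determinism

Default test-suite populations use tens of images per condition; the
headline QC benchmark uses 500 + 500 training and test images at
256 × 256 px, chosen so a full run completes in minutes on one CPU while
keeping binomial uncertainty on a 95% precision estimate near one
percentage point.  All tests fix seeds; the acceptance script threads its
single `--seed` through every stream it uses.
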