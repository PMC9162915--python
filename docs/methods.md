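# Methods

This note documents the models, parameters and numerical choices behind
`tmaquant`, and what the synthetic cohorts do and do not show about real
tissue-microarray (TMA) data.

## Synthetic cohort model

**Spot geometry.** Each patient contributes one 0.6 mm circular tissue
spot imaged on two consecutive sections, one per antibody clone.
Default calibration is 1 µm/px, giving a 700 × 700 px canvas (600 px
disc + 50 px margin). Images carry two scalar channels in
optical-density-like units — nuclear counterstain and antibody stain —
rather than RGB; this keeps the analysis free of a color-deconvolution
step while an RGB export would remain possible on top of it.

**Densities.** Per-patient CTLA-4⁺ and CD3⁺ densities are a bivariate
log-normal: moment-matched to the entity's configured mean and SD, with
the configured correlation (default 0.69) applied to the log densities.
The log-normal is a modeling choice, motivated by the strong right skew
of observed density distributions (cohort means far above medians); no
distributional form is claimed for real data. CD3 densities are *not*
measured from images — they enter the patient table as an input column,
matching a workflow in which the T-cell density was quantified
separately — so the CTLA-4/CD3 ratio inherits whatever error that
column carries.

**Cells.** The latent cell field of a spot holds CTLA-4⁺ lymphocytes at
the patient's density plus CTLA-4⁻ nuclei at a fixed
`other_cell_density` (default 1200 cells/mm²), placed uniformly in the
disc. Each section independently drops 10 % of cells and jitters
positions by a 2 µm Gaussian — adjacent sections contain nearly, not
exactly, the same cells. Lymphocytes are rendered as a Gaussian nucleus
(σ = 2 µm, amplitude 1.0) plus a membranous ring of stain at radius
5.5 ± 0.75 µm; other cells get only the nucleus. A uniform tissue
background (0.15 OD) inside the disc makes the tissue area measurable
even in cell-poor spots.

**Cross-reactive staining.** In an affected entity, the affected clone
stains a contiguous tissue territory diffusely (default pattern
`cytoplasmic-diffuse`; `membranous` and `colloid-blob` are available).
The territory is a half-plane cut through the disc at a random
orientation, with its offset set to the quantile matching the
per-patient target fraction (a Beta draw around the entity mean, e.g.
0.58 for the clone-A artifact entity). Every cell inside the territory
counts as non-specifically stained for that clone — so the planted
non-specific cell fraction equals the territory's cell share by
construction — while the same cells on the clean clone keep their
native class. A territory never exists on both clones of one spot.

**Covariates.** Binary covariates (pN, PD-L1 tumor/immune, HPV) follow
a logistic link on the standardised log CTLA-4 density; pT (ordinal
1–4) uses a proportional-odds link. Default effects plant the
directions reported for inflamed tumors: higher density → lower pT/pN,
more frequent PD-L1 positivity. Missingness (drawn after the values,
so planted effects refer to complete data) defaults to realistic rates
(40–85 % depending on the covariate) and can be disabled.

**What the generator does not emulate:** photorealistic histology,
staining gradients, scanner artifacts, melanin pigment, tissue folds,
or segmentation-resistant morphologies. Passing tests therefore
demonstrate the *logic* of the workflow (artifact detection, exclusion
accounting, merging, statistics) under its stated assumptions, not
segmentation performance on real slides.

## Segmentation

Nuclei are connected components of the nuclear channel above a global
threshold (0.30 OD, above the 0.15 tissue background), split by
marker-controlled watershed where distinct intensity maxima touch
(markers = local maxima with ≥ 3 µm separation, ordered
lexicographically by (row, col) for bit-reproducibility). Components
outside 20–400 µm² are discarded.

Stain measurement is competitive: one Euclidean distance transform
assigns every pixel to its nearest detected centroid, so an adjacent
unstained nucleus cannot double-count a lymphocyte's ring. Per cell,

* `mean_stain` = mean stain over the cell's territory within 7 µm of
  the centroid;
* `membrane_score` = stain mass in the 4.5–7 µm annulus divided by the
  mass within 9 µm (0 when the cell carries no stain).

A ring-stained lymphocyte scores ≈ 0.95; a uniformly filled cell scores
the annulus-area fraction ≈ 0.33.

**Positivity threshold τ.** A ring covers ≈ 0.34 of the measurement
disc, so a specifically stained cell's *mean* stain is ≈ 0.34 × the
ring amplitude. The default τ is the midpoint between background and
that expected cell mean (0.5 · 0.34 · amplitude ≈ 0.17 OD for the
default profiles). τ lives in the configuration, never in code paths.

**Tissue area** is the pixel count of the thresholded (lightly
smoothed) channel sum after diamond closing and small-object removal,
× (µm/px)²/10⁶. On a rendered 0.6 mm disc this recovers π·0.3² mm²
within ~1 %.

**Resolution limits.** At 1 µm/px, recovery of planted positive-cell
counts is within ~3 % up to ≈ 2000 cells/mm²; extreme lymphoma-like
densities (≳ 4000 cells/mm²) undercount by 10–17 % because crowded
nuclei merge. Both clones are affected equally, so concordance,
exclusion and association logic are unaffected; absolute density means
for the densest entities are conservative.

## Artifact detection and exclusion

Stained regions are connected components of the smoothed stain channel
above half of τ, after closing and hole filling (a ring becomes a
disc). Five features feed a standardised logistic scorer: log₁₀ area,
circularity (4πA/P², Crofton perimeter), mean membrane score of member
positive cells, stained-area fraction (raw stained pixels / filled
region — low for hollow rings, ≈ 1 for diffuse fills) and log₁₀ cell
count. Training uses a per-entity stratified patient split (75 % train,
rounding half up per entity, seeded shuffle); performance is the
held-out ROC AUC, computed as the exact pairwise probability that a
non-specific region outscores a specific one (ties half-credit).

The per-spot non-specific fraction is the share of detected cells whose
centroid lies in a region classified non-specific, relative to **all**
detected cells (the alternative denominator, stained cells only, is a
configuration switch). A spot with fraction ≥ 0.05 is excluded for that
antibody — the boundary is closed: exactly 5 % is excluded, 4 % is
retained.

`discordance_score` (|a−b|/(a+b) of the two clone densities) is
provided to flag candidate spots for review; it never excludes
directly.

## Merging and statistics

Per patient: both clones valid → arithmetic mean of densities; one
excluded/missing → the other; both → patient not analyzed. The
CTLA-4/CD3 ratio is reported as a percentage (×100); the ratio is
missing when CD3 = 0 or the merged density is missing. Reported
percentages round half away from zero to one decimal (126/4723 → 2.7 %).

Association analysis dichotomizes the analyte at the median of the
patients analyzable for that covariate (ties low; an all-equal analyte
is an error), builds the contingency table against the covariate levels
and applies the chi-square test without continuity correction, two
sided. Missing data are dropped per covariate. No multiple-testing
correction is applied. Covariates reduced to a single level are skipped
with a warning, not an error.

## Problem sizes and seeds

Simulated studies use desk-scale sizes chosen as the package's own
defaults: the default cohort is 10 entities × 10 patients (200 spot
images); the concordance study uses 500 patients (1000 images); the
segmentation-recovery study 20 noiseless spots of ~100 lymphocytes; the
type-I-error study 200 statistics-only replicates of 200 patients. All
randomness flows from `numpy` `SeedSequence`s derived from the cohort
seed (per-patient streams), the split seed, and explicit seeds for
permutation tests, so every figure in the reports is bit-reproducible.

## Known limitations

* Classical thresholds replace trained networks; the contract (per-cell
  records, region decisions, split/AUC evaluation) is the normative
  part, not the technique.
* Undercounting at extreme density (above).
* The half-plane artifact territory is geometrically simple; detectors
  that exploit its shape would not transfer to real artifacts — the
  classifier therefore uses only shape/texture summaries that have
  real-data analogues.
* The CTLA-4/CD3 ratio convention (×100) is a documented choice; ratios
  from other conventions differ by a constant factor.
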