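# tmaquant

Quantification of CTLA-4⁺ lymphocytes on tissue-microarray (TMA)
immunohistochemistry with **two independent antibody clones** and
automated exclusion of non-specific staining.

## The problem

CTLA-4 is an inhibitory immune-checkpoint receptor on T-cell subsets.
Measuring the density of CTLA-4⁺ lymphocytes (cells/mm²) across many
tumor entities on TMAs is attractive — one slide carries hundreds of
0.6 mm tissue spots — but available antibodies cross-react: each clone
distinctly stains some tissues that do not contain the target (e.g.
diffuse cytoplasmic staining of adrenocortical or hepatocellular tumor
parenchyma). Because cross-reactivities are clone-specific, staining
**consecutive sections** of the same spot with two clones lets an
automated pipeline tell true lymphocytic staining (membranous rings)
from artifact (large diffuse regions) and drop the affected
spot/antibody combinations.

`tmaquant` implements that workflow as a tested, seeded, desk-scale
pipeline, together with a synthetic TMA-cohort generator that provides
complete ground truth:

1. **simulate** — paired two-channel spot images (nuclear counterstain +
   antibody stain) for two virtual clones sharing one lymphocyte
   population, with per-patient log-normal densities, planted
   clinicopathological covariates (pT, pN, PD-L1, HPV) and entity- and
   clone-specific cross-reactive territories;
2. **segment** — deterministic nucleus detection (threshold +
   marker-controlled watershed), CTLA-4 positivity calling and a
   membrane-localisation score per cell; tissue area in mm²;
3. **qc-train / qc-apply** — stained-region features (area, circularity,
   membrane score, stained-area fraction, cell count) feed a linear
   classifier trained on a per-entity stratified 75/25 patient split and
   evaluated by held-out ROC AUC; a spot with ≥ 5 % of its cells in
   regions called non-specific is excluded for that antibody;
4. **quantify** — density = positive cells / area; per patient the two
   clone densities are averaged, falling back to the clean clone when
   the other was excluded; CTLA-4/CD3 ratio = 100 · density(CTLA-4) /
   density(CD3) (CD3 densities are an input column);
5. **stats** — inter-clone Pearson concordance, per-entity/category
   summaries (n, %, mean ± SD, median) and two-sided chi-square
   associations of the median-dichotomized analyte with each covariate,
   dropping missing data per covariate.

## Worked example

```sh
tmaquant run-all --seed 1 --out-dir out/
```

runs the default cohort (10 tumor entities × 10 patients, cross-reactive
staining planted for clone A in adrenal cortical adenoma and for clone B
in pheochromocytoma and hepatocellular carcinoma) and prints

```
analyzed 100 patients; excluded 30 of 200 stains (15.0%)
```

meaning every planted cross-reactive spot (3 entities × 10 patients, one
clone each) — and nothing else — was excluded, and all 100 patients kept
an analyzable density from at least one clone. `out/run_log.json`
records (seed 1):

* held-out artifact-detector AUC **1.0**;
* inter-clone concordance `r` rising from **0.969** before exclusion to
  **1.000** after it — the artifact spots are what destroys concordance;
* the exclusion accounting per clone (10.0 % of clone-A stains, 20.0 %
  of clone-B stains, 15.0 % combined — the synthetic cohort plants
  artifacts in 3 of 10 entities, so its exclusion rate is higher than a
  90-entity cohort's would be).

`out/summary_entity.csv` reproduces the expected density ordering
(lymphomas ≫ epithelial tumors ≫ mesenchymal tumors) and
`out/associations_density.csv` recovers the planted directions (higher
CTLA-4⁺ density with lower pT/pN, PD-L1 positivity).

Library use mirrors the CLI:

```python
from tmaquant import PipelineConfig, default_cohort_config, run_cohort

result = run_cohort(PipelineConfig(cohort=default_cohort_config(seed=1)))
print(result.exclusion_report.combined_percent)
print(result.concordance["post_r"])
```

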