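# seasonrhythm

Seasonal (circannual) rhythm analysis of cognition, clinical diagnosis, CSF
biomarkers, and brain gene-module expression — with seeded synthetic-cohort
generators so every stage is verifiable by parameter recovery without any
restricted data.

## What it does

- **Cosinor regression** (`seasonrhythm.cosinor`): free-phase annual cosine
  models (`cos` + `sin` quadrature pair) with covariates; amplitude,
  acrophase/nadir timing, standardized amplitude (SD units), 2-df F-test of
  rhythmicity, age-equivalent effect size, and participant-resampling
  percentile bootstrap CIs.
- **Seasonal logistic models** (`seasonrhythm.logistic`): odds of MCI/dementia
  as a continuous cosine of assessment date (2-df likelihood-ratio test) or as
  the categorical winter/spring (Jan–Jun) vs summer/fall (Jul–Dec) contrast
  with Wald CIs.
- **Group-modulated rhythms** (`seasonrhythm.stratified`): a binary group may
  shift both the level (t-test) and the rhythm (joint 2-df interaction F-test)
  of an outcome; confounder-adjustment sweeps with per-model complete-case
  samples; per-modifier interaction scans.
- **Gene-module rhythmicity** (`seasonrhythm.modules`): per-gene z-scoring,
  mean-of-z module scores, cosinor scans on date of death, cognition
  association scans, max-statistic permutation family-wise adjustment
  (gene→module label shuffling, or date permutation), the three-criterion
  module selection with a ±2-month circular phase window, and the
  module×phenotype Spearman/Bonferroni grid.
- **TF enrichment** (`seasonrhythm.tfenrich`): strand-aware TSS points,
  TSS-to-TFBS proximity linking (0-based half-open BED coordinates, default
  2,000 bp window), and per-module logistic enrichment over a TF catalogue
  with Bonferroni correction (α = 0.05/161 by default).
- **Synthetic cohorts** (`seasonrhythm.simulate`): pure functions of
  (config, seed) for cohort tables, CSF panels, block-correlated expression
  matrices with planted rhythmic modules, and TFBS layouts with planted
  enrichments; every dataset ships with a `truth.json` of its generating
  parameters.

## CLI

```bash
seasonrhythm simulate --preset combined --seed 1 --out data/
seasonrhythm cosinor  --input data/cohort.tsv \
    --covariates age_years,sex,education_years --bootstrap 1000 --seed 17
seasonrhythm logistic --input data/cohort.tsv --mode categorical \
    --covariates age_years,sex,education_years
seasonrhythm stratified --input data/cohort.tsv --group group \
    --covariates age_years,sex,education_years
seasonrhythm sweep --input data/cohort.tsv --sets sets.yaml --out sweep.tsv
seasonrhythm simulate --preset expression --seed 2 --out expr/
seasonrhythm modules --expr expr/expression.tsv --modules expr/module_defs.tsv \
    --meta expr/sample_meta.tsv --nperm 10000 --seed 7 --out mods/
seasonrhythm simulate --preset tfbs --seed 3 --out tf/
seasonrhythm tfenrich --genes tf/genes.bed --tfbs tf/tfbs.bed \
    --modules tf/module_defs.tsv --window 2000 --out enrich/
```

Presets: `combined` (n=2,761 pooled three-cohort table), `mars`, `sds`
(n=271 memory-clinic table), `cnc` (n=321 CSF panel), `expression`
(5,000 genes × 507 samples, 47 modules, 4 planted), `tfbs` (161-TF catalogue).

## Data formats

Long-format participant tables as CSV/TSV with ISO-8601 dates; expression as
genes×samples TSV or MatrixMarket + name files; module definitions as
two-column TSV (gene, module); gene annotation as BED6 (or GFF3, converted
to 0-based internally); TFBS as BED4 with the TF name in column 4.
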