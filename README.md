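# ecocline

Tools for quantifying the flattening of a tree-cover gradient and testing
whether phenotypic divergence between habitats along that gradient has been
lost. The package implements the full analysis as a reusable, tested
pipeline driven entirely by synthetic data:

- **`ecocline.synthetic_data`** — rasters with linear latitudinal cover
  trends, noise and deforestation patches; sampling sites labelled by a
  potential-forest mask; lognormal individuals whose log-trait means are
  linear in site tree cover, with equal/proportional/unrelated region
  covariances by configuration; historical cohorts from a pre-shift model.
- **`ecocline.gradient`** — latitudinal band means (5 km bands by default),
  southward alignment between regions (2.5°), region × latitude ANCOVA on
  band means, and strict-threshold deforestation masks.
- **`ecocline.morphometrics`** — log-log allometric size correction,
  likelihood-ratio tests of covariance equality/proportionality (Flury
  hierarchy) gating the pooled PCA, per-era PCAs, and within-era score
  normalization.
- **`ecocline.divergence`** — Wilcoxon rank-sum tests (exact for small
  untied groups, tie/continuity-corrected normal otherwise) under
  Dunn-Šidák family-wise control, plus between-habitat F_ST summaries.
- **`ecocline.resampling`** — habitat-stratified bootstrap null for absence
  of divergence at the individual and whole-site level, with a calibration
  harness.
- **`ecocline.projection`** — sample-size-weighted trait-on-cover
  regressions, the trait association screen, and raster projection maps
  with block-mean aggregation and post-aggregation back-transform.
- **`ecocline.pipeline` / `ecocline.cli`** — single-config end-to-end run
  with per-stage artifacts, figures and a provenance log.

Rasters are exchanged as ESRI ASCII grids (`.asc`, plain text, readable by
standard GIS tools); tables as CSV; PCA models as JSON.

## CLI

```sh
ecocline all --seed 1 --out runs/demo          # full pipeline, demo scenario
ecocline simulate --seed 1 --out runs/inputs   # synthetic inputs only
ecocline gradient bands --raster runs/demo/cover_Central.asc --band-km 5 \
    --region Central --out central_bands.csv
ecocline gradient ancova --a central_bands.csv --b west_bands.csv --shift-deg 2.5
ecocline gradient defmask --t0 pre.asc --t1 post.asc --threshold 10 --out mask.asc
ecocline morpho --morph runs/demo/individuals.csv --out runs/morpho
ecocline diverge --morph runs/morpho/morph_derived.csv --region Central --out div.csv
ecocline resample --source central.csv --counts forest=27,ecotone=11 \
    --trait PC1 --observed 0.02 --B 1000 --seed 1 --out null.csv
ecocline project --raster cover.asc --sites sites.csv --morph morph.csv \
    --trait log_wing --out map.asc
```

A YAML config (see `ecocline.pipeline.RunConfig`) controls all constants
(band width, alignment shift, deforestation threshold, bootstrap replicates,
alpha, family size, historical cutoff) and the synthetic scenario; CLI flags
override the config. Identical seeds reproduce identical bundles.

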