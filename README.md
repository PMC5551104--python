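# coarsesdm

**How much does county-resolution georeferencing bias a species
distribution model?**

Many occurrence records in citizen-science databases are georeferenced
only to a county; modelers then substitute the county centroid's (or the
county-averaged) environment for the unknown true locality. `coarsesdm`
measures what that substitution does to presence-background species
distribution models (SDMs) — on synthetic landscapes where the true
distribution is known exactly, so every error is attributable to the
coarsening and not to ecology.

It is aimed at spatial ecologists and methods researchers who want a
transparent, fully seeded test bed for georeferencing-degradation
questions, and it ships every stage as a reusable library:

- **synthetic landscapes** — autocorrelated monthly climate (exponential-
  covariance Gaussian fields via circulant embedding), a Voronoi county
  map with a small-homogeneous-county region and a large-heterogeneous-
  county region, virtual species with product-Gaussian niches, and
  suitability-weighted occurrence sampling;
- **climate preparation** — the 19 bioclim variables from monthly normals,
  z-normalization, raster PCA, component selection, and per-county
  centroid-offset / climatic-variance metrics;
- **record treatments** — database-style filters (one record per county,
  >= 10 records per species) and five training datasets per species: true
  localities, county centroids, county averages, and 50/50 mixes of each
  with true localities;
- **a MaxEnt re-implementation** — the L1-regularized Gibbs distribution
  over background cells, with the classic automatic feature classes
  (linear, quadratic, product, hinge), sample-size-dependent
  regularization, coordinate-descent fitting with verified KKT optimality,
  and raw/logistic output;
- **model comparison** — presence-background AUC, minimum-training-
  presence and sensitivity-equals-specificity thresholds, thresholded
  range areas and overprediction ratios, the niche-overlap statistics
  Schoener's D, Hellinger similarity I and relative rank RR, and Wilcoxon
  signed-rank paired tests.

The model core follows scikit-learn conventions (`MaxentModel().fit(X, y)`
with `y = 1` presence / `y = 0` background rows, fitted attributes with
trailing underscores, `get_params`/`set_params`), as does the PCA
transformer.

## The statistic at the core

A fitted model is the Gibbs distribution over background cells

    p(x) = exp(lambda . f(x)) / Z,

where `f` expands environmental covariates into [0,1]-scaled features and
`lambda` maximizes the penalized presence log-likelihood
`mean_pres(lambda . f) - log Z - sum_j beta_j |lambda_j|`. Each treatment's
model is binarized at two thresholds; the headline quantity is the
**overprediction ratio** `area(treatment) / area(true localities)`, and
surfaces are further compared with `D`, `I`, `RR` (all in [0, 1], 1 =
identical) and AUC.

## Worked example

```python
from coarsesdm import ExperimentConfig, SpeciesPlanEntry, run_experiment, summarize

config = ExperimentConfig(
    n_rows=90, n_cols=90,                  # planar grid, split at x = 45
    mean_area_small=16, mean_area_large=160,
    n_bg=1200,
    species_plan=(SpeciesPlanEntry("large", 10, 3, 0.5),
                  SpeciesPlanEntry("small", 10, 3, 0.5),
                  SpeciesPlanEntry("small", 30, 2, 0.75)),
    master_seed=7,
)
print(summarize(run_experiment(config)))
```

prints (abridged):

```
Predicted-area ratios vs true-locality models (percent):
                 mean_pct_mtp  median_pct_mtp  mean_pct_ses  median_pct_ses
treatment
true_locality           100.0           100.0         100.0           100.0
county_centroid         184.2           163.9         169.4           158.8
county_average          131.0           126.1         127.0           121.9
mix_centroid            182.5           193.3         144.8           136.1
mix_average             133.7           113.2         133.1           124.1

Mean niche-overlap metrics vs true-locality models:
                      I       D      RR
treatment
county_centroid  0.8844  0.6608  0.8061
county_average   0.8614  0.6135  0.7777
mix_centroid     0.9450  0.7768  0.8782
mix_average      0.9534  0.7783  0.8809
```

Reading it: with only 10-30 records each, these eight virtual species'
county-centroid models predict on average 1.84x the reference range area
at the minimum-training-presence threshold (`mean_pct_mtp` 184% vs 100%),
county-averaged environments reduce but do not remove the inflation, and
the overlap statistics tell the same story (centroid I = 0.88 vs the
ideal 1.0). On the full default configuration (120 x 120 grid, 62 species
spanning 10-300 records) the same directional pattern holds, the
discrepancy shrinks with record count (negative Spearman correlation),
and the small-county region is less affected than the large-county region
at matched sample sizes.

The same pipeline is scriptable from the shell:

```
coarsesdm simulate --seed 1 --out landscape/      # rasters + county table
coarsesdm run --config experiment.cfg --seed 1 --out results/
```

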