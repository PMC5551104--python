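# Methods

`coarsesdm` quantifies how coarse, county-resolution occurrence records
bias presence-background species distribution models (SDMs) relative to
models built from exact localities. Because the bias can only be measured
when the *true* distribution is known, the package works entirely on
synthetic landscapes with virtual species: the truth is constructed, the
degraded data are derived from it, and every downstream discrepancy is
attributable to the georeferencing treatment alone.

## Synthetic landscape

**Climate.** Monthly maximum/minimum temperature and precipitation are
generated on a regular planar grid. Each monthly mean-temperature surface
is a linear north-south gradient (`gradient_strength`, default 10 °C
across the domain), a seasonal sinusoid (`seasonal_amplitude`, default
12 °C, coldest in month 1), and a zero-mean Gaussian random field with
exponential covariance `exp(-d/ell)` (`autocorr_length` ell, default 12
cells). Monthly anomaly fields share a common annual field (inter-month
correlation 0.8). The diurnal range is `1 + softplus(...)` degrees, so
`tmax - tmin >= 1` everywhere by construction. Precipitation passes a
drive surface (west-east gradient, seasonally rotating phase, Gaussian
noise) through a softplus map, which keeps it nonnegative while preserving
the spatial autocorrelation structure near zero (truncation would not).

Random fields are sampled by circulant embedding: the exponential
covariance is laid out on a doubled torus, diagonalized by the 2-D FFT,
and the field is an inverse FFT of spectrally weighted complex white
noise. Slightly negative embedding eigenvalues (small for this kernel at
2x padding) are clamped to zero; the realized semivariogram matches the
analytic exponential variogram to a few percent (tested).

**Counties.** The domain is split at a meridian-like line `split_x`. Cells
west of it form the *large-county region*, cells east the *small-county
region* (emulating the contrast between large, climatically heterogeneous
western US counties and small, homogeneous eastern ones). Voronoi seeds
are placed uniformly in each region with density `1/mean_area`
(defaults 240 and 16 cells), and every cell joins its nearest seed.
Because climate field statistics are spatially uniform, within-county
climatic variance is driven by county size alone, which is exactly the
contrast the experiment needs. County centroids are arithmetic means of
member cell centers, snapped to the nearest member cell if the mean falls
outside a concave county — so every centroid is raster-extractable.

**Virtual species.** A species is a product-Gaussian suitability function
in environmental space: `s(x) = prod_k exp(-(z_k - c_k)^2 / (2 w_k^2))`.
Niches are defined on the leading `niche_dim = 3` principal components of
the climate (the dominant climate axes). This matters: a product-Gaussian
over many (~9) components with sub-SD widths is a degenerate spike —
suitability is near zero almost everywhere and no presence-background
model can recover it — whereas a low-dimensional niche is the standard,
ecologically plausible virtual-species design. Occurrences are sampled
without replacement across cells with probability proportional to
suitability; each record carries the id of the county that truly contains
it. Sampling can be confined to one county region so that strictly
"eastern"/"western" species exist by construction. Observer bias (e.g.,
clustering near population centers) is deliberately not modeled.

## Climate preparation

The 19 standard bioclim variables (BIO1-BIO19) are derived from the 36
monthly layers using the ANUCLIM/WorldClim definitions; quarters are the
twelve wraparound 3-month windows, ties resolving to the earliest window
in January-start order. BIO15's denominator is `1 + BIO12/12` (the
WorldClim convention, finite in arid cells). All standard deviations in
the package — normalization, BIO4, BIO15, and the county summaries — are
population SDs (divide by N), the raster-statistics convention.

Layers are normalized to zero mean and unit SD over the study mask, then
reduced by PCA (eigendecomposition of the cell-by-layer covariance;
components ordered by descending eigenvalue; the largest-magnitude loading
of each component is made positive). The smallest k components whose
cumulative variance fraction reaches `cum_threshold = 0.985` become the
model covariates (k is typically 8-9 on these synthetic stacks, where the
19 variables are less mutually redundant than on real continental
climatologies).

Per-county representativeness metrics, all weighted by eigenvalue
fractions `w_k = lambda_k / sum(lambda)`:

- *offset metric*: `sum_k w_k |z_k(centroid cell) - mean_county(z_k)|` —
  how unrepresentative the centroid is of county-average climate;
- *variance metric*: `sum_k w_k Var_county(z_k)` — within-county climatic
  heterogeneity;
- per-layer within-county SD.

Absolute (not signed) per-component differences are combined additively;
a weighted Euclidean norm would rank counties identically.

## Record filters and the five treatments

Filters, applied in input order (input order stands in for database
insertion order): records whose coordinates do not fall in their claimed
county are dropped; exact duplicate (species, cell) records are dropped;
only the first record per (species, county) is kept — which makes each
species' sample size equal to that of its county-centroid sister dataset —
and species with fewer than 10 records are excluded.

Per species, five training sets:

1. **true_locality** — covariates at the record cells (the reference);
2. **county_centroid** — coordinates replaced by the county centroid,
   covariates read at the centroid cell;
3. **county_average** — covariates replaced by per-county means of each
   component layer (records no longer tied to any cell; the model consumes
   covariate vectors only, so this needs no special casing);
4. **mix_centroid** and 5. **mix_average** — `floor(n/2)` randomly chosen
   records converted as in (2)/(3) respectively, the *same* selection in
   both, the rest kept as true localities. Flooring at odd n biases toward
   the higher-quality data, the conservative choice.

East/west subsetting: a species is strictly eastern (western) iff every
record lies east (west) of `split_x`; straddlers are excluded. Sample-size
matching first trims the larger-median side to the other side's [min, max]
count range, then removes random species (seeded, always from the side
with the larger median and with counts above the opposing median) until
the medians differ by at most 2 records or no removal helps.

## MaxEnt model

The SDM core is a from-scratch re-implementation of the classic MaxEnt
presence-background model (v3.3-era behavior), not a wrapper: the Gibbs
distribution over background cells maximizing

    L(lambda) = mean_presence(eta) - log sum_bg exp(eta) - sum_j beta_j |lambda_j|

with `eta = lambda . f(x)` over an automatic feature expansion. Features:
linear and quadratic always; hinge (both orientations) from 15 presences;
pairwise products from 80 — the classic auto-feature thresholds. Hinge
knots are 20 equally spaced interior points per covariate over the
background range (a bounded-size departure from MaxEnt's per-presence-value
knots). All features are min/max-scaled to [0, 1] on the background, with
out-of-range values clamped; features constant on the background are
dropped.

Regularization: `beta_j = beta_multiplier * class_default * dev_j / sqrt(n)`.
For linear/quadratic/product features the class default interpolates the
classic table (1.0 at n <= 10 through 0.05 at n >= 100) and `dev_j` is the
presence SD of the feature clamped to [0.05, 0.5]. For hinge features the
class default is 0.5 with `dev_j = 1` — the rule used by maxnet, the
reference R re-implementation. The SD-scaled alternative for hinge
features makes `beta_j` collapse toward zero for knots outside the
presence range, which lets weights on near-collinear hinge features grow
without bound and stalls convergence; the constant rule keeps the problem
well-conditioned.

Optimization is cyclic coordinate descent with prox-Newton soft-threshold
updates, backtracking on the exact objective, incremental updates of the
Gibbs weights, and a per-sweep full refresh against floating-point drift.
Convergence requires both a relative objective change below `tol = 1e-5`
and near-satisfaction of the stationarity (KKT) conditions; hitting
`max_iter = 500` sweeps flags the model as non-converged (never silent,
and non-converged fits are excluded from experiment aggregates and
listed). At the optimum, `|mean_presence(f_j) - E_model(f_j)| <= beta_j`
with equality (signed) for active features — asserted in the tests at
1e-3.

Outputs: *raw* `exp(eta)/Z` (sums to 1 over the background) and *logistic*
`tau e^H raw / (1 + tau e^H raw)` with prevalence `tau = 0.5` and H the
entropy of the fitted distribution — a strictly increasing transform, so
rank-based quantities are identical between the two. Presence cells are
not excluded from the background (plain uniform background sampling,
default 10,000 cells or the whole mask if smaller; the experiment uses
2,000 on its 14,400-cell grids and shares one seeded background across all
species and treatments).

## Comparison metrics

- **AUC**: Mann-Whitney rank formulation on presence vs background scores,
  ties counting 1/2; invariant under monotone transforms.
- **Thresholds**: *minimum training presence* = the lowest predicted value
  among training presences; *sensitivity = specificity* = the candidate
  (from the sorted union of observed scores) minimizing
  |sensitivity − specificity|, specificity computed on background points as
  pseudo-negatives, float-roundoff ties resolving to the lower threshold.
- **Area**: cells with prediction >= threshold (inclusive — with a strict
  inequality the minimum-training-presence threshold would exclude its own
  defining record). Overprediction ratio = area(treatment)/area(reference),
  also reported as percent.
- **Niche overlap** on mask-normalized surfaces:
  Schoener's `D = 1 - 0.5 sum|p_A - p_B|`; Hellinger-based
  `I = 1 - 0.5 sum(sqrt(p_A) - sqrt(p_B))^2`; relative rank RR = the
  probability that a random cell pair is ordered identically by the two
  surfaces, computed exactly by O(n log n) concordant-pair counting.
  Pairs tied in both surfaces count as agreement, pairs tied in exactly
  one count 1/2 — so self-comparison is exactly 1.
- **Wilcoxon signed-rank** (two-sided) for paired per-species comparisons:
  zero differences dropped, exact null for n <= 25 without ties, tie-
  corrected normal approximation otherwise.

D and I use the raw (normalized) surfaces; areas use the logistic output
with thresholds derived from the same output (rank-equivalent either way).

## The experiment

`run_experiment` wires everything together, deterministically: every
stage's RNG seed is an explicit function of (master seed, stage name,
species index) via `SeedSequence`, so any species' pipeline can be
replayed in isolation. Defaults, chosen as a desk-scale rendition of the
study design:

- 120 x 120 grid, split at the x-midline; county mean areas 16 / 240 cells
  (~450 small, ~30 large counties);
- 62 virtual species: per region 10 species each at target sample sizes
  10 and 30; the small region additionally 6 each at 100 and 300 and 10 at
  25. Targets are *post-filter* record counts (distinct occupied
  counties): the sampler draws suitability-weighted occurrences and keeps
  the first per county until the target (or the species' suitable range)
  is exhausted. The large region's ~30 counties cap attainable counts near
  25, mirroring how the sparsely collected west capped real sample sizes;
  the target-25 small-region block exists so the region contrast can be
  made at genuinely comparable record counts. Niche widths scale with
  target size (0.5-2.5 component SDs): widespread species are climate
  generalists. A species whose niche supports fewer than 10 occupiable
  counties is redrawn (up to 20 candidate niche centers) — the experiment,
  like any occurrence-database study, only models species with enough
  records.
- per-species treatment fits with shared background; non-converged fits
  excluded and reported.

Aggregates mirror the natural summaries of such a study: per-treatment
mean/median predicted-area ratios at both thresholds; per-treatment mean
I/D/RR; AUC summaries; paired Wilcoxon tests (true vs centroid AUC;
centroid vs average and mix vs centroid overlaps); record count vs
|ratio − 1| with its Spearman correlation; and the matched-n region
contrast (median percent area change, signed and absolute, small vs large
county region, with a Mann-Whitney p on the absolute discrepancies).

## What passing tests do and do not show

The synthetic world reproduces, qualitatively and robustly: centroid
models overpredict (mean minimum-training-presence area ratio well above
1, strongest in the large-county region), the discrepancy shrinks with
record count (negative Spearman correlation), mixes sit between pure
treatments, and AUC degrades under coarsening. Effect *magnitudes* are
landscape-specific and larger than on real continental data (a 120-cell
domain with 12-cell climate correlation makes centroid displacement
relatively more damaging than 30-arcsec PRISM cells in small eastern
counties); numeric agreement with any real-data study is out of scope.
The region contrast (small less affected than large) holds clearly on
average but is the weakest signal at ~20 species per side and n ~ 10-25
records: at some seeds the matched-subset medians come within a few
percentage points. The generator also omits observer bias, elevation, and
coastline masks; all cells are valid and sampling effort is proportional
to suitability, so tests say nothing about spatially biased collection.

## Numerical notes

- All generator outputs are pure functions of their arguments including
  seeds; experiment tables are byte-identical across reruns.
- PCA eigenvalues are clipped at zero; components of (numerically) zero
  variance are never selected.
- `threshold_sens_eq_spec` treats gaps within 1e-12 as tied (1-ulp
  asymmetries between sensitivity and specificity fractions would
  otherwise break the tie-to-lower rule).
- Counties with no masked-in cells raise; single-cell counties have zero
  variance and SD by the population convention.
- The coordinate-descent weight update is capped at ±5 per step with
  backtracking, which cannot affect the optimum (the objective is concave)
  but prevents overshoot on nearly flat directions.
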