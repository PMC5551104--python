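"""End-to-end synthetic experiment orchestration.

Simulate a landscape, derive and reduce the climate covariates, create
virtual species, build the five training-data treatments, fit a MaxEnt
model per treatment, and aggregate the comparison metrics into summary
tables: per-treatment mean/median predicted-area ratios at both thresholds,
mean niche-overlap statistics, AUC summaries and paired Wilcoxon tests, a
sample-size-versus-discrepancy table, and the small-county-region versus
large-county-region contrast under matched sample sizes.

Every stage derives its RNG seed from the master seed through an explicit
function of (master seed, stage name, species index), so any single
species' pipeline is reproducible in isolation.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import climate as climate_mod
from . import comparison, treatments
from .bioclim import derive_bioclim
from .grid import EnvStack, GridSpec, write_ascii_grid
from .maxent import MaxentModel, sample_background
from .simulate import (LARGE_REGION, SMALL_REGION, VirtualSpecies,
                       generate_counties, generate_monthly_climate,
                       sample_occurrences, true_suitability)

_STAGE_CODES = {"climate": 1, "counties": 2, "background": 3,
                "species": 4, "occurrences": 5, "mixing": 6, "matching": 7}


def child_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic child seed for (master seed, stage, index)."""
    ss = np.random.SeedSequence([int(master_seed), _STAGE_CODES[stage], int(index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class SpeciesPlanEntry:
    """One block of virtual species sharing a region and sampling intensity.

    ``n_target`` is the number of distinct occupied counties to aim for
    (the record count after the one-per-county filter); ``width_mult``
    scales the niche width in units of the per-component SD over the
    domain, so higher-n species are wider-ranging generalists.
    """

    region: str          # "small" | "large"
    n_target: int
    count: int
    width_mult: float


DEFAULT_SPECIES_PLAN = (
    SpeciesPlanEntry("large", 10, 10, 0.5),
    SpeciesPlanEntry("large", 30, 10, 0.75),
    SpeciesPlanEntry("small", 10, 10, 0.5),
    SpeciesPlanEntry("small", 30, 10, 0.75),
    SpeciesPlanEntry("small", 100, 6, 1.25),
    SpeciesPlanEntry("small", 300, 6, 2.5),
    # the region contrast needs small-region species whose realized record
    # counts overlap the large region's attainable range (its ~30 counties
    # cap one-per-county records near 25), emulating the comparable-n
    # east/west subsets of the real study design
    SpeciesPlanEntry("small", 25, 10, 0.7),
)

_REGION_TAGS = {"small": SMALL_REGION, "large": LARGE_REGION}


@dataclass
class ExperimentConfig:
    """Study conditions of the synthetic experiment."""

    n_rows: int = 120
    n_cols: int = 120
    cell_size: float = 1.0
    split_frac: float = 0.5          # split_x as a fraction of domain width
    gradient_strength: float = 10.0
    autocorr_length: float = 12.0
    seasonal_amplitude: float = 12.0
    mean_area_small: float = 16.0
    mean_area_large: float = 240.0
    cum_threshold: float = 0.985
    niche_dim: int = 3               # species respond to the leading components
    n_bg: int = 2000
    beta_multiplier: float = 1.0
    n_knots: int = 20
    max_iter: int = 500
    mix_fraction: float = 0.5
    min_records: int = 10
    species_plan: tuple = DEFAULT_SPECIES_PLAN
    master_seed: int = 0
    out_dir: str | None = None
    save_rasters: bool = False

    @property
    def split_x(self) -> float:
        return self.cell_size * self.n_cols * self.split_frac

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        """Parse a flat ``key = value`` config file."""
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "species_plan":
                plan = []
                for blk in value.split(";"):
                    region, n_target, count, width = blk.strip().split(":")
                    plan.append(SpeciesPlanEntry(region, int(n_target),
                                                 int(count), float(width)))
                kwargs[key] = tuple(plan)
            elif key in ("out_dir",):
                kwargs[key] = value
            elif key in ("save_rasters",):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif key in ("n_rows", "n_cols", "n_bg", "n_knots", "max_iter",
                         "min_records", "master_seed", "niche_dim"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


@dataclass
class ExperimentReport:
    """All result tables from one experiment run."""

    per_species: pd.DataFrame
    table_area_ratios: pd.DataFrame
    table_overlap: pd.DataFrame
    auc_summary: pd.DataFrame
    paired_tests: pd.DataFrame
    sample_size_effect: pd.DataFrame
    east_west: pd.DataFrame
    county_summary: pd.DataFrame
    excluded: list
    n_components: int = 0
    species_meta: pd.DataFrame = field(default=None)


# ---------------------------------------------------------------------------


def _expand_plan(plan) -> list[SpeciesPlanEntry]:
    out = []
    for entry in plan:
        out.extend([entry] * entry.count)
    return out


def _sample_species_records(species, components, partition, region_tag,
                            n_target, min_records, seed) -> pd.DataFrame | None:
    """Suitability-weighted occurrences yielding up to ``n_target`` distinct
    counties (records beyond the first per county are dropped downstream)."""
    s = true_suitability(species, components)
    in_region = np.isin(
        partition.labels,
        partition.centroids.index[partition.centroids["region"] == region_tag])
    support = int(np.count_nonzero((s > 0) & in_region & components.mask))
    if support == 0:
        return None
    n_draw = min(support, max(6 * n_target, n_target + 30))
    occ = sample_occurrences(species, components, partition, n=n_draw,
                             seed=seed, region=region_tag)
    first = occ[~occ.duplicated(subset="county_id", keep="first")]
    first = first.head(n_target)
    if len(first) < min_records:
        return None
    return first.reset_index(drop=True)


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run the full synthetic experiment described by ``config``."""
    t0 = time.time()
    spec = GridSpec(config.n_rows, config.n_cols, config.cell_size)
    monthly = generate_monthly_climate(
        spec, config.gradient_strength, config.autocorr_length,
        config.seasonal_amplitude, seed=child_seed(config.master_seed, "climate"))
    partition = generate_counties(
        spec, config.split_x, config.mean_area_small, config.mean_area_large,
        seed=child_seed(config.master_seed, "counties"))

    env = derive_bioclim(monthly)
    normalized, normalizer = climate_mod.normalize_layers(env)
    pca = climate_mod.fit_pca(normalized)
    components = climate_mod.select_components(pca, normalized,
                                               config.cum_threshold)
    background = sample_background(
        components, config.n_bg,
        seed=child_seed(config.master_seed, "background"))

    # virtual species respond to the leading components only (a
    # low-dimensional niche on the dominant climate axes); models are
    # trained on the full component stack
    d = min(config.niche_dim, components.n_layers)
    species_env = EnvStack(spec=spec, layers=components.layers[:d],
                           layer_names=components.layer_names[:d],
                           mask=components.mask)
    niche_sds = species_env.masked_matrix().std(axis=0)
    region_cells = {
        tag: np.nonzero(np.isin(
            partition.labels,
            partition.centroids.index[partition.centroids["region"] == tag]))
        for tag in (SMALL_REGION, LARGE_REGION)}

    county_summary = pd.DataFrame({
        "offset_metric": climate_mod.county_climate_offset(
            components, pca, partition),
        "variance_metric": climate_mod.county_climate_variance(
            components, pca, partition),
        "sd_annual_temp": climate_mod.within_county_sd(
            env.layer("BIO1"), partition),
        "sd_annual_precip": climate_mod.within_county_sd(
            env.layer("BIO12"), partition),
        "area": partition.areas(),
        "region": partition.centroids["region"],
    })

    per_species_rows, meta_rows, excluded = [], [], []
    for i, entry in enumerate(_expand_plan(config.species_plan)):
        sp_id = f"sp{i:03d}_{entry.region}_n{entry.n_target}"
        region_tag = _REGION_TAGS[entry.region]
        rng = np.random.default_rng(child_seed(config.master_seed, "species", i))
        rows, cols = region_cells[region_tag]
        # the study models only species with enough records: draw niche
        # centers until the species occupies at least min_records counties
        # (or give up after a fixed number of candidates)
        occ = None
        for attempt in range(20):
            home = rng.integers(len(rows))
            center = species_env.values_at(np.array([rows[home]]),
                                           np.array([cols[home]]))[0]
            species = VirtualSpecies(species_id=sp_id, niche_center=center,
                                     niche_width=entry.width_mult * niche_sds,
                                     seed=int(rng.integers(2**31)))
            occ = _sample_species_records(
                species, species_env, partition, region_tag, entry.n_target,
                config.min_records,
                seed=child_seed(config.master_seed, "occurrences",
                                i * 32 + attempt))
            if occ is not None:
                break
        if occ is None:
            excluded.append((sp_id, "too few occupiable counties"))
            continue
        occ = treatments.filter_records(occ, partition, config.min_records)
        if occ.empty:
            excluded.append((sp_id, "below min_records after filtering"))
            continue

        ts_all = treatments.build_all_treatments(
            occ, partition, components, config.mix_fraction,
            seed=child_seed(config.master_seed, "mixing", i))

        presence_scores, background_scores = {}, {}
        logistic_grids, raw_grids = {}, {}
        failed = None
        for name, ts in ts_all.items():
            model = MaxentModel(beta_multiplier=config.beta_multiplier,
                                n_knots=config.n_knots,
                                max_iter=config.max_iter)
            X = np.vstack([ts.X, background.X])
            y = np.r_[np.ones(ts.n), np.zeros(background.n)]
            model.fit(X, y)
            if not model.converged_:
                failed = name
                break
            presence_scores[name] = model.predict_logistic(ts.X)
            background_scores[name] = model.predict_logistic(background.X)
            logistic_grids[name] = model.predict_logistic_grid(components)
            raw_grids[name] = model.predict_raw_grid(components)
        if failed is not None:
            excluded.append((sp_id, f"non-converged fit ({failed})"))
            continue

        comp_res = comparison.SpeciesComparison.build(
            sp_id, len(occ), presence_scores, background_scores,
            logistic_grids, raw_grids, components.mask)
        per_species_rows.append(comp_res.table)
        meta_rows.append({"species_id": sp_id, "region": entry.region,
                          "n_target": entry.n_target,
                          "n_records": len(occ),
                          "width_mult": entry.width_mult})

    if not per_species_rows:
        raise RuntimeError("no species survived filtering; enlarge the plan")
    per_species = pd.concat(per_species_rows, ignore_index=True)
    species_meta = pd.DataFrame(meta_rows)
    per_species = per_species.merge(species_meta[["species_id", "region"]],
                                    on="species_id")

    report = ExperimentReport(
        per_species=per_species,
        table_area_ratios=_area_ratio_table(per_species),
        table_overlap=_overlap_table(per_species),
        auc_summary=_auc_summary(per_species),
        paired_tests=_paired_tests(per_species),
        sample_size_effect=_sample_size_effect(per_species),
        east_west=_east_west_contrast(per_species, species_meta,
                                      config.master_seed),
        county_summary=county_summary,
        excluded=excluded,
        n_components=components.n_layers,
        species_meta=species_meta,
    )
    if config.out_dir:
        save_report(report, config, spec, partition, pca, components,
                    normalizer, elapsed=time.time() - t0)
    return report


# ---------------------------------------------------------------------------
# Aggregation (treatment-level analogs of the study's summary tables)


def _pivot(df: pd.DataFrame, value: str, aggs: tuple[str, ...]) -> pd.DataFrame:
    return df.groupby("treatment")[value].agg(list(aggs)).reindex(
        treatments.TREATMENTS)


def _area_ratio_table(per_species: pd.DataFrame) -> pd.DataFrame:
    """Mean/median predicted-area ratio (percent) per treatment and threshold."""
    out = {}
    for thr in ("mtp", "ses"):
        grp = per_species.groupby("treatment")[f"area_ratio_{thr}"]
        out[f"mean_pct_{thr}"] = grp.mean() * 100.0
        out[f"median_pct_{thr}"] = grp.median() * 100.0
    return pd.DataFrame(out).reindex(treatments.TREATMENTS)


def _overlap_table(per_species: pd.DataFrame) -> pd.DataFrame:
    """Mean I, D, RR versus the true-locality model per treatment."""
    rows = per_species[per_species["treatment"] != "true_locality"]
    return rows.groupby("treatment")[["I", "D", "RR"]].mean().reindex(
        [t for t in treatments.TREATMENTS if t != "true_locality"])


def _auc_summary(per_species: pd.DataFrame) -> pd.DataFrame:
    grp = per_species.groupby("treatment")["auc"]
    return pd.DataFrame({"median": grp.median(), "mean": grp.mean(),
                         "min": grp.min(), "max": grp.max()}
                        ).reindex(treatments.TREATMENTS)


def _paired(per_species, treatment_a, treatment_b, metric):
    wide = per_species.pivot(index="species_id", columns="treatment",
                             values=metric)
    stat, p = comparison.wilcoxon_signed_rank(wide[treatment_a],
                                              wide[treatment_b])
    return {"metric": metric, "treatment_a": treatment_a,
            "treatment_b": treatment_b, "statistic": stat, "p_value": p,
            "mean_diff": float((wide[treatment_a] - wide[treatment_b]).mean())}


def _paired_tests(per_species: pd.DataFrame) -> pd.DataFrame:
    pairs = [("true_locality", "county_centroid", "auc")]
    pairs += [("county_average", "county_centroid", m) for m in ("I", "D", "RR")]
    pairs += [("mix_centroid", "county_centroid", m) for m in ("I", "D", "RR")]
    return pd.DataFrame([_paired(per_species, a, b, m) for a, b, m in pairs])


def _sample_size_effect(per_species: pd.DataFrame) -> pd.DataFrame:
    """Record count versus |area-ratio - 1| for the county-centroid models
    at the minimum-training-presence threshold (scatter-table analog)."""
    rows = per_species[per_species["treatment"] == "county_centroid"]
    return rows[["species_id", "n_records", "area_ratio_mtp"]].assign(
        abs_discrepancy=lambda d: (d["area_ratio_mtp"] - 1.0).abs()
    ).reset_index(drop=True)


def spearman_sample_size_effect(report: ExperimentReport) -> tuple[float, float]:
    """Spearman correlation between n and |area ratio - 1| (centroid, MTP)."""
    tab = report.sample_size_effect
    rho, p = stats.spearmanr(tab["n_records"], tab["abs_discrepancy"])
    return float(rho), float(p)


def _east_west_contrast(per_species: pd.DataFrame, species_meta: pd.DataFrame,
                        master_seed: int) -> pd.DataFrame:
    """Median percent area change (centroid vs true, MTP threshold) in the
    small-county versus large-county region under matched sample sizes."""
    cent = per_species[per_species["treatment"] == "county_centroid"]
    east = cent[cent["region"] == "small"].set_index("species_id")
    west = cent[cent["region"] == "large"].set_index("species_id")
    if east.empty or west.empty:
        return pd.DataFrame()
    east_ids, west_ids = treatments.match_sample_sizes(
        east["n_records"], west["n_records"],
        seed=child_seed(master_seed, "matching"))
    rows = []
    for region, ids, sub in (("small", east_ids, east), ("large", west_ids, west)):
        pct = sub.loc[ids, "area_ratio_mtp"] * 100.0 - 100.0
        rows.append({"region": region, "n_species": len(ids),
                     "median_n_records": float(sub.loc[ids, "n_records"].median()),
                     "median_pct_change": float(pct.median()),
                     "median_abs_pct_change": float(pct.abs().median()),
                     "mean_pct_change": float(pct.mean())})
    u, p = stats.mannwhitneyu(
        east.loc[east_ids, "area_ratio_mtp"].sub(1).abs(),
        west.loc[west_ids, "area_ratio_mtp"].sub(1).abs(),
        alternative="two-sided")
    out = pd.DataFrame(rows)
    out["mannwhitney_p"] = p
    return out


# ---------------------------------------------------------------------------
# Persistence


def save_report(report: ExperimentReport, config: ExperimentConfig,
                spec=None, partition=None, pca=None, components=None,
                normalizer=None, elapsed: float | None = None) -> None:
    """Write all result tables (and optional rasters) under config.out_dir."""
    out = Path(config.out_dir)
    (out / "results").mkdir(parents=True, exist_ok=True)
    tables = {
        "per_species.csv": report.per_species,
        "table_area_ratios.csv": report.table_area_ratios,
        "table_overlap.csv": report.table_overlap,
        "auc_summary.csv": report.auc_summary,
        "paired_tests.csv": report.paired_tests,
        "sample_size_effect.csv": report.sample_size_effect,
        "east_west.csv": report.east_west,
        "county_summary.csv": report.county_summary,
        "species_meta.csv": report.species_meta,
    }
    for name, df in tables.items():
        df.to_csv(out / "results" / name)
    meta = {"excluded": report.excluded,
            "n_components": report.n_components,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(config).items()}}
    if elapsed is not None:
        meta["elapsed_seconds"] = round(elapsed, 2)
    (out / "results" / "run_meta.json").write_text(json.dumps(meta, indent=1))
    if config.save_rasters and partition is not None:
        (out / "rasters").mkdir(exist_ok=True)
        write_ascii_grid(out / "rasters" / "counties.asc",
                         partition.labels.astype(float), spec, fmt="%d")
        partition.centroids.to_csv(out / "rasters" / "county_centroids.csv")
        for i, name in enumerate(components.layer_names):
            write_ascii_grid(out / "rasters" / f"{name}.asc",
                             components.layers[i], spec, components.mask)
        pca.to_json(out / "rasters" / "pca_model.json")


def summarize(report: ExperimentReport) -> str:
    """Human-readable digest of the main tables."""
    lines = ["Predicted-area ratios vs true-locality models (percent):",
             report.table_area_ratios.round(1).to_string(),
             "", "Mean niche-overlap metrics vs true-locality models:",
             report.table_overlap.round(4).to_string(),
             "", "AUC summary:", report.auc_summary.round(4).to_string(),
             "", "Paired Wilcoxon signed-rank tests:",
             report.paired_tests.round(5).to_string(index=False)]
    if not report.east_west.empty:
        lines += ["", "Region contrast (matched n, centroid vs true, "
                  "minimum-training-presence threshold):",
                  report.east_west.round(3).to_string(index=False)]
    rho, p = spearman_sample_size_effect(report)
    lines += ["", f"Sample-size effect: Spearman rho(n, |ratio-1|) = "
              f"{rho:.3f} (p = {p:.4g}, n = {len(report.sample_size_effect)})"]
    if report.excluded:
        lines += ["", f"Excluded species: {report.excluded}"]
    return "\n".join(lines)
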