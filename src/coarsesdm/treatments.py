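"""Record filtering and the five training-data treatments.

The filters emulate the vetting applied to citizen-science county records:
drop records whose coordinates disagree with their claimed county, drop
duplicate (species, cell) entries, keep only the first record per
(species, county) so that sample sizes match the county-centroid sister
dataset, and retain only species with at least ``min_records`` records.

The five treatments per species:

``true_locality``
    covariates read at each record's cell (the reference).
``county_centroid``
    coordinates replaced by the record's county centroid; covariates read
    at the centroid cell.
``county_average``
    covariates replaced by the per-county mean of each component layer
    (the record is no longer tied to any cell).
``mix_centroid`` / ``mix_average``
    a random half of the records converted as above, the same selection in
    both, the rest kept as true localities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import EnvStack
from .simulate import CountyPartition

TREATMENTS = ["true_locality", "county_centroid", "county_average",
              "mix_centroid", "mix_average"]


@dataclass
class TrainingSet:
    """Per-record covariate vectors for one species under one treatment."""

    species_id: str
    treatment: str
    X: np.ndarray                  # (n, k) covariates
    county_ids: np.ndarray         # (n,)
    xy: np.ndarray                 # (n, 2); NaN where no point applies
    converted: np.ndarray = field(default=None)  # (n,) bool
    seed: int | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, float))
        n = self.X.shape[0]
        if self.converted is None:
            self.converted = np.zeros(n, dtype=bool)
        for name in ("county_ids", "xy", "converted"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match X")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"z{i+1}" for i in range(self.X.shape[1])])
        df.insert(0, "species_id", self.species_id)
        df.insert(1, "treatment", self.treatment)
        df["x"], df["y"] = self.xy[:, 0], self.xy[:, 1]
        df["county_id"] = self.county_ids
        df["converted"] = self.converted
        return df


# ---------------------------------------------------------------------------
# Filtering


def filter_records(raw: pd.DataFrame, partition: CountyPartition,
                   min_records: int = 10) -> pd.DataFrame:
    """Apply the record filters in input order.

    Drops records whose cell's county label differs from the claimed
    county_id, exact duplicate (species, cell) pairs, all but the first
    record per (species, county), and species with fewer than
    ``min_records`` records remaining. Idempotent.
    """
    if raw.empty:
        return raw.copy()
    df = raw.reset_index(drop=True)
    row, col = partition.spec.cell_of(df["x"].to_numpy(), df["y"].to_numpy())
    actual = partition.labels[row, col]
    df = df[actual == df["county_id"].to_numpy()]
    cells = pd.Series(list(zip(row[df.index], col[df.index])), index=df.index)
    df = df[~pd.DataFrame({"s": df["species_id"], "c": cells}).duplicated()]
    df = df[~df.duplicated(subset=["species_id", "county_id"], keep="first")]
    counts = df.groupby("species_id")["county_id"].transform("size")
    df = df[counts >= min_records]
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Treatment constructors


def _cells_of(occ: pd.DataFrame, env: EnvStack):
    return env.spec.cell_of(occ["x"].to_numpy(), occ["y"].to_numpy())


def county_mean_covariates(components: EnvStack,
                           partition: CountyPartition) -> pd.DataFrame:
    """Per-county mean of each component layer over member masked-in cells."""
    valid = components.mask & (partition.labels >= 0)
    labels = partition.labels[valid]
    nmax = labels.max() + 1
    counts = np.bincount(labels, minlength=nmax)
    ids = partition.county_ids
    out = np.empty((len(ids), components.n_layers))
    for k in range(components.n_layers):
        s1 = np.bincount(labels, weights=components.layers[k][valid],
                         minlength=nmax)
        with np.errstate(invalid="ignore"):
            out[:, k] = (s1 / counts)[ids]
    return pd.DataFrame(out, index=pd.Index(ids, name="county_id"),
                        columns=components.layer_names)


def make_true_locality_dataset(occ: pd.DataFrame,
                               components: EnvStack) -> TrainingSet:
    """Treatment (1): covariates at the record cells."""
    rows, cols = _cells_of(occ, components)
    if np.any(~components.mask[rows, cols]):
        raise ValueError("record outside the study mask")
    return TrainingSet(
        species_id=_single_species(occ), treatment="true_locality",
        X=components.values_at(rows, cols),
        county_ids=occ["county_id"].to_numpy(),
        xy=occ[["x", "y"]].to_numpy(float))


def make_centroid_dataset(occ: pd.DataFrame, partition: CountyPartition,
                          components: EnvStack) -> TrainingSet:
    """Treatment (2): coordinates moved to the county centroid."""
    cents = partition.centroids.loc[occ["county_id"].to_numpy(), ["x", "y"]]
    xy = cents.to_numpy(float)
    rows, cols = components.spec.cell_of(xy[:, 0], xy[:, 1])
    return TrainingSet(
        species_id=_single_species(occ), treatment="county_centroid",
        X=components.values_at(rows, cols),
        county_ids=occ["county_id"].to_numpy(), xy=xy,
        converted=np.ones(len(occ), dtype=bool))


def make_county_average_dataset(occ: pd.DataFrame, partition: CountyPartition,
                                components: EnvStack) -> TrainingSet:
    """Treatment (3): covariates = per-county component means."""
    means = county_mean_covariates(components, partition)
    return TrainingSet(
        species_id=_single_species(occ), treatment="county_average",
        X=means.loc[occ["county_id"].to_numpy()].to_numpy(),
        county_ids=occ["county_id"].to_numpy(),
        xy=occ[["x", "y"]].to_numpy(float),
        converted=np.ones(len(occ), dtype=bool))


def make_mixed_datasets(occ: pd.DataFrame, partition: CountyPartition,
                        components: EnvStack, fraction: float = 0.5,
                        seed: int = 0) -> tuple[TrainingSet, TrainingSet]:
    """Treatments (4) and (5): floor(fraction*n) records converted to
    county-scale data, the identical selection in both outputs."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    n = len(occ)
    if n < 2:
        raise ValueError("need at least 2 records to mix")
    rng = np.random.default_rng(seed)
    n_convert = int(np.floor(fraction * n))
    convert = np.zeros(n, dtype=bool)
    convert[rng.choice(n, size=n_convert, replace=False)] = True

    true_ts = make_true_locality_dataset(occ, components)
    cent_ts = make_centroid_dataset(occ, partition, components)
    avg_ts = make_county_average_dataset(occ, partition, components)

    def mixed(base: TrainingSet, name: str) -> TrainingSet:
        X = np.where(convert[:, None], base.X, true_ts.X)
        xy = np.where(convert[:, None], base.xy, true_ts.xy)
        return TrainingSet(species_id=true_ts.species_id, treatment=name,
                           X=X, county_ids=true_ts.county_ids, xy=xy,
                           converted=convert.copy(), seed=seed)

    return mixed(cent_ts, "mix_centroid"), mixed(avg_ts, "mix_average")


def build_all_treatments(occ: pd.DataFrame, partition: CountyPartition,
                         components: EnvStack, fraction: float = 0.5,
                         seed: int = 0) -> dict[str, TrainingSet]:
    """All five treatments for one species' filtered records."""
    mix_c, mix_a = make_mixed_datasets(occ, partition, components, fraction, seed)
    return {
        "true_locality": make_true_locality_dataset(occ, components),
        "county_centroid": make_centroid_dataset(occ, partition, components),
        "county_average": make_county_average_dataset(occ, partition, components),
        "mix_centroid": mix_c,
        "mix_average": mix_a,
    }


def _single_species(occ: pd.DataFrame) -> str:
    species = occ["species_id"].unique()
    if len(species) != 1:
        raise ValueError("expected records of exactly one species")
    return str(species[0])


# ---------------------------------------------------------------------------
# East/west subsetting and sample-size matching


def split_east_west(occ: pd.DataFrame, split_x: float
                    ) -> tuple[list[str], list[str]]:
    """Species with every record strictly east (x > split_x) or strictly
    west (x < split_x); straddling species excluded from both lists."""
    east, west = [], []
    for sp, grp in occ.groupby("species_id", sort=True):
        x = grp["x"].to_numpy()
        if np.all(x > split_x):
            east.append(sp)
        elif np.all(x < split_x):
            west.append(sp)
    return east, west


def match_sample_sizes(east: pd.Series, west: pd.Series, seed: int = 0,
                       median_tol: float = 2.0
                       ) -> tuple[list[str], list[str]]:
    """Select species subsets with comparable record-count distributions.

    ``east`` and ``west`` map species id to record count. The side with
    the larger median is first restricted to counts within the other
    side's [min, max]; then species are removed at random (seeded) from
    whichever side has the larger median — always a species whose count
    exceeds the opposing median, so removal can only help — until the
    medians differ by at most ``median_tol`` or no further removal helps.
    """
    if east.empty or west.empty:
        raise ValueError("both sides must contain at least one species")
    rng = np.random.default_rng(seed)
    sides = {"east": east.copy(), "west": west.copy()}

    big, small = (("east", "west") if east.median() >= west.median()
                  else ("west", "east"))
    lo, hi = sides[small].min(), sides[small].max()
    trimmed = sides[big][(sides[big] >= lo) & (sides[big] <= hi)]
    if not trimmed.empty:
        sides[big] = trimmed

    while True:
        med = {k: v.median() for k, v in sides.items()}
        if abs(med["east"] - med["west"]) <= median_tol:
            break
        high = "east" if med["east"] > med["west"] else "west"
        low = "west" if high == "east" else "east"
        cand = sides[high][sides[high] > med[low]]
        if cand.empty or len(sides[high]) <= 1:
            break
        drop = rng.choice(np.sort(cand.index.to_numpy()))
        sides[high] = sides[high].drop(drop)
    return sorted(sides["east"].index), sorted(sides["west"].index)
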