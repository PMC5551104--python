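"""Synthetic landscapes: climate surfaces, county tessellations, virtual species.

The generators build a self-contained world with the statistical structure a
county-resolution bias experiment needs: spatially autocorrelated monthly
climate with regional gradients, a county map with one region of many small
counties and one region of few large ones, virtual species with unimodal
(product-Gaussian) suitability in environmental space, and occurrence
records sampled proportionally to suitability.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import EnvStack, GridSpec

OCCURRENCE_COLUMNS = ["species_id", "x", "y", "county_id", "source_tag"]

SMALL_REGION = "small-county region"
LARGE_REGION = "large-county region"


# ---------------------------------------------------------------------------
# Gaussian random fields


def sample_gaussian_field(spec: GridSpec, autocorr_length: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Draw a zero-mean, unit-variance Gaussian field with exponential
    covariance ``exp(-d / autocorr_length)`` on the grid.

    Uses circulant embedding on a doubled torus: the covariance of the
    padded lattice is diagonalized by the 2-D FFT, so an exact sample is an
    inverse FFT of spectrally weighted white noise. Negative embedding
    eigenvalues (small for the exponential kernel with 2x padding) are
    clamped to zero.
    """
    if autocorr_length <= 0:
        raise ValueError("autocorr_length must be positive")
    P, Q = 2 * spec.n_rows, 2 * spec.n_cols
    di = np.minimum(np.arange(P), P - np.arange(P))[:, None]
    dj = np.minimum(np.arange(Q), Q - np.arange(Q))[None, :]
    dist = np.hypot(di, dj) * spec.cell_size
    lam = np.fft.fft2(np.exp(-dist / autocorr_length)).real
    np.clip(lam, 0.0, None, out=lam)
    eps = rng.standard_normal((P, Q)) + 1j * rng.standard_normal((P, Q))
    field = np.fft.ifft2(np.sqrt(lam) * eps) * np.sqrt(P * Q)
    return np.ascontiguousarray(field.real[: spec.n_rows, : spec.n_cols])


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


# ---------------------------------------------------------------------------
# Monthly climate


@dataclass
class MonthlyClimate:
    """Twelve months of maximum/minimum temperature (degC) and precipitation (mm)."""

    spec: GridSpec
    tmax: np.ndarray  # (12, n_rows, n_cols)
    tmin: np.ndarray
    precip: np.ndarray

    def __post_init__(self) -> None:
        for name in ("tmax", "tmin", "precip"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12, *self.spec.shape):
                raise ValueError(f"{name} must have shape (12, n_rows, n_cols)")
            setattr(self, name, arr)
        if np.any(self.tmax < self.tmin):
            raise ValueError("tmax < tmin at some cell/month")
        if np.any(self.precip < 0):
            raise ValueError("negative precipitation")


def generate_monthly_climate(spec: GridSpec, gradient_strength: float = 10.0,
                             autocorr_length: float = 12.0,
                             seasonal_amplitude: float = 12.0,
                             seed: int = 0, *,
                             noise_sd_temp: float = 2.0,
                             noise_sd_precip: float = 0.8,
                             precip_scale: float = 60.0) -> MonthlyClimate:
    """Generate 36 synthetic monthly climate layers.

    Each monthly mean-temperature layer is a large-scale linear gradient
    (``gradient_strength`` degC across the domain, cooling with y), a
    seasonal sinusoid (amplitude ``seasonal_amplitude`` degC, coldest in
    month 1), and a spatially autocorrelated Gaussian field with exponential
    correlation length ``autocorr_length``. Monthly fields share a common
    annual anomaly field (correlation 0.8 between months). The diurnal
    range is 1 degC plus a positive autocorrelated field, so
    ``tmax - tmin >= 1`` everywhere by construction. Precipitation is a
    softplus map of gradient + seasonal + noise, hence nonnegative while
    preserving the autocorrelation structure near zero; its seasonal phase
    rotates with x so different parts of the domain have wet summers versus
    wet winters.
    """
    if spec.n_rows < 4 or spec.n_cols < 4:
        raise ValueError("grid too small: need at least 4 cells per axis")
    if autocorr_length <= 0:
        raise ValueError("autocorr_length must be positive")
    rng = np.random.default_rng(seed)
    x, y = spec.cell_centers()
    x_norm = (x - x.min()) / max(x.max() - x.min(), 1e-12)
    y_norm = (y - y.min()) / max(y.max() - y.min(), 1e-12)

    months = np.arange(12)
    season_t = -np.cos(2 * np.pi * months / 12.0)  # -1 in Jan, +1 in Jul

    annual_t = sample_gaussian_field(spec, autocorr_length, rng)
    rho = 0.8
    tmax = np.empty((12, *spec.shape))
    tmin = np.empty((12, *spec.shape))
    precip = np.empty((12, *spec.shape))

    diurnal = 1.0 + _softplus(
        1.5 + 0.25 * noise_sd_temp * sample_gaussian_field(spec, autocorr_length, rng))

    annual_p = sample_gaussian_field(spec, autocorr_length, rng)
    for m in range(12):
        monthly_t = sample_gaussian_field(spec, autocorr_length, rng)
        anom_t = noise_sd_temp * (rho * annual_t + np.sqrt(1 - rho**2) * monthly_t)
        tmean = (18.0 + gradient_strength * (0.5 - y_norm)
                 + seasonal_amplitude * season_t[m] + anom_t)
        tmax[m] = tmean + diurnal / 2.0
        tmin[m] = tmean - diurnal / 2.0

        monthly_p = sample_gaussian_field(spec, autocorr_length, rng)
        anom_p = noise_sd_precip * (rho * annual_p + np.sqrt(1 - rho**2) * monthly_p)
        seasonal_p = 0.8 * np.cos(2 * np.pi * m / 12.0 - np.pi * x_norm)
        drive = (0.5 + (gradient_strength / 10.0) * (x_norm - 0.5)
                 + seasonal_p + anom_p)
        precip[m] = precip_scale * _softplus(drive)

    return MonthlyClimate(spec=spec, tmax=tmax, tmin=tmin, precip=precip)


# ---------------------------------------------------------------------------
# County tessellation


@dataclass
class CountyPartition:
    """Assignment of every valid grid cell to exactly one county.

    ``labels`` holds a county id per cell (-1 outside the study mask);
    ``centroids`` is a DataFrame indexed by county id with columns
    ``x, y, region``, where the centroid is the arithmetic mean of member
    cell centers snapped to the nearest member cell center if the mean
    falls outside the county.
    """

    spec: GridSpec
    labels: np.ndarray  # int grid, -1 = outside mask
    centroids: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != self.spec.shape:
            raise ValueError("labels shape does not match GridSpec")
        present = np.unique(self.labels[self.labels >= 0])
        if not np.array_equal(np.sort(self.centroids.index.to_numpy()), present):
            raise ValueError("centroid table does not match label raster")

    @property
    def mask(self) -> np.ndarray:
        return self.labels >= 0

    @property
    def county_ids(self) -> np.ndarray:
        return self.centroids.index.to_numpy()

    def county_of(self, x, y) -> np.ndarray:
        row, col = self.spec.cell_of(x, y)
        return self.labels[row, col]

    def centroid_cells(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of each county centroid, aligned with ``county_ids``."""
        return self.spec.cell_of(self.centroids["x"].to_numpy(),
                                 self.centroids["y"].to_numpy())

    def cells_of(self, county_id: int) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.labels == county_id)

    def areas(self) -> pd.Series:
        """Cell counts per county id."""
        lab = self.labels[self.labels >= 0]
        return pd.Series(np.bincount(lab, minlength=self.county_ids.max() + 1)
                         )[self.county_ids].rename("area")


def generate_counties(spec: GridSpec, split_x: float,
                      mean_area_small: float = 16.0,
                      mean_area_large: float = 240.0,
                      seed: int = 0,
                      mask: np.ndarray | None = None) -> CountyPartition:
    """Tessellate the grid into counties via seeded Voronoi cells.

    Cells with center x < ``split_x`` form the large-county region, the
    rest the small-county region; Voronoi seeds are placed uniformly at
    random within each region with density 1/mean_area, and every cell is
    assigned to its globally nearest seed (ties to the lowest seed index).
    """
    if not mean_area_large > mean_area_small >= 4:
        raise ValueError("require mean_area_large > mean_area_small >= 4")
    rng = np.random.default_rng(seed)
    if mask is None:
        mask = np.ones(spec.shape, dtype=bool)
    x, y = spec.cell_centers()
    west = (x < split_x) & mask
    east = (~(x < split_x)) & mask

    seed_rows, seed_cols, seed_regions = [], [], []
    region_specs = [(west, mean_area_large, LARGE_REGION),
                    (east, mean_area_small, SMALL_REGION)]
    occupied = [np.count_nonzero(r[0]) for r in region_specs]
    n_nonempty = sum(1 for c in occupied if c > 0)
    for (region_mask, mean_area, tag), n_cells in zip(region_specs, occupied):
        if n_cells == 0:
            continue
        n_seeds = max(1, int(round(n_cells / mean_area)))
        if n_nonempty > 1 and n_seeds < 2:
            raise ValueError(
                f"{tag} too small to host at least 2 counties "
                f"({n_cells} cells, mean area {mean_area})")
        rows, cols = np.nonzero(region_mask)
        pick = rng.choice(len(rows), size=min(n_seeds, len(rows)), replace=False)
        seed_rows.extend(rows[pick])
        seed_cols.extend(cols[pick])
        seed_regions.extend([tag] * len(pick))

    sx, sy = spec.center_of(np.array(seed_rows), np.array(seed_cols))
    labels = np.full(spec.shape, -1, dtype=int)
    mrows, mcols = np.nonzero(mask)
    mx, my = spec.center_of(mrows, mcols)
    # globally nearest seed; argmin breaks ties toward the lowest seed
    # index; blocked to bound memory on large grids
    nearest = np.empty(len(mrows), dtype=int)
    block = max(1, 4_000_000 // max(len(sx), 1))
    for start in range(0, len(mrows), block):
        end = start + block
        d2 = ((mx[start:end, None] - sx[None, :]) ** 2
              + (my[start:end, None] - sy[None, :]) ** 2)
        nearest[start:end] = np.argmin(d2, axis=1)
    labels[mrows, mcols] = nearest

    records = []
    for cid in np.unique(labels[labels >= 0]):
        rows, cols = np.nonzero(labels == cid)
        cx, cy = spec.center_of(rows, cols)
        gx, gy = cx.mean(), cy.mean()
        r, c = spec.cell_of(gx, gy)
        if labels[r, c] != cid:  # concave county: snap to nearest member cell
            k = np.argmin((cx - gx) ** 2 + (cy - gy) ** 2)
            gx, gy = cx[k], cy[k]
        records.append((cid, gx, gy, seed_regions[cid]))
    centroids = pd.DataFrame(records, columns=["county_id", "x", "y", "region"]
                             ).set_index("county_id")
    return CountyPartition(spec=spec, labels=labels, centroids=centroids)


# ---------------------------------------------------------------------------
# Virtual species


@dataclass(frozen=True)
class VirtualSpecies:
    """A species with known product-Gaussian suitability in covariate space."""

    species_id: str
    niche_center: np.ndarray
    niche_width: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "niche_center",
                           np.atleast_1d(np.asarray(self.niche_center, float)))
        object.__setattr__(self, "niche_width",
                           np.atleast_1d(np.asarray(self.niche_width, float)))
        if self.niche_center.shape != self.niche_width.shape:
            raise ValueError("niche_center and niche_width must align")
        if np.any(self.niche_width <= 0):
            raise ValueError("niche_width must be positive on every axis")


def true_suitability(species: VirtualSpecies, env: EnvStack) -> np.ndarray:
    """Product-Gaussian suitability in [0, 1] over the environmental stack.

    suitability(cell) = prod_k exp(-(z_k - c_k)^2 / (2 w_k^2)); cells
    outside the mask get 0.
    """
    if env.n_layers != species.niche_center.size:
        raise ValueError(
            f"env has {env.n_layers} layers but niche is "
            f"{species.niche_center.size}-dimensional")
    z = env.layers  # (k, R, C)
    c = species.niche_center[:, None, None]
    w = species.niche_width[:, None, None]
    log_s = -0.5 * np.sum(((z - c) / w) ** 2, axis=0)
    s = np.exp(log_s)
    s[~env.mask] = 0.0
    return s


def sample_occurrences(species: VirtualSpecies, env: EnvStack,
                       partition: CountyPartition, n: int, seed: int,
                       region: str | None = None) -> pd.DataFrame:
    """Sample ``n`` distinct occurrence cells with probability proportional
    to true suitability; records carry the cell's true county id.

    ``region`` optionally confines the sampling support to one county
    region (used to build strictly-eastern / strictly-western species).
    Returns a DataFrame with columns species_id, x, y, county_id,
    source_tag ('true').
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    s = true_suitability(species, env)
    support = env.mask & (s > 0) & (partition.labels >= 0)
    if region is not None:
        in_region = np.isin(
            partition.labels,
            partition.centroids.index[partition.centroids["region"] == region])
        support &= in_region
    rows, cols = np.nonzero(support)
    if len(rows) < n:
        raise ValueError(
            f"only {len(rows)} cells with positive suitability; need {n}")
    weights = s[rows, cols]
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(rows), size=n, replace=False, p=weights / weights.sum())
    rows, cols = rows[pick], cols[pick]
    x, y = env.spec.center_of(rows, cols)
    return pd.DataFrame({
        "species_id": species.species_id,
        "x": x, "y": y,
        "county_id": partition.labels[rows, cols],
        "source_tag": "true",
    })
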