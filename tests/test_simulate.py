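import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

from coarsesdm import (GridSpec, VirtualSpecies, generate_counties,
                       generate_monthly_climate, sample_occurrences,
                       true_suitability)
from coarsesdm.grid import EnvStack
from coarsesdm.simulate import (LARGE_REGION, SMALL_REGION, CountyPartition,
                                sample_gaussian_field)


class TestGaussianField:
    def test_deterministic_given_seed(self):
        spec = GridSpec(30, 30)
        a = sample_gaussian_field(spec, 5.0, np.random.default_rng(7))
        b = sample_gaussian_field(spec, 5.0, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_variogram_matches_exponential_covariance(self):
        """The empirical semivariogram follows sill*(1 - exp(-h/ell)):
        ~63% of sill at h = ell and ~95% at h = 3*ell."""
        spec = GridSpec(140, 140)
        ell = 8.0
        rng = np.random.default_rng(11)
        gammas = {int(h): [] for h in (ell, 2 * ell, 3 * ell)}
        sills = []
        for _ in range(3):
            z = sample_gaussian_field(spec, ell, rng)
            sills.append(z.var())
            for h in gammas:
                dx = 0.5 * np.mean((z[:, :-h] - z[:, h:]) ** 2)
                dy = 0.5 * np.mean((z[:-h, :] - z[h:, :]) ** 2)
                gammas[h].append((dx + dy) / 2.0)
        sill = np.mean(sills)
        for h, expected in [(8, 1 - np.exp(-1)), (16, 1 - np.exp(-2)),
                            (24, 1 - np.exp(-3))]:
            ratio = np.mean(gammas[h]) / sill
            assert abs(ratio - expected) < 0.12, (h, ratio, expected)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            sample_gaussian_field(GridSpec(10, 10), 0.0, np.random.default_rng(0))


class TestMonthlyClimate:
    def test_same_seed_bit_identical(self):
        spec = GridSpec(12, 12)
        a = generate_monthly_climate(spec, seed=3)
        b = generate_monthly_climate(spec, seed=3)
        assert np.array_equal(a.tmax, b.tmax)
        assert np.array_equal(a.tmin, b.tmin)
        assert np.array_equal(a.precip, b.precip)

    def test_no_gradient_no_noise_gives_flat_tmax(self):
        mc = generate_monthly_climate(GridSpec(10, 10), gradient_strength=0.0,
                                      seed=5, noise_sd_temp=0.0)
        for m in range(12):
            assert np.ptp(mc.tmax[m]) == pytest.approx(0.0, abs=1e-12)

    def test_physical_invariants(self):
        mc = generate_monthly_climate(GridSpec(25, 25), seed=9)
        assert np.all(mc.tmax - mc.tmin >= 1.0)
        assert np.all(mc.precip >= 0)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_monthly_climate(GridSpec(3, 10), seed=0)
        with pytest.raises(ValueError):
            generate_monthly_climate(GridSpec(10, 10), autocorr_length=-1.0, seed=0)


class TestCounties:
    def test_single_region_single_seed(self):
        spec = GridSpec(8, 8)
        part = generate_counties(spec, split_x=-10.0, mean_area_small=64,
                                 mean_area_large=100, seed=1)
        assert len(part.county_ids) == 1
        assert np.all(part.labels == part.county_ids[0])
        # centroid is the grid mean snapped onto a member cell
        r, c = part.centroid_cells()
        assert part.labels[r[0], c[0]] == part.county_ids[0]

    def test_realized_mean_areas_near_requested(self):
        spec = GridSpec(200, 200)
        part = generate_counties(spec, split_x=100.0, mean_area_small=25,
                                 mean_area_large=400, seed=2)
        areas = part.areas()
        regions = part.centroids["region"]
        for tag, want in [(SMALL_REGION, 25), (LARGE_REGION, 400)]:
            got = areas[regions == tag].mean()
            assert abs(got - want) / want < 0.30, (tag, got)

    def test_labels_match_brute_force_nearest_seed(self):
        spec = GridSpec(40, 40)
        part = generate_counties(spec, split_x=20.0, mean_area_small=20,
                                 mean_area_large=100, seed=3)
        sx = part.centroids.index.to_numpy()
        # independent oracle: cdist over all (cell, seed) pairs; seeds are
        # recovered from the label raster by regenerating with same seed is
        # circular, so recompute nearest from the actual seed positions via
        # the stored Voronoi property: every cell's county minimizes the
        # distance to that county's seed cell among all counties.
        rows, cols = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        cx, cy = spec.center_of(rows.ravel(), cols.ravel())
        pts = np.column_stack([cx, cy])
        # seed locations: cells equidistant-minimal are unknown; use the
        # county seed = cell whose label region minimizes max-dist is not
        # recoverable. Instead re-run the generator's own seed draw:
        rng = np.random.default_rng(3)
        x, y = spec.cell_centers()
        west = x < 20.0
        seed_pts = []
        for region_mask, mean_area in [(west, 100), (~west, 20)]:
            n_cells = int(region_mask.sum())
            n_seeds = max(1, int(round(n_cells / mean_area)))
            rr, cc = np.nonzero(region_mask)
            pick = rng.choice(len(rr), size=n_seeds, replace=False)
            px, py = spec.center_of(rr[pick], cc[pick])
            seed_pts.append(np.column_stack([px, py]))
        seed_pts = np.vstack(seed_pts)
        oracle = np.argmin(cdist(pts, seed_pts), axis=1)
        assert np.array_equal(part.labels.ravel(), oracle)

    def test_partition_completeness_and_centroids_inside(self):
        spec = GridSpec(50, 50)
        part = generate_counties(spec, split_x=25.0, mean_area_small=16,
                                 mean_area_large=120, seed=4)
        assert part.areas().sum() == spec.n_cells
        r, c = part.centroid_cells()
        assert np.array_equal(part.labels[r, c], part.county_ids)

    def test_too_small_region_rejected(self):
        with pytest.raises(ValueError):
            generate_counties(GridSpec(10, 10), split_x=5.0,
                              mean_area_small=10, mean_area_large=1000, seed=0)
        with pytest.raises(ValueError):
            generate_counties(GridSpec(10, 10), split_x=5.0,
                              mean_area_small=4, mean_area_large=3, seed=0)


def _env_1layer(values: np.ndarray) -> EnvStack:
    values = np.asarray(values, float)
    spec = GridSpec(*values.shape)
    return EnvStack(spec=spec, layers=values[None], layer_names=["z"])


class TestSuitability:
    def test_closed_form_values(self):
        env = _env_1layer(np.array([[0.0, 1.0, 2.0, 5.0]]))
        vs = VirtualSpecies("s", niche_center=[1.0], niche_width=[1.0])
        s = true_suitability(vs, env)
        assert s[0, 1] == pytest.approx(1.0)
        assert s[0, 0] == pytest.approx(np.exp(-0.5))   # one width away
        assert s[0, 2] == pytest.approx(np.exp(-0.5))

    def test_strictly_decreasing_from_center(self):
        env = _env_1layer(np.linspace(0, 10, 50)[None, :])
        vs = VirtualSpecies("s", [0.0], [2.0])
        s = true_suitability(vs, env)[0]
        assert np.all(np.diff(s) < 0)

    def test_dimension_mismatch_rejected(self):
        env = _env_1layer(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            true_suitability(VirtualSpecies("s", [0, 0], [1, 1]), env)


def _patch_partition(spec: GridSpec) -> CountyPartition:
    import pandas as pd
    labels = np.zeros(spec.shape, dtype=int)
    x, y = spec.center_of(*np.nonzero(labels == 0))
    cents = pd.DataFrame({"county_id": [0], "x": [x.mean()], "y": [y.mean()],
                          "region": [SMALL_REGION]}).set_index("county_id")
    return CountyPartition(spec=spec, labels=labels, centroids=cents)


class TestOccurrenceSampling:
    def test_support_constraint_exact(self):
        vals = np.full((4, 5), 1e6)
        vals[1, :] = 0.0           # only 5 cells have nonzero suitability
        vals[2, :] = 0.0
        env = _env_1layer(vals)
        part = _patch_partition(env.spec)
        vs = VirtualSpecies("s", [0.0], [1.0])
        occ = sample_occurrences(vs, env, part, n=10, seed=1)
        rows, _ = env.spec.cell_of(occ["x"].to_numpy(), occ["y"].to_numpy())
        assert sorted(rows) == [1] * 5 + [2] * 5
        with pytest.raises(ValueError):
            sample_occurrences(vs, env, part, n=11, seed=1)

    def test_deterministic_given_seed(self):
        env = _env_1layer(np.random.default_rng(0).normal(size=(10, 10)))
        part = _patch_partition(env.spec)
        vs = VirtualSpecies("s", [0.0], [1.0])
        a = sample_occurrences(vs, env, part, n=20, seed=9)
        b = sample_occurrences(vs, env, part, n=20, seed=9)
        assert a.equals(b)

    def test_frequencies_proportional_to_suitability(self):
        """2,000 single draws: cell frequencies match the analytic
        suitability-proportional weights (chi-square GOF)."""
        vals = np.full((3, 4), 50.0)
        vals[0, :4] = [0.0, 0.5, 1.0, 1.5]      # 4 cells with usable mass
        env = _env_1layer(vals)
        part = _patch_partition(env.spec)
        vs = VirtualSpecies("s", [0.0], [1.0])
        s = true_suitability(vs, env)
        probs = s[0, :4] / s[0, :4].sum()
        counts = np.zeros(4)
        for i in range(2000):
            occ = sample_occurrences(vs, env, part, n=1, seed=10_000 + i)
            _, col = env.spec.cell_of(occ["x"].iloc[0], occ["y"].iloc[0])
            counts[int(col)] += 1
        assert stats.chisquare(counts, 2000 * probs).pvalue > 0.01

    def test_sampled_cells_are_above_average_suitability(self, landscape,
                                                         species_env):
        sds = species_env.masked_matrix().std(axis=0)
        M = species_env.masked_matrix()
        vs = VirtualSpecies("s", M[1234], 1.0 * sds)
        occ = sample_occurrences(vs, species_env, landscape["partition"],
                                 n=30, seed=5)
        s = true_suitability(vs, species_env)
        rows, cols = species_env.spec.cell_of(occ["x"].to_numpy(),
                                              occ["y"].to_numpy())
        assert s[rows, cols].mean() > s[species_env.mask].mean()
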