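"""Grid-cell and weakly-spatially-modulated input generators."""

import numpy as np
import pytest

from gridplace.environment import Environment, DEFAULT_ENV
from gridplace.fieldstats import spatial_information
from gridplace import spatial_inputs as si


class TestEnvironment:
    def test_default_binning(self, env):
        assert env.n_bins == 3200
        assert env.shape == (40, 80)
        assert env.bin_size_cm == pytest.approx(2.5)
        assert env.bin_area_cm2 == pytest.approx(6.25)

    def test_non_square_bins_rejected(self):
        with pytest.raises(ValueError):
            Environment(width_cm=200, height_cm=100, nx=80, ny=50)

    def test_bin_centers_and_lookup_roundtrip(self, env):
        centers = env.bin_centers()
        assert centers.shape == (3200, 2)
        ix, iy = env.position_to_bin(centers)
        np.testing.assert_array_equal(iy * env.nx + ix, np.arange(3200))
        # right/top walls fold into the last bin
        ix, iy = env.position_to_bin(np.array([200.0, 100.0]))
        assert (ix, iy) == (79, 39)


class TestGridCells:
    def test_field_radius_is_032_of_spacing(self, grid_pop_default):
        np.testing.assert_allclose(
            grid_pop_default.field_sigma_cm, 0.32 * grid_pop_default.spacing_cm
        )
        # printed example: spacing 38.8 cm -> sigma 12.416 cm
        assert 0.32 * 38.8 == pytest.approx(12.416)

    def test_module_composition(self):
        pop = si.sample_grid_population(4000, seed=3)
        frac12 = np.isin(pop.module, [1, 2]).mean()
        assert frac12 == pytest.approx(0.87, abs=0.02)
        for m, mean in zip([1, 2, 3, 4], si.MODULE_SPACING_MEANS_CM):
            sel = pop.module == m
            assert abs(pop.spacing_cm[sel].mean() - mean) < 1.5

    def test_determinism_and_errors(self):
        a = si.sample_grid_population(25, seed=11)
        b = si.sample_grid_population(25, seed=11)
        np.testing.assert_array_equal(a.spacing_cm, b.spacing_cm)
        np.testing.assert_array_equal(a.offset_cm, b.offset_cm)
        np.testing.assert_array_equal(
            si.grid_rate_map(a, 0), si.grid_rate_map(b, 0)
        )
        with pytest.raises(ValueError):
            si.sample_grid_population(0)

    def test_rate_falls_to_fifth_of_peak_at_field_border(self, env):
        # one cell whose lattice is aligned so that field-center distances to
        # probe bins are exact: spacing chosen so sigma = 15 cm = 6 bins
        pop = si.single_spacing_population(1, 46.875, orientation_sd_deg=0, seed=0)
        pop.offset_cm[0] = np.array([101.25, 51.25])  # a bin center
        rates = si.grid_rate_map(pop, 0, env)
        iy, ix = 20, 40  # bin whose center is (101.25, 51.25)
        peak = rates[iy, ix]
        at_sigma = rates[iy, ix + 6]       # 15 cm away, d = sigma
        at_half_sigma = rates[iy, ix + 3]  # 7.5 cm away, d = sigma / 2
        assert at_sigma / peak == pytest.approx(1 / 5, rel=1e-9)
        assert at_half_sigma / peak == pytest.approx(5 ** (-0.25), rel=1e-9)

    def test_rate_map_matches_brute_force_nearest_center(self, env):
        pop = si.sample_grid_population(3, seed=5)
        for i in range(3):
            rates = si.grid_rate_map(pop, i, env)
            centers = si.hex_field_centers(
                pop.spacing_cm[i], pop.orientation_deg[i], pop.offset_cm[i], env
            )
            rng = np.random.default_rng(int(pop.amp_seed[i]))
            amps = np.clip(rng.normal(1.0, 0.1, len(centers)), 0, None)
            bc = env.bin_centers()
            d = np.linalg.norm(bc[:, None, :] - centers[None, :, :], axis=2)
            nearest = d.argmin(axis=1)
            expected = amps[nearest] * np.exp(
                -np.log(5.0) * (d.min(axis=1) / pop.field_sigma_cm[i]) ** 2
            )
            np.testing.assert_allclose(rates.ravel(), expected, rtol=1e-12)

    def test_autocorrelogram_peak_at_one_spacing(self, env):
        pop = si.single_spacing_population(1, 40.0, orientation_mean_deg=0,
                                           orientation_sd_deg=0, seed=2)
        rates = si.grid_rate_map(pop, 0, env)
        ac = si.spatial_autocorrelogram(rates)
        cy, cx = env.ny - 1, env.nx - 1
        b = env.bin_size_cm
        # along the first lattice vector (orientation 0): offset = spacing
        at_spacing = ac[cy, cx + int(round(40.0 / b))]
        trough = ac[cy, cx + int(round(20.0 / b))]
        assert at_spacing > 0.4
        assert trough < at_spacing - 0.4


class TestWSM:
    def test_normalized_to_unit_interval(self):
        m = si.wsm_rate_map(6.0, seed=4)
        assert m.min() == 0.0 and m.max() == 1.0
        with pytest.raises(ValueError):
            si.wsm_rate_map(0.0)

    def test_spatial_information_decreases_with_smoothing(self):
        """Salt-and-pepper maps carry far more spatial information than the
        default 6-cm maps; info falls monotonically over the 1-4 cm range.

        (Because maps are renormalized to [0, 1], the information is not
        monotone over the full 1-16 cm range: very wide kernels produce
        large coherent high/low regions and the median rises again.)
        """
        rng = np.random.default_rng(0)
        med = {}
        for sn in (1.0, 2.0, 4.0, 6.0):
            med[sn] = np.median(
                [spatial_information(si.wsm_rate_map(sn, rng=rng)) for _ in range(80)]
            )
        assert med[1.0] > med[2.0] > med[4.0]
        assert med[6.0] < 0.5 * med[1.0]


class TestPVCorrelation:
    def test_zero_distance_is_unity(self, grid_maps_default):
        pv = si.pv_distance_correlation(grid_maps_default, max_dist_cm=30)
        assert pv.mean_corr[0] == pytest.approx(1.0)

    def test_grid_population_orthogonal_then_repeating(self, grid_maps_default):
        """Grid-only PVs decorrelate at 20-28 cm and re-correlate near the
        typical spacing (~45 cm) -- the structure that blocks large fields."""
        pv = si.pv_distance_correlation(grid_maps_default, max_dist_cm=80)
        d = pv.distance_cm
        near_orth = pv.mean_corr[(d >= 20) & (d <= 28)].mean()
        secondary = pv.mean_corr[(d >= 38) & (d <= 52)].max()
        assert abs(near_orth) < 0.25
        assert secondary > 0.0
        assert secondary > near_orth + 0.1

    def test_wsm_fraction_removes_secondary_peak(self, grid_pop_default,
                                                 grid_maps_default):
        """Mixing in WSM cells monotonically suppresses the secondary PV
        correlation peak at grid-spacing distances."""
        gmaps = grid_maps_default[:60]
        rng_seed = 42
        prominences = []
        for n_wsm in (0, 60, 240):
            maps = gmaps
            if n_wsm:
                maps = np.concatenate(
                    [gmaps, si.wsm_population_maps(n_wsm, 6.0, seed=rng_seed)]
                )
            pv = si.pv_distance_correlation(maps, max_dist_cm=60)
            d = pv.distance_cm
            # height of the spacing-distance peak above the 20-30 cm trough
            # (mixtures shift the overall baseline, so prominence is the
            # meaningful measure of the periodic structure)
            prominences.append(
                pv.mean_corr[(d >= 38) & (d <= 52)].max()
                - pv.mean_corr[(d >= 18) & (d <= 32)].min()
            )
        assert prominences[0] > prominences[1] > prominences[2]

    def test_constant_pv_excluded(self, env):
        maps = np.zeros((3, env.ny, env.nx))
        maps[0, 0, 0] = 1.0  # all other locations have constant (0,0,0) PVs
        pv = si.pv_distance_correlation(maps, max_dist_cm=20)
        assert pv.n_excluded_pvs == env.n_bins - 1
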