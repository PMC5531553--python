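"""Place-field detection, spatial information, and the lesion error rate."""

import numpy as np
import pytest

from gridplace.environment import DEFAULT_ENV
from gridplace import fieldstats as fsm


def gaussian_bump(env, cx, cy, sd_cm, peak=1.0):
    bc = env.bin_centers()
    d2 = (bc[:, 0] - cx) ** 2 + (bc[:, 1] - cy) ** 2
    return (peak * np.exp(-d2 / (2 * sd_cm**2))).reshape(env.shape)


class TestDetectFields:
    def test_zero_map_is_inactive(self, env):
        fs = fsm.detect_fields(np.zeros(env.shape), env)
        assert not fs.active and fs.n_fields == 0 and not fs.is_place_cell

    def test_gaussian_bump_area_matches_analytic_contour(self, env):
        """The 20%-of-peak contour of a Gaussian of sd 10 cm is a circle of
        radius 10*sqrt(2 ln 5) ~ 17.9 cm, area ~ 1011 cm^2."""
        m = gaussian_bump(env, 100.0, 50.0, 10.0)
        fs = fsm.detect_fields(m, env)
        assert fs.n_fields == 1
        r_contour = 10.0 * np.sqrt(2 * np.log(5))
        analytic = np.pi * r_contour**2
        # independent oracle: count bin centers inside the analytic contour
        bc = env.bin_centers()
        inside = np.hypot(bc[:, 0] - 100.0, bc[:, 1] - 50.0) <= r_contour
        assert fs.fields[0].area_cm2 == pytest.approx(inside.sum() * env.bin_area_cm2)
        assert abs(fs.fields[0].area_cm2 - analytic) < 100.0  # discretization
        assert np.hypot(*(fs.fields[0].centroid_cm - [100.0, 50.0])) < 2.0

    def test_area_threshold_is_strict(self, env):
        m = np.zeros(env.shape)
        m[10:14, 10:18] = 1.0  # 32 bins = 200 cm^2 exactly
        assert fsm.detect_fields(m, env).n_fields == 0
        m[14, 10] = 1.0  # 33 bins
        assert fsm.detect_fields(m, env).n_fields == 1

    def test_invariant_to_positive_rescaling(self, env):
        m = gaussian_bump(env, 60.0, 40.0, 12.0)
        a = fsm.detect_fields(m, env)
        b = fsm.detect_fields(7.3 * m, env)
        assert a.n_fields == b.n_fields
        np.testing.assert_array_equal(a.field_mask, b.field_mask)

    def test_connectivity_option(self, env):
        m = np.zeros(env.shape)
        m[5:11, 5:11] = 1.0
        m[11, 11] = 1.0  # diagonal-touching extra bin
        m[12:18, 12:18] = 1.0
        f8 = fsm.detect_fields(m, env, connectivity=8)
        f4 = fsm.detect_fields(m, env, connectivity=4)
        assert f8.n_fields == 1  # 73 bins joined via the diagonal bridge
        assert f4.n_fields == 2  # two 36-bin squares (225 cm^2 each)


class TestSpatialInformation:
    def test_uniform_map_has_zero_information(self):
        assert fsm.spatial_information(np.full((40, 80), 3.7)) == pytest.approx(0.0)

    def test_single_active_bin_closed_form(self, env):
        m = np.zeros(env.shape)
        m[13, 57] = 5.0
        assert fsm.spatial_information(m) == pytest.approx(np.log2(3200))

    def test_matches_naive_double_loop(self, env):
        """Vectorized computation agrees with the brute-force sum to 1e-12."""
        rng = np.random.default_rng(8)
        for _ in range(3):
            m = rng.random(env.shape)
            lam = m.ravel()
            p = 1.0 / lam.size
            mean = lam.mean()
            expected = 0.0
            for v in lam:  # naive oracle
                if v > 0:
                    expected += p * (v / mean) * np.log2(v / mean)
            assert fsm.spatial_information(m) == pytest.approx(expected, abs=1e-12)

    def test_rescaling_invariance_and_errors(self, env):
        m = np.abs(np.random.default_rng(1).normal(size=env.shape))
        assert fsm.spatial_information(3 * m) == pytest.approx(
            fsm.spatial_information(m)
        )
        with pytest.raises(ValueError):
            fsm.spatial_information(np.zeros(env.shape))


class TestErrorRate:
    def test_enumerated_toy_maps(self):
        ref = np.array([True, False, False, False])
        assert fsm.error_rate(ref, ref).eps == 0.0
        assert fsm.error_rate(np.zeros(4, bool), ref).eps == 0.5
        obs = np.array([True, True, False, False])
        score = fsm.error_rate(obs, ref)
        assert score.eps == pytest.approx(1 / 6)
        assert score.miss_rate == 0.0
        assert score.false_alarm_rate == pytest.approx(1 / 3)

    def test_location_independent_firing_scores_half(self):
        """Any firing pattern independent of the field gives eps = 0.5 in
        expectation; total silence gives exactly 0.5."""
        rng = np.random.default_rng(2)
        ref = np.zeros(3200, bool)
        ref[rng.choice(3200, 50, replace=False)] = True
        eps = [
            fsm.error_rate(rng.random(3200) < p, ref).eps
            for p in (0.1, 0.5, 0.9) for _ in range(60)
        ]
        assert np.mean(eps) == pytest.approx(0.5, abs=0.01)

    def test_complement_symmetry(self):
        rng = np.random.default_rng(3)
        ref = rng.random(500) < 0.3
        obs = rng.random(500) < 0.4
        a = fsm.error_rate(obs, ref)
        b = fsm.error_rate(~obs, ~ref)
        assert a.eps == pytest.approx(b.eps)

    def test_empty_reference_class_rejected(self):
        with pytest.raises(ValueError):
            fsm.error_rate(np.ones(4, bool), np.ones(4, bool))


class TestRateMapsFromSpikes:
    def test_counts_over_occupancy(self, env):
        # 1 s parked in one bin, 1 s in another; 5 spikes in the first
        dt = 0.001
        pos = np.concatenate([
            np.tile([10.1, 10.1], (1000, 1)),
            np.tile([150.1, 80.1], (1000, 1)),
        ])
        spikes = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        m = fsm.rate_map_from_spikes(spikes, pos, dt, env, smooth_cm=0)
        ix, iy = env.position_to_bin(np.array([10.1, 10.1]))
        jx, jy = env.position_to_bin(np.array([150.1, 80.1]))
        assert m[iy, ix] == pytest.approx(5.0)
        assert m[jy, jx] == pytest.approx(0.0)
        assert np.isnan(m[0, 79])  # unvisited

    def test_no_spikes_gives_zero_map(self, env):
        pos = np.tile([50.0, 50.0], (100, 1))
        m = fsm.rate_map_from_spikes(np.array([]), pos, 0.001, env)
        assert np.nansum(m) == 0.0

    def test_smoothing_conserves_total_spike_count(self, env):
        """With full uniform coverage, sum(rate * occupancy) is unchanged by
        the reflecting-kernel smoothing."""
        dt = 0.01
        pos = env.bin_centers()  # visit every bin once
        rng = np.random.default_rng(5)
        # spikes: pick 200 random visit indices, spike at those times
        idx = rng.choice(len(pos), 200)
        spikes = idx * dt + dt / 2
        m = fsm.rate_map_from_spikes(spikes, pos, dt, env, smooth_cm=5.0)
        occ = fsm.occupancy_map(pos, dt, env)
        assert np.nansum(m * occ) == pytest.approx(200.0, rel=1e-9)


class TestSummary:
    def test_single_cell_single_field(self, env):
        m = np.zeros(env.shape)
        m[10:16, 10:18] = 1.0  # 48 bins = 300 cm^2
        s = fsm.summarize_population([fsm.detect_fields(m, env)])
        assert s["mean_field_size_cm2"] == pytest.approx(300.0)
        assert s["mean_fields_per_active_cell"] == 1.0
        assert s["n_place_cells"] == 1

    def test_empty_population(self):
        s = fsm.summarize_population([])
        assert s["n_active"] == 0 and s["n_fields"] == 0

    def test_cumulative_distribution_is_valid(self, env):
        rng = np.random.default_rng(9)
        sets = [
            fsm.detect_fields(gaussian_bump(env, x, y, sd), env)
            for x, y, sd in zip(
                rng.uniform(40, 160, 5), rng.uniform(30, 70, 5), rng.uniform(8, 14, 5)
            )
        ]
        s = fsm.summarize_population(sets)
        cum = s["cumulative_fraction"]
        assert np.all(np.diff(cum) >= 0) and cum[-1] == pytest.approx(1.0)
        assert np.all(np.diff(s["field_sizes_cm2"]) >= 0)
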