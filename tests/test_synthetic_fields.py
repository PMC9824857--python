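"""Terrain derivatives, covariate generation and simulator determinism."""

import numpy as np
import pytest

from yieldreg2d import SimConfig, generate_field_years
from yieldreg2d.synthetic_fields import (CELL_SIZE, compute_aspect,
                                         compute_slope, compute_tpi,
                                         generate_dem, generate_nitrogen_map,
                                         generate_sar_channels, yield_response)


class TestTerrain:
    def test_flat_dem_has_zero_slope_and_tpi(self):
        dem = np.full((10, 10), 1200.0)
        assert np.allclose(compute_slope(dem), 0.0)
        assert np.allclose(compute_tpi(dem), 0.0)

    def test_east_rising_plane_slope_and_aspect(self):
        """A plane rising 1 m per 10 m cell eastward has slope
        atan(0.1) ~= 5.711 degrees and a constant westward aspect on the
        interior (border replication halves the edge gradient)."""
        cols = np.arange(12, dtype=float)
        dem = np.tile(cols, (10, 1)) * 1.0     # +1 m per cell eastward
        slope = compute_slope(dem)
        interior = slope[1:-1, 1:-1]
        assert np.allclose(interior, np.degrees(np.arctan(1.0 / CELL_SIZE)),
                           atol=1e-9)
        aspect = compute_aspect(dem)[1:-1, 1:-1]
        # gx > 0, gy = 0 -> atan2(0, -gx) = pi (downslope faces west)
        assert np.allclose(aspect, np.pi)
        assert np.allclose(compute_tpi(dem)[1:-1, 1:-1], 0.0, atol=1e-12)

    def test_single_cell_bump_tpi(self):
        dem = np.zeros((9, 9))
        dem[4, 4] = 1.0
        tpi = compute_tpi(dem)
        assert tpi[4, 4] == pytest.approx(1.0)
        assert tpi[4, 5] == pytest.approx(-1.0 / 8)

    def test_too_small_grid_raises(self):
        with pytest.raises(ValueError):
            compute_slope(np.zeros((2, 5)))


class TestDem:
    def test_zero_relief_is_constant(self):
        cfg = SimConfig(dem_relief=0.0, seed=1)
        dem = generate_dem(cfg)
        assert np.allclose(dem, cfg.dem_base)

    def test_same_seed_same_surface(self):
        cfg = SimConfig(seed=9)
        np.testing.assert_array_equal(generate_dem(cfg), generate_dem(cfg))

    def test_variance_grows_with_relief(self):
        """Monte-Carlo over seeds: doubling the relief raises the spatial
        variance of the surface at fixed smoothness."""
        v_small, v_large = [], []
        for seed in range(20):
            v_small.append(generate_dem(SimConfig(dem_relief=5.0, seed=seed)).var())
            v_large.append(generate_dem(SimConfig(dem_relief=20.0, seed=seed)).var())
        assert np.mean(v_large) > np.mean(v_small)


class TestNitrogen:
    def test_single_rate_gives_constant_map(self, rng):
        cfg = SimConfig(n_rates=[100.0], seed=0)
        assert np.all(generate_nitrogen_map(cfg, rng) == 100.0)

    def test_block_structure(self, rng):
        cfg = SimConfig(height=30, width=30, block_size=5, seed=0)
        grid = generate_nitrogen_map(cfg, rng)
        blocks = grid.reshape(6, 5, 6, 5).transpose(0, 2, 1, 3).reshape(36, 25)
        assert np.all(blocks == blocks[:, :1])    # 36 internally constant blocks
        assert set(np.unique(grid)) <= set(cfg.n_rates)

    def test_block_covering_whole_field(self, rng):
        cfg = SimConfig(height=20, width=20, block_size=20, seed=0)
        grid = generate_nitrogen_map(cfg, rng)
        assert np.unique(grid).size == 1

    def test_empty_rates_raise(self, rng):
        cfg = SimConfig(seed=0)
        cfg.n_rates = []
        with pytest.raises(ValueError):
            generate_nitrogen_map(cfg, rng)


class TestSar:
    def test_wetter_year_has_higher_backscatter(self):
        cfg = SimConfig(seed=4)
        dem = generate_dem(cfg)
        tpi = np.zeros_like(dem)
        vv_dry, _ = generate_sar_channels(dem, tpi, 66.0,
                                          np.random.default_rng(5), cfg)
        vv_wet, _ = generate_sar_channels(dem, tpi, 199.0,
                                          np.random.default_rng(5), cfg)
        assert vv_wet.mean() > vv_dry.mean()

    def test_vh_weaker_than_vv_response(self):
        cfg = SimConfig(seed=4)
        dem = generate_dem(cfg)
        tpi = compute_tpi(dem)
        vv, vh = generate_sar_channels(dem, tpi, 130.0,
                                       np.random.default_rng(5), cfg)
        assert vh.mean() < vv.mean()              # VH baseline is lower
        assert np.corrcoef(vv.ravel(), vh.ravel())[0, 1] > 0.8


class TestYieldResponse:
    def _covs(self, cfg, nitrogen, precip, tpi=0.0):
        cov = np.zeros((3, 3, 8))
        cov[..., 0] = nitrogen
        cov[..., 1] = precip
        cov[..., 4] = tpi
        return cov

    def test_zero_nitrogen_zero_yield_without_noise(self):
        cfg = SimConfig(noise_sd=0.0, seed=0)
        y = yield_response(self._covs(cfg, 0.0, 100.0), cfg)
        assert np.all(y == 0.0)

    def test_monotone_in_nitrogen(self):
        cfg = SimConfig(noise_sd=0.0, seed=0)
        rates = [0, 25, 50, 75, 100, 125, 150]
        ys = [yield_response(self._covs(cfg, r, 110.0), cfg)[0, 0]
              for r in rates]
        assert np.all(np.diff(ys) >= 0)

    def test_matches_hand_computed_formula(self):
        """One cell evaluated by direct arithmetic:
        ymax0=110, N=100, half-sat=40, precip=130, ref=100, coeff=0.006,
        flat terrain -> 110 * 100/140 * 1.18."""
        cfg = SimConfig(noise_sd=0.0, seed=0)
        y = yield_response(self._covs(cfg, 100.0, 130.0), cfg)
        assert y[0, 0] == pytest.approx(110.0 * (100 / 140) * 1.18)

    def test_noise_truncated_at_zero(self):
        cfg = SimConfig(noise_sd=50.0, seed=0)
        y = yield_response(self._covs(cfg, 10.0, 80.0),
                           cfg, np.random.default_rng(0))
        assert np.all(y >= 0.0)


class TestGenerateFieldYears:
    def test_three_years_share_terrain(self, tiny_fields):
        assert len(tiny_fields) == 3
        for fy in tiny_fields[1:]:
            np.testing.assert_array_equal(fy.covariates[..., 3],
                                          tiny_fields[0].covariates[..., 3])
            np.testing.assert_array_equal(fy.mask, tiny_fields[0].mask)

    def test_mask_fraction_in_bounds(self, tiny_fields, tiny_sim_cfg):
        frac = tiny_fields[0].mask.mean()
        assert 0.5 * tiny_sim_cfg.mask_fraction <= frac <= 1.0

    def test_same_seed_byte_identical(self, tiny_sim_cfg):
        a = generate_field_years(tiny_sim_cfg)
        b = generate_field_years(tiny_sim_cfg)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.covariates, fb.covariates)
            np.testing.assert_array_equal(fa.yield_map, fb.yield_map)

    def test_precipitation_is_scalar_per_year(self, tiny_fields):
        for fy in tiny_fields:
            assert np.unique(fy.covariates[..., 1]).size == 1

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(height=10)
        with pytest.raises(ValueError):
            SimConfig(noise_sd=-1.0)
        with pytest.raises(ValueError):
            SimConfig(years=[(2020, 100.0)])
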