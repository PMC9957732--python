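"""RMA diffusion regression, chronological Monte Carlo, TPS surfaces, isochrones."""

from __future__ import annotations

import numpy as np
import pytest

from potspread import (
    CostRaster,
    SimConfig,
    SiteRecord,
    diffusion_mc,
    haversine_matrix,
    isochrones,
    rma_fit,
    simulate_sites,
    tps_surface,
)
from potspread.chronology_diffusion import predict_dates


class TestRmaFit:
    def test_noise_free_front_recovers_speed_exactly(self):
        d = np.linspace(0, 2000, 30)
        dates = 5900.0 - d / 8.0
        fit = rma_fit(d, dates)
        assert fit.speed == pytest.approx(8.0)
        assert fit.r == pytest.approx(-1.0)
        assert fit.intercept == pytest.approx(5900.0)

    def test_distance_scaling_equivariance(self):
        """Same dates over twice the distance = twice the front speed."""
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 1000, 25)
        dates = 6000 - d / 5 + rng.normal(0, 10, 25)
        assert rma_fit(2 * d, dates).speed == pytest.approx(2 * rma_fit(d, dates).speed)

    def test_slope_is_geometric_mean_of_ols_slopes(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 100, 40)
        y = 3 * x + rng.normal(0, 25, 40)
        fit = rma_fit(x, y)
        b_yx = np.polyfit(x, y, 1)[0]
        b_xy = np.polyfit(y, x, 1)[0]
        assert abs(fit.slope) == pytest.approx(np.sqrt(abs(b_yx / b_xy)))

    def test_symmetric_under_axis_exchange(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 100, 20)
        y = -2 * x + rng.normal(0, 15, 20)
        assert rma_fit(y, x).slope == pytest.approx(1 / rma_fit(x, y).slope)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            rma_fit(np.ones(5), np.arange(5.0))


def front_sites(n=20, speed=8.0, origin_date=6500.0, posterior_sd=0.0, n_draws=50, seed=0):
    rng = np.random.default_rng(seed)
    sites = []
    for i in range(n):
        lon = 10 + 50 * rng.random()
        sites.append(SiteRecord(f"s{i}", lon, 57.0, "r"))
    sites.insert(0, SiteRecord("origin", 62.0, 57.0, "r"))
    geo = haversine_matrix(sites)
    o = geo.labels.index("origin")
    for i, s in enumerate(sites):
        true = origin_date - geo.values[o, i] / speed
        s.date_posterior = true + (rng.normal(0, posterior_sd, n_draws)
                                   if posterior_sd else np.zeros(n_draws))
    return sites, geo


class TestDiffusionMC:
    def test_zero_width_posteriors_collapse_ci(self):
        sites, geo = front_sites(posterior_sd=0.0)
        fit = diffusion_mc(sites, geo, "origin", n_draws=50, seed=0)
        assert fit.speed == pytest.approx(8.0)
        assert fit.speed_ci_low == pytest.approx(fit.speed_ci_high) == pytest.approx(8.0)

    def test_ci_covers_truth_across_replicates(self):
        """Under the study conditions (40 sites, 8 km/yr, 100-yr posterior
        width) the Monte-Carlo CI contains the true speed in >=90% of runs."""
        cover = 0
        n_rep = 25
        for seed in range(n_rep):
            cfg = SimConfig(n_sites=40, seed=seed)
            sites, _ = simulate_sites(cfg)
            geo = haversine_matrix(sites)
            fit = diffusion_mc(sites, geo, "ORIGIN", n_draws=100, seed=seed)
            cover += fit.speed_ci_low <= cfg.true_speed <= fit.speed_ci_high
        assert cover >= 0.9 * n_rep

    def test_median_draw_speed_within_ten_percent(self):
        cfg = SimConfig(n_sites=40, seed=5)
        sites, _ = simulate_sites(cfg)
        fit = diffusion_mc(sites, haversine_matrix(sites), "ORIGIN", n_draws=200, seed=5)
        assert abs(np.median(fit.speed_draws) / cfg.true_speed - 1) < 0.10

    def test_upstream_origin_leaves_estimate_within_ci(self):
        """Moving the assumed origin further east along the same gradient
        changes the speed estimate by less than the chronological CI width."""
        sites, geo = front_sites(n=25, posterior_sd=100.0, n_draws=100, seed=3)
        fit1 = diffusion_mc(sites, geo, "origin", n_draws=100, seed=0)
        upstream = [SiteRecord("far_origin", 69.0, 57.0, "r",
                               np.full(100, 6500.0 + 7 * 60.0))] + sites
        geo2 = haversine_matrix(upstream)
        fit2 = diffusion_mc(upstream, geo2, "far_origin", n_draws=100, seed=0)
        assert fit1.speed_ci_low - 1 <= fit2.speed <= fit1.speed_ci_high + 1

    def test_missing_origin_rejected(self):
        sites, geo = front_sites()
        with pytest.raises(ValueError, match="origin"):
            diffusion_mc(sites, geo, "nowhere")


GRID = (0.0, 0.0, 10.0, 30, 40)  # xll, yll, cellsize, n_rows, n_cols


class TestTpsSurface:
    def test_reproduces_affine_field_exactly(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 400, (12, 2))
        vals = 3.0 + 0.02 * pts[:, 0] - 0.05 * pts[:, 1]
        surf = tps_surface(pts, vals, GRID, lam=0.0)
        r = surf.raster
        xs = r.xll + (np.arange(r.n_cols) + 0.5) * r.cellsize
        ys = r.yll + (r.n_rows - np.arange(r.n_rows) - 0.5) * r.cellsize
        gx, gy = np.meshgrid(xs, ys)
        expected = 3.0 + 0.02 * gx - 0.05 * gy
        assert np.allclose(r.values, expected, atol=1e-8)

    def test_interpolates_data_points_at_zero_smoothing(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 400, (15, 2))
        vals = np.sin(pts[:, 0] / 60) + np.cos(pts[:, 1] / 40)
        from scipy.interpolate import RBFInterpolator  # residual check at the points
        surf = tps_surface(pts, vals, GRID, lam=0.0)
        assert surf.lam == 0.0
        pred = RBFInterpolator(pts, vals, kernel="thin_plate_spline", degree=1)(pts)
        assert np.max(np.abs(pred - vals)) < 1e-8

    def test_large_smoothing_tends_to_least_squares_plane(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 400, (25, 2))
        vals = 1.0 + 0.01 * pts[:, 0] - 0.02 * pts[:, 1] + rng.normal(0, 0.5, 25)
        surf = tps_surface(pts, vals, GRID, lam=1e9)
        X = np.column_stack([np.ones(25), pts])
        beta = np.linalg.lstsq(X, vals, rcond=None)[0]
        r = surf.raster
        xs = r.xll + (np.arange(r.n_cols) + 0.5) * r.cellsize
        ys = r.yll + (r.n_rows - np.arange(r.n_rows) - 0.5) * r.cellsize
        gx, gy = np.meshgrid(xs, ys)
        plane = beta[0] + beta[1] * gx + beta[2] * gy
        assert np.allclose(r.values, plane, atol=1e-3)

    def test_collinear_points_rejected_at_zero_smoothing(self):
        pts = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(ValueError, match="ollinear"):
            tps_surface(pts, np.arange(5.0), GRID, lam=0.0)


class TestIsochrones:
    def test_monotone_gradient_gives_meridional_contours(self):
        z = np.tile(np.linspace(0, 100, 40), (30, 1))
        surf = tps_like = type("S", (), {})()
        from potspread.chronology_diffusion import Surface
        surf = Surface(CostRaster(0.0, 0.0, 10.0, z), 0.0, "date")
        feats = isochrones(surf, levels=[50.0])
        assert feats
        for f in feats:
            xs = [c[0] for c in f["geometry"]["coordinates"]]
            assert np.ptp(xs) < 11.0  # a near-vertical (north–south) line

    def test_radial_surface_gives_near_circular_contour(self):
        n = 60
        y, x = np.mgrid[0:n, 0:n]
        z = np.hypot(x - n / 2, y - n / 2)
        from potspread.chronology_diffusion import Surface
        surf = Surface(CostRaster(0.0, 0.0, 1.0, z), 0.0, "date")
        (feat,) = isochrones(surf, levels=[15.0])
        pts = np.asarray(feat["geometry"]["coordinates"])
        radii = np.hypot(pts[:, 0] - n / 2, pts[:, 1] - (n / 2 - 1) - 0.5 + 0.5)
        assert radii.std() / radii.mean() < 0.05

    def test_level_count_matches_levels_in_range(self):
        z = np.tile(np.linspace(0, 100, 40), (30, 1))
        from potspread.chronology_diffusion import Surface
        surf = Surface(CostRaster(0.0, 0.0, 10.0, z), 0.0, "date")
        feats = isochrones(surf, interval_years=25.0)
        levels = {f["properties"]["level"] for f in feats}
        # interior levels always produce contours; extreme levels touch only
        # the grid edge and may yield none
        assert {25.0, 50.0, 75.0} <= levels <= {0.0, 25.0, 50.0, 75.0, 100.0}

    def test_no_levels_in_range_rejected(self):
        from potspread.chronology_diffusion import Surface
        surf = Surface(CostRaster(0.0, 0.0, 1.0, np.zeros((5, 5))), 0.0)
        with pytest.raises(ValueError, match="level"):
            isochrones(surf, levels=[10.0])


def test_predicted_dates_follow_fit_line():
    fit = rma_fit(np.array([0.0, 100, 200, 300]), np.array([6500.0, 6490, 6480, 6470]))
    assert predict_dates(fit, np.array([1000.0]))[0] == pytest.approx(6400.0)
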