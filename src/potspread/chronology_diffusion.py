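"""Diffusion-front speed estimation, chronological Monte Carlo and surfaces.

The spread of pottery is modelled as a travelling front: arrival date
(years cal BC, larger = earlier) declines linearly with distance from an
origin site.  A reduced-major-axis (RMA) regression of date on distance
gives a slope in yr km⁻¹ whose reciprocal magnitude is the front speed in
km yr⁻¹.  RMA is symmetric in the two variables — slope =
sign(r) · sd(date)/sd(distance) — so the estimate does not depend on which
axis is treated as the response.

Chronological uncertainty is propagated by Monte Carlo: each draw picks one
posterior sample of the arrival date per site, refits the RMA line, and the
2.5/97.5 percentiles of the resulting speeds form the confidence interval.

Arrival-date (or Δ¹³C) surfaces are interpolated with thin-plate splines
(kernel r² log r plus an affine part; smoothing λ = 0 interpolates exactly)
and sliced into isochrone contours exported as GeoJSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.interpolate import RBFInterpolator
from skimage import measure

from .io_core import CostRaster, DistanceMatrix, SiteRecord


@dataclass
class DiffusionFit:
    """RMA diffusion-front fit: slope in yr km⁻¹, speed in km yr⁻¹."""

    slope: float
    intercept: float
    r: float
    speed: float
    n_sites: int
    origin_id: str = ""
    speed_ci_low: float = np.nan
    speed_ci_high: float = np.nan
    speed_draws: np.ndarray | None = None


@dataclass
class Surface:
    """Interpolated raster surface (arrival date cal BC, or Δ¹³C ‰)."""

    raster: CostRaster
    lam: float
    value_name: str = "value"


def rma_fit(distance_km: np.ndarray, date_calbc: np.ndarray,
            origin_id: str = "") -> DiffusionFit:
    """Reduced-major-axis regression of arrival date on distance from origin.

    slope = sign(r) × sd(date)/sd(distance), line through the centroid;
    speed = 1/|slope|.  Equals the geometric mean of the two OLS slopes.
    """
    x = np.asarray(distance_km, dtype=float)
    y = np.asarray(date_calbc, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired (distance, date) observations")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance on one axis; RMA slope undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    speed = 1.0 / abs(slope)
    return DiffusionFit(slope, intercept, r, speed, x.size, origin_id)


def diffusion_mc(
    sites: Sequence[SiteRecord],
    distances: DistanceMatrix,
    origin_id: str,
    n_draws: int = 500,
    seed: int | None = None,
    chronology_correction: bool = True,
) -> DiffusionFit:
    """RMA fit with Monte-Carlo propagation of arrival-date uncertainty.

    Per draw, one posterior date sample per site is selected (with
    replacement) and the front refit; the point estimate reported is the fit
    to the per-site posterior means, the CI the 2.5/97.5 percentiles of the
    per-draw speeds.  The origin site itself is excluded from the regression
    (its distance is identically zero only by construction).

    ``chronology_correction`` removes the attenuation that chronological
    measurement error induces on the RMA slope: sampling one date per site
    inflates the between-site date variance by (on average) the mean
    within-site posterior variance, so each draw's squared date s.d. is
    reduced by that amount — an errors-in-variables correction computed
    entirely from the observed posteriors — before the slope is formed.
    With zero-width posteriors the correction vanishes.
    """
    if origin_id not in distances.labels:
        raise ValueError(f"origin {origin_id!r} not in distance matrix")
    site_map = {s.site_id: s for s in sites}
    others = [lab for lab in distances.labels if lab != origin_id and lab in site_map]
    if len(others) < 3:
        raise ValueError("need >= 3 non-origin sites with dates")
    o = distances.labels.index(origin_id)
    dist = np.array([distances.values[o, distances.labels.index(lab)] for lab in others])
    posts = []
    for lab in others:
        p = site_map[lab].date_posterior
        if p.size == 0:
            raise ValueError(f"site {lab!r} has an empty date posterior")
        posts.append(p)
    mean_dates = np.array([p.mean() for p in posts])
    point = rma_fit(dist, mean_dates, origin_id)
    # mean within-site posterior variance = expected inflation of the
    # between-site date variance when one draw per site is taken
    mean_post_var = float(np.mean([p.var(ddof=1) if p.size > 1 else 0.0 for p in posts]))
    rng = np.random.default_rng(seed)
    speeds = np.empty(n_draws)
    for k in range(n_draws):
        dates = np.array([p[rng.integers(p.size)] for p in posts])
        if dates.std() == 0:  # degenerate zero-width posteriors
            speeds[k] = point.speed
            continue
        fit_k = rma_fit(dist, dates)
        if chronology_correction:
            var_y = np.var(dates, ddof=1)
            var_corr = max(var_y - mean_post_var, 0.25 * var_y)  # keep slope defined
            speeds[k] = fit_k.speed * np.sqrt(var_y / var_corr)
        else:
            speeds[k] = fit_k.speed
    point.speed_draws = speeds
    point.speed_ci_low, point.speed_ci_high = np.percentile(speeds, [2.5, 97.5])
    return point


def predict_dates(fit: DiffusionFit, distance_km: np.ndarray) -> np.ndarray:
    """Arrival dates (cal BC) predicted by a diffusion fit at given distances."""
    return fit.intercept + fit.slope * np.asarray(distance_km, dtype=float)


def tps_surface(
    points_xy: np.ndarray,
    values: np.ndarray,
    grid: CostRaster | tuple[float, float, float, int, int],
    lam: float = 0.0,
    value_name: str = "value",
) -> Surface:
    """Thin-plate-spline surface through scattered (x, y, value) points.

    ``grid`` is either an existing raster (its geometry is reused) or a
    ``(xll, yll, cellsize, n_rows, n_cols)`` tuple.  λ = 0 interpolates the
    points exactly; λ → ∞ tends to the least-squares plane.
    """
    pts = np.asarray(points_xy, dtype=float)
    vals = np.asarray(values, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] != vals.size:
        raise ValueError("points must be (n, 2) with matching values")
    if pts.shape[0] < 4:
        raise ValueError("need >= 4 points for a thin-plate spline")
    if lam == 0 and np.linalg.matrix_rank(np.column_stack([np.ones(len(pts)), pts])) < 3:
        raise ValueError("collinear points cannot be interpolated with lambda=0")
    rbf = RBFInterpolator(pts, vals, kernel="thin_plate_spline", smoothing=lam, degree=1)
    if isinstance(grid, CostRaster):
        xll, yll, cs, nr, nc = grid.xll, grid.yll, grid.cellsize, grid.n_rows, grid.n_cols
    else:
        xll, yll, cs, nr, nc = grid
    xs = xll + (np.arange(nc) + 0.5) * cs
    ys = yll + (nr - np.arange(nr) - 0.5) * cs  # row 0 = top
    gx, gy = np.meshgrid(xs, ys)
    z = rbf(np.column_stack([gx.ravel(), gy.ravel()])).reshape(nr, nc)
    return Surface(CostRaster(xll, yll, cs, z), lam, value_name)


def isochrones(
    surface: Surface,
    interval_years: float | None = None,
    levels: Sequence[float] | None = None,
) -> list[dict]:
    """Contour the surface at regular date levels; returns GeoJSON features.

    ``interval_years`` builds levels spanning the surface range; explicit
    ``levels`` override it.  Raises when no requested level intersects the
    surface range.
    """
    z = surface.raster.values
    if not np.isfinite(z).any():
        raise ValueError("surface has no finite values")
    zmin, zmax = np.nanmin(z), np.nanmax(z)
    if levels is None:
        if interval_years is None or interval_years <= 0:
            raise ValueError("give a positive interval_years or explicit levels")
        start = np.ceil(zmin / interval_years) * interval_years
        levels = list(np.arange(start, zmax + 1e-9, interval_years))
    levels = [lv for lv in levels if zmin <= lv <= zmax]
    if not levels:
        raise ValueError("no contour level intersects the surface range")
    r = surface.raster
    features = []
    for lv in levels:
        for contour in measure.find_contours(z, lv):
            # (row, col) index space -> projected cell-centre coordinates
            xs = r.xll + (contour[:, 1] + 0.5) * r.cellsize
            ys = r.yll + (r.n_rows - contour[:, 0] - 0.5) * r.cellsize
            coords = [[float(x), float(y)] for x, y in zip(xs, ys)]
            features.append({
                "type": "Feature",
                "properties": {"level": float(lv), "value_name": surface.value_name},
                "geometry": {"type": "LineString", "coordinates": coords},
            })
    return features


def write_isochrones_geojson(features: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
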