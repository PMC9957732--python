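"""Landscape distance matrices: great-circle, least-cost and circuit-theory.

Three notions of between-site distance feed the cultural analyses:

* great-circle (haversine) distance in km on WGS84 coordinates;
* least-cost distance — Dijkstra shortest paths on a lattice graph built
  from a projected cost raster, edge weight = mean of the two cell costs ×
  step length, with an 8- or 16-neighbourhood (knight's moves reduce the
  angular discretization error to ≈2.8%);
* effective resistance — the landscape as a resistor network (edge
  conductance = reciprocal of the cost-weighted step), integrating *all*
  paths between two sites rather than the single cheapest one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix, diags
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.sparse.linalg import factorized

from .io_core import CostRaster, DistanceMatrix, SiteRecord, logger

EARTH_RADIUS_KM = 6371.0

# neighbourhood step offsets (drow, dcol)
_STEPS_8 = [(0, 1), (1, 0), (1, 1), (1, -1)]
_STEPS_16 = _STEPS_8 + [(1, 2), (2, 1), (2, -1), (1, -2)]


@dataclass(frozen=True)
class CostModel:
    """How a DEM or cost raster is turned into per-cell traversal costs.

    ``cost = base_cost × (1 + slope_penalty × tan(slope))`` when applied to a
    DEM; rasters that already hold costs are used as-is.  Costs are clamped to
    a small positive floor so the lattice stays traversable.
    """

    base_cost: float = 1.0
    slope_penalty: float = 0.0
    neighborhood: int = 16
    cost_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.neighborhood not in (8, 16):
            raise ValueError("neighborhood must be 8 or 16")
        if self.base_cost <= 0:
            raise ValueError("base cost must be positive")


def haversine_km(
    lon1: float, lat1: float, lon2, lat2, radius_km: float = EARTH_RADIUS_KM
) -> np.ndarray:
    """Great-circle distance (km) between points in degrees; broadcasts."""
    f1, f2 = np.radians(lat1), np.radians(lat2)
    dl, df = np.radians(np.asarray(lon2) - lon1), f2 - f1
    a = np.sin(df / 2) ** 2 + np.cos(f1) * np.cos(f2) * np.sin(dl / 2) ** 2
    return 2 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def haversine_matrix(
    sites: Sequence[SiteRecord], radius_km: float = EARTH_RADIUS_KM
) -> DistanceMatrix:
    """Pairwise great-circle distance matrix in km."""
    lon = np.array([s.lon for s in sites])
    lat = np.array([s.lat for s in sites])
    n = len(sites)
    d = np.zeros((n, n))
    for i in range(n):
        d[i] = haversine_km(lon[i], lat[i], lon, lat, radius_km)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix([s.site_id for s in sites], d, "greatcircle_km")


def cost_from_dem(dem: CostRaster, model: CostModel) -> CostRaster:
    """Per-cell cost raster from a DEM via the slope-penalty cost function."""
    z = dem.values
    gy, gx = np.gradient(z, dem.cellsize)
    slope_tan = np.hypot(gx, gy)  # tan(slope) from finite differences
    cost = model.base_cost * (1.0 + model.slope_penalty * slope_tan)
    cost = np.where(np.isfinite(z), np.maximum(cost, model.cost_floor), np.nan)
    return CostRaster(dem.xll, dem.yll, dem.cellsize, cost, nodata=dem.nodata)


def _lattice_edges(raster: CostRaster, model: CostModel):
    """(node_i, node_j, step_length_m, mean_cost) arrays over the traversable lattice."""
    vals = raster.values
    nr, nc = vals.shape
    ok = np.isfinite(vals)
    if (vals[ok] <= 0).any():
        raise ValueError("cost raster has non-positive traversable cells")
    steps = _STEPS_8 if model.neighborhood == 8 else _STEPS_16
    ii, jj, ww, cc = [], [], [], []
    idx = np.arange(nr * nc).reshape(nr, nc)
    for dr, dcl in steps:
        r0 = slice(max(0, -dr), min(nr, nr - dr))
        c0 = slice(max(0, -dcl), min(nc, nc - dcl))
        r1 = slice(max(0, dr), min(nr, nr + dr))
        c1 = slice(max(0, dcl), min(nc, nc + dcl))
        a, b = idx[r0, c0].ravel(), idx[r1, c1].ravel()
        va, vb = vals[r0, c0].ravel(), vals[r1, c1].ravel()
        good = np.isfinite(va) & np.isfinite(vb)
        length = raster.cellsize * float(np.hypot(dr, dcl))
        ii.append(a[good]); jj.append(b[good])
        ww.append(np.full(good.sum(), length))
        cc.append(0.5 * (va[good] + vb[good]))
    return (np.concatenate(ii), np.concatenate(jj),
            np.concatenate(ww), np.concatenate(cc), nr * nc)


def equirectangular_projector(lon0: float, lat0: float, radius_km: float = EARTH_RADIUS_KM):
    """Local equirectangular degrees→metres projection anchored at (lon0, lat0).

    Adequate for sub-continental extents; pairs SiteRecords with a projected
    cost raster built on the same anchor.
    """
    kx = np.cos(np.radians(lat0)) * radius_km * 1000.0 * np.pi / 180.0
    ky = radius_km * 1000.0 * np.pi / 180.0

    def project(lon: float, lat: float) -> tuple[float, float]:
        return (lon - lon0) * kx, (lat - lat0) * ky

    return project


def _site_points(sites, project) -> tuple[list[str], np.ndarray]:
    """Normalize SiteRecords (via ``project``) or (id, x, y) triples to
    labelled projected coordinates in the raster's units."""
    labels, xy = [], []
    for s in sites:
        if isinstance(s, SiteRecord):
            if project is None:
                raise ValueError(
                    "raster analyses need projected coordinates: pass (id, x, y) "
                    "points or a project callable (e.g. equirectangular_projector)")
            labels.append(s.site_id)
            xy.append(project(s.lon, s.lat))
        else:
            sid, x, y = s
            labels.append(str(sid))
            xy.append((float(x), float(y)))
    return labels, np.asarray(xy)


def _snap_sites(raster: CostRaster, xy: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    """Node index of the nearest traversable cell for each projected point."""
    ok = np.isfinite(raster.values)
    ok_rows, ok_cols = np.nonzero(ok)
    nodes = []
    for lab, (x, y) in zip(labels, xy):
        r, c = raster.nearest_cell(x, y)
        if not ok[r, c]:
            d2 = (ok_rows - r) ** 2 + (ok_cols - c) ** 2
            k = int(np.argmin(d2))
            logger.info("site %s snapped to nearest traversable cell (%d,%d)",
                        lab, ok_rows[k], ok_cols[k])
            r, c = int(ok_rows[k]), int(ok_cols[k])
        nodes.append(r * raster.n_cols + c)
    return np.asarray(nodes)


def least_cost_matrix(
    raster: CostRaster,
    sites,
    model: CostModel = CostModel(),
    project=None,
) -> DistanceMatrix:
    """Accumulated-cost distance between sites on the raster lattice.

    Edge weight is mean adjacent cell cost × metric step length, so on a
    unit-cost raster the result approximates straight-line metric distance
    (within the neighbourhood's angular error).  Values are returned in km of
    cost-weighted length.
    """
    labels, xy = _site_points(sites, project)
    ii, jj, ww, cc, n_nodes = _lattice_edges(raster, model)
    w = ww * cc
    graph = coo_matrix((np.concatenate([w, w]),
                        (np.concatenate([ii, jj]), np.concatenate([jj, ii]))),
                       shape=(n_nodes, n_nodes)).tocsr()
    nodes = _snap_sites(raster, xy, labels)
    dist = dijkstra(graph, directed=False, indices=nodes)
    d = dist[:, nodes]
    if not np.isfinite(d).all():
        bad = np.argwhere(~np.isfinite(d))[0]
        raise ValueError(
            f"sites {labels[bad[0]]!r} and {labels[bad[1]]!r} are "
            "not connected on the traversable lattice"
        )
    d = 0.5 * (d + d.T) / 1000.0  # m -> km
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d, "leastcost_km")


def effective_resistance(
    edges: Sequence[tuple[int, int, float]], n_nodes: int,
    pairs: Sequence[tuple[int, int]],
) -> np.ndarray:
    """Two-point effective resistances of an undirected resistor network.

    ``edges`` are (i, j, conductance) triples.  Solves the graph Laplacian
    with one node grounded; raises if any requested pair spans components.
    """
    ii = np.array([e[0] for e in edges]); jj = np.array([e[1] for e in edges])
    gg = np.array([float(e[2]) for e in edges])
    if (gg <= 0).any():
        raise ValueError("conductances must be positive")
    A = coo_matrix((np.concatenate([gg, gg]),
                    (np.concatenate([ii, jj]), np.concatenate([jj, ii]))),
                   shape=(n_nodes, n_nodes)).tocsr()
    n_comp, labels = connected_components(A, directed=False)
    deg = np.asarray(A.sum(axis=1)).ravel()
    L = (diags(deg) - A).tocsr()
    out = np.empty(len(pairs))
    # ground one node per component; factorize the reduced Laplacian once per component
    solvers: dict[int, tuple] = {}
    for k, (a, b) in enumerate(pairs):
        if a == b:
            out[k] = 0.0
            continue
        if labels[a] != labels[b]:
            raise ValueError(f"nodes {a} and {b} are in different components")
        comp = labels[a]
        if comp not in solvers:
            members = np.nonzero(labels == comp)[0]
            ground = members[-1]
            keep = members[members != ground]
            pos = {node: i for i, node in enumerate(keep)}
            Lr = L[keep][:, keep].tocsc()
            solvers[comp] = (factorized(Lr), pos, ground)
        solve, pos, ground = solvers[comp]
        m = len(pos)
        rhs = np.zeros(m)
        if a != ground:
            rhs[pos[a]] += 1.0
        if b != ground:
            rhs[pos[b]] -= 1.0
        v = solve(rhs)
        va = v[pos[a]] if a != ground else 0.0
        vb = v[pos[b]] if b != ground else 0.0
        out[k] = va - vb
    return out


def resistance_matrix(
    raster: CostRaster,
    sites,
    model: CostModel = CostModel(),
    project=None,
) -> DistanceMatrix:
    """Circuit-theory effective-resistance distances between sites.

    Each lattice edge gets conductance 1/(mean cell cost × step length); the
    pairwise effective resistance integrates every path through the
    landscape, so broad corridors conduct better than single narrow ones.
    """
    labels, xy = _site_points(sites, project)
    ii, jj, ww, cc, n_nodes = _lattice_edges(raster, model)
    cond = 1.0 / (ww * cc)
    nodes = _snap_sites(raster, xy, labels)
    n = len(labels)
    pair_idx = [(int(nodes[i]), int(nodes[j])) for i in range(n) for j in range(i + 1, n)]
    res = effective_resistance(list(zip(ii, jj, cond)), n_nodes, pair_idx)
    d = np.zeros((n, n))
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = res[k]
            k += 1
    return DistanceMatrix(labels, d, "resistance")
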