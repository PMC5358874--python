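"""Home-range estimation: 100% MCP, alpha-Hull, and LSCV kernel density.

Three classical estimators of an animal's use of space from relocation
points, each computed in a Lambert azimuthal equal-area projection centred
on the points so areas are exact:

* minimum convex polygon (MCP) — smallest convex polygon enclosing all
  relocations; eligible from five locations;
* alpha-Hull — Delaunay-triangulate the relocations and delete triangles
  whose mean edge length exceeds alpha times the triangulation's mean edge
  length (unique edges counted once by default), keeping the union of the
  remaining triangles; with alpha large this recovers the MCP;
* kernel density estimate (KDE) — bivariate Gaussian kernel with a single
  scalar bandwidth chosen by least-squares cross-validation; the 95% and
  50% percent-volume contours of the utilization distribution are the home
  range and core use area. Eligible when mean daily locations exist for at
  least 20 days; coordinate sets skewed beyond an SD-ratio band of (0.5, 2)
  are anisotropically standardized before estimation and the density
  mapped back.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import ConvexHull, Delaunay
from shapely.geometry import Polygon

from .config import AnalysisParameters
from .geometry import LambertAzimuthalEqualArea
from .segmentation import InterNestingPeriod


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class HomeRangeEstimate:
    """Method-tagged polygon set with its area and centroid.

    ``polygons`` is a shapely (Multi)Polygon in lon/lat; ``polygons_xy`` the
    projected original in km with ``proj`` the projection used. Ineligible
    inputs (too few points/days) yield ``eligible=False`` with empty
    geometry rather than an exception.
    """

    turtle_id: str
    period_id: str
    method: str                       # MCP | AHULL | KDE95 | KDE50
    polygons: object | None
    polygons_xy: object | None
    proj: LambertAzimuthalEqualArea | None
    area_km2: float
    centroid_lon: float
    centroid_lat: float
    eligible: bool = True
    reason: str | None = None
    extras: dict = field(default_factory=dict)


def _ineligible(turtle_id, period_id, method, reason):
    return HomeRangeEstimate(turtle_id, period_id, method, None, None, None,
                             float("nan"), float("nan"), float("nan"),
                             eligible=False, reason=reason)


def mean_daily_locations(period: InterNestingPeriod) -> pd.DataFrame:
    """One mean location per UTC calendar day with at least one fix.

    The mean is arithmetic in a local equal-area projection and
    back-transformed, so it is a true spatial centroid of the day's fixes.
    """
    fixes = period.fixes
    if len(fixes) == 0:
        raise ValueError("empty period")
    proj = LambertAzimuthalEqualArea(float(fixes["lon"].mean()),
                                     float(fixes["lat"].mean()))
    x, y = proj.forward(fixes["lon"].to_numpy(), fixes["lat"].to_numpy())
    df = pd.DataFrame({"date": fixes["timestamp"].dt.date, "x": x, "y": y})
    daily = df.groupby("date", sort=True)[["x", "y"]].mean().reset_index()
    lon, lat = proj.inverse(daily["x"].to_numpy(), daily["y"].to_numpy())
    return pd.DataFrame({"date": daily["date"], "lon": lon, "lat": lat})


def _project(points: pd.DataFrame):
    proj = LambertAzimuthalEqualArea(float(points["lon"].mean()),
                                     float(points["lat"].mean()))
    x, y = proj.forward(points["lon"].to_numpy(), points["lat"].to_numpy())
    return proj, np.column_stack([x, y])


def _finalize(turtle_id, period_id, method, geom_xy, proj, extras=None):
    if geom_xy.is_empty or geom_xy.area <= 0:
        raise DegenerateGeometryError(f"{method}: zero-area geometry")
    cx, cy = geom_xy.centroid.x, geom_xy.centroid.y
    clon, clat = proj.inverse(cx, cy)
    geom_ll = shapely.transform(
        geom_xy, lambda a: np.column_stack(proj.inverse(a[:, 0], a[:, 1])))
    return HomeRangeEstimate(turtle_id, period_id, method, geom_ll, geom_xy,
                             proj, float(geom_xy.area), float(clon), float(clat),
                             extras=extras or {})


def mcp_estimate(points: pd.DataFrame, turtle_id: str = "", period_id: str = "",
                 params: AnalysisParameters = AnalysisParameters()) -> HomeRangeEstimate:
    """100% minimum convex polygon of the input locations."""
    if len(points) < params.mcp_min_points:
        return _ineligible(turtle_id, period_id, "MCP",
                           f"{len(points)} locations < {params.mcp_min_points}")
    proj, xy = _project(points)
    try:
        hull = ConvexHull(xy)
    except Exception as exc:
        raise DegenerateGeometryError(f"MCP: degenerate input ({exc})") from exc
    poly = Polygon(xy[hull.vertices])
    return _finalize(turtle_id, period_id, "MCP", poly, proj)


def _triangulation_edges(tri: Delaunay):
    """Unique undirected edges of a Delaunay triangulation as an (m, 2) array."""
    s = tri.simplices
    e = np.vstack([s[:, [0, 1]], s[:, [1, 2]], s[:, [0, 2]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


def alpha_hull_estimate(points: pd.DataFrame, alpha: float | None = None,
                        turtle_id: str = "", period_id: str = "",
                        params: AnalysisParameters = AnalysisParameters(),
                        unique_edges: bool = True) -> HomeRangeEstimate:
    """alpha-Hull home range by Delaunay triangle pruning.

    A triangle is kept iff the mean of its three edge lengths is at most
    ``alpha`` times the mean edge length of the whole triangulation. By
    default the global mean counts each shared edge once
    (``unique_edges=False`` counts edges once per incident triangle).
    """
    alpha = params.alpha if alpha is None else alpha
    if len(points) < params.mcp_min_points:
        return _ineligible(turtle_id, period_id, "AHULL",
                           f"{len(points)} locations < {params.mcp_min_points}")
    proj, xy = _project(points)
    try:
        tri = Delaunay(xy)
    except Exception as exc:
        raise DegenerateGeometryError(f"alpha-Hull: degenerate input ({exc})") from exc

    def elen(a, b):
        return np.linalg.norm(xy[a] - xy[b], axis=-1)

    s = tri.simplices
    tri_edge_lengths = np.column_stack([elen(s[:, 0], s[:, 1]),
                                        elen(s[:, 1], s[:, 2]),
                                        elen(s[:, 0], s[:, 2])])
    if unique_edges:
        ue = _triangulation_edges(tri)
        global_mean = float(np.mean(elen(ue[:, 0], ue[:, 1])))
    else:
        global_mean = float(np.mean(tri_edge_lengths))
    keep = tri_edge_lengths.mean(axis=1) <= alpha * global_mean
    if not np.any(keep):
        raise DegenerateGeometryError(
            f"alpha-Hull: every triangle removed at alpha={alpha}; increase alpha")
    polys = [Polygon(xy[t]) for t in s[keep]]
    hull = shapely.union_all(polys)
    extras = {"fraction_triangles_removed": float(1.0 - keep.mean()),
              "n_triangles": int(len(s))}
    return _finalize(turtle_id, period_id, "AHULL", hull, proj, extras)


# ---------------------------------------------------------------------------
# kernel density


@dataclass(frozen=True)
class KdeConfig:
    """KDE settings: LSCV bandwidth, grid resolution (default h/4), margin in
    multiples of h, SD-ratio rescale band, and the >= 20 daily-location
    eligibility rule."""

    bandwidth_method: str = "lscv"
    grid_resolution_km: float | None = None
    grid_margin_h: float = 3.0
    sd_ratio_bounds: tuple = (0.5, 2.0)
    min_days: int = 20

    def __post_init__(self):
        if self.grid_resolution_km is not None and self.grid_resolution_km <= 0:
            raise ValueError("grid_resolution_km must be positive")
        if self.min_days < 1:
            raise ValueError("min_days must be >= 1")


def reference_bandwidth(xy: np.ndarray) -> float:
    """Normal-reference scalar bandwidth h_ref = sigma * n^(-1/6)."""
    n = len(xy)
    sigma = float(np.sqrt(0.5 * (np.var(xy[:, 0]) + np.var(xy[:, 1]))))
    return sigma * n ** (-1.0 / 6.0)


def lscv_bandwidth(xy: np.ndarray, n_grid: int = 100,
                   span: tuple = (0.05, 2.0)) -> tuple[float, bool]:
    """Least-squares cross-validation bandwidth for a bivariate Gaussian kernel.

    Minimizes the LSCV score over a log-spaced grid of ``n_grid`` candidates
    in ``[span[0] * h_ref, span[1] * h_ref]``. A minimum on the grid
    boundary is the classic LSCV failure; the normal-reference bandwidth is
    returned instead with ``failed=True`` and a warning.
    """
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if n < 3:
        raise DegenerateGeometryError("LSCV needs at least 3 points")
    d2 = np.sum((xy[:, None, :] - xy[None, :, :]) ** 2, axis=-1)
    iu = np.triu_indices(n, k=1)
    d2o = d2[iu]
    if np.all(d2o < 1e-12):
        raise DegenerateGeometryError("all points identical")
    h_ref = reference_bandwidth(xy)
    hs = np.geomspace(span[0] * h_ref, span[1] * h_ref, n_grid)
    scores = np.empty(n_grid)
    for i, h in enumerate(hs):
        e4 = np.exp(-d2o / (4 * h * h)).sum()
        e2 = np.exp(-d2o / (2 * h * h)).sum()
        int_f2 = (n + 2.0 * e4) / (4 * np.pi * h * h * n * n)
        loo = 2.0 * e2 / (n * (n - 1) * 2 * np.pi * h * h)
        scores[i] = int_f2 - 2.0 * loo
    k = int(np.argmin(scores))
    if k in (0, n_grid - 1):
        warnings.warn("LSCV minimum on grid boundary; falling back to the "
                      "normal-reference bandwidth", RuntimeWarning, stacklevel=2)
        return h_ref, True
    return float(hs[k]), False


def _percent_volume_level(density: np.ndarray, cell_area: float, pct: float) -> float:
    """Density level whose superlevel set holds ``pct`` of the UD mass."""
    flat = np.sort(density.ravel())[::-1]
    mass = np.cumsum(flat) * cell_area
    total = mass[-1]
    idx = int(np.searchsorted(mass, pct * total))
    idx = min(idx, len(flat) - 1)
    return float(flat[idx])


def _contour_polygons(density, level, x0, y0, cell):
    """Closed contour loops at ``level`` as an even-odd polygon union (km)."""
    from skimage import measure

    loops = measure.find_contours(density, level)
    polys = []
    for lp in loops:
        if len(lp) < 4:
            continue
        xs = x0 + lp[:, 1] * cell
        ys = y0 + lp[:, 0] * cell
        p = Polygon(np.column_stack([xs, ys]))
        if p.is_valid and p.area > 0:
            polys.append(p)
    if not polys:
        raise DegenerateGeometryError("no closed contour at requested level")
    polys.sort(key=lambda p: p.area, reverse=True)
    out = polys[0]
    for p in polys[1:]:
        out = out.difference(p) if out.contains(p) else out.union(p)
    return out


def kde_estimate(daily_points: pd.DataFrame, config: KdeConfig = KdeConfig(),
                 turtle_id: str = "", period_id: str = "",
                 bandwidth_km: float | None = None):
    """Utilization distribution with 95% (home range) and 50% (core) contours.

    Returns ``(kde95, kde50, grid_info)`` where ``grid_info`` carries the
    density array (normalized to unit mass), cell size, origin and the
    bandwidth used. ``bandwidth_km`` overrides LSCV when given (e.g. an
    oracle bandwidth in calibration experiments).
    """
    if len(daily_points) < config.min_days:
        r = f"{len(daily_points)} daily locations < {config.min_days}"
        return (_ineligible(turtle_id, period_id, "KDE95", r),
                _ineligible(turtle_id, period_id, "KDE50", r), None)
    proj, xy = _project(daily_points)

    # SD-ratio rescale: standardize heavily skewed coordinate sets
    sdx, sdy = np.std(xy[:, 0]), np.std(xy[:, 1])
    lo, hi = config.sd_ratio_bounds
    ratio = sdx / sdy if sdy > 0 else np.inf
    rescaled = not (lo <= ratio <= hi)
    if rescaled:
        sx, sy = max(sdx, 1e-9), max(sdy, 1e-9)
        work = np.column_stack([xy[:, 0] / sx, xy[:, 1] / sy])
    else:
        sx = sy = 1.0
        work = xy

    lscv_failed = False
    if bandwidth_km is not None:
        h = float(bandwidth_km)
    else:
        h, lscv_failed = lscv_bandwidth(work)
    cell = config.grid_resolution_km if config.grid_resolution_km else h / 4.0
    margin = config.grid_margin_h * h
    x0, x1 = work[:, 0].min() - margin, work[:, 0].max() + margin
    y0, y1 = work[:, 1].min() - margin, work[:, 1].max() + margin
    nx = int(np.ceil((x1 - x0) / cell)) + 1
    ny = int(np.ceil((y1 - y0) / cell)) + 1
    gx = x0 + np.arange(nx) * cell
    gy = y0 + np.arange(ny) * cell

    # separable Gaussian evaluation: (ny, nx) density
    kx = np.exp(-0.5 * ((gx[None, :] - work[:, 0][:, None]) / h) ** 2)
    ky = np.exp(-0.5 * ((gy[None, :] - work[:, 1][:, None]) / h) ** 2)
    density = np.einsum("py,px->yx", ky, kx) / (len(work) * 2 * np.pi * h * h)
    cell_area = cell * cell
    density = density / (density.sum() * cell_area)   # exact unit mass on grid

    results = []
    for pct, name in ((0.95, "KDE95"), (0.50, "KDE50")):
        level = _percent_volume_level(density, cell_area, pct)
        poly_w = _contour_polygons(density, level, x0, y0, cell)
        if rescaled:
            poly_xy = shapely.transform(
                poly_w, lambda a: np.column_stack([a[:, 0] * sx, a[:, 1] * sy]))
        else:
            poly_xy = poly_w
        est = _finalize(turtle_id, period_id, name, poly_xy, proj,
                        {"bandwidth_km": h, "rescaled": rescaled,
                         "lscv_failed": lscv_failed, "contour_level": level})
        results.append(est)

    grid_info = {"density": density, "cell_km": cell, "x0": x0, "y0": y0,
                 "bandwidth_km": h, "rescaled": rescaled,
                 "scale_x": sx, "scale_y": sy, "proj": proj}
    return results[0], results[1], grid_info


def polygon_centroid(polygons, proj: LambertAzimuthalEqualArea | None = None):
    """Area-weighted centroid of a polygon set, in lon/lat.

    ``polygons`` may be a HomeRangeEstimate (its projection is reused) or a
    shapely geometry in km with an explicit ``proj``.
    """
    if isinstance(polygons, HomeRangeEstimate):
        geom, proj = polygons.polygons_xy, polygons.proj
    else:
        geom = polygons
    if geom is None or geom.is_empty or geom.area <= 0:
        raise DegenerateGeometryError("zero total area")
    c = geom.centroid
    lon, lat = proj.inverse(c.x, c.y)
    return float(lon), float(lat)


def estimate_all(period: InterNestingPeriod,
                 params: AnalysisParameters = AnalysisParameters(),
                 kde_config: KdeConfig | None = None) -> list[HomeRangeEstimate]:
    """MCP + alpha-Hull on the period's filtered fixes, KDE on mean daily
    locations when the >= 20-day rule is met."""
    kde_config = kde_config or KdeConfig(min_days=params.kde_min_days,
                                         sd_ratio_bounds=params.sd_ratio_bounds)
    pts = period.fixes[["lon", "lat"]]
    out = [mcp_estimate(pts, period.turtle_id, period.period_id, params),
           alpha_hull_estimate(pts, params.alpha, period.turtle_id,
                               period.period_id, params)]
    daily = mean_daily_locations(period)
    k95, k50, _ = kde_estimate(daily, kde_config, period.turtle_id, period.period_id)
    out.extend([k95, k50])
    return out
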