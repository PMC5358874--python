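"""Home-range estimators against independent geometric oracles."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import Polygon

from internesting.homerange import (
    DegenerateGeometryError,
    KdeConfig,
    alpha_hull_estimate,
    kde_estimate,
    lscv_bandwidth,
    mcp_estimate,
    mean_daily_locations,
    polygon_centroid,
    reference_bandwidth,
)
from internesting.segmentation import InterNestingPeriod

KM_PER_DEG = 111.195


def _pts(xy_km):
    """km offsets near (0 deg, 0 deg) -> lon/lat DataFrame."""
    xy = np.asarray(xy_km, dtype=float)
    return pd.DataFrame({"lon": xy[:, 0] / KM_PER_DEG, "lat": xy[:, 1] / KM_PER_DEG})


# ------------------------------------------------------- daily locations


def test_mean_daily_locations_arithmetic():
    fixes = pd.DataFrame({
        "timestamp": pd.to_datetime(["2011-05-01T02:00Z", "2011-05-01T10:00Z",
                                     "2011-05-01T18:00Z", "2011-05-02T02:00Z"],
                                    utc=True),
        "lon": [0.0, 0.0, 0.0, 0.1], "lat": [0.0, 0.2, 0.4, 0.1],
        "lc": ["3"] * 4})
    p = InterNestingPeriod("T", date(2011, 5, 1), date(2011, 5, 2), "ssm", fixes)
    daily = mean_daily_locations(p)
    assert len(daily) == 2                       # one point per distinct date
    assert daily["lat"].iloc[0] == pytest.approx(0.2, abs=1e-6)


# ------------------------------------------------------- MCP


def test_mcp_triangle_area_with_interior_points():
    pts = _pts([(0, 0), (4, 0), (0, 3), (1, 1), (0.5, 0.5)])
    est = mcp_estimate(pts)
    assert est.area_km2 == pytest.approx(6.0, rel=1e-4)


def test_mcp_matches_brute_force_hull_on_random_sets():
    rng = np.random.default_rng(8)
    for _ in range(20):
        xy = rng.uniform(-30, 30, (200, 2))
        pts = _pts(xy)
        est = mcp_estimate(pts)
        # oracle: shapely hull on the same projected plane
        px, py = est.proj.forward(pts["lon"].to_numpy(), pts["lat"].to_numpy())
        oracle = shapely.MultiPoint(np.column_stack([px, py])).convex_hull.area
        assert est.area_km2 == pytest.approx(oracle, rel=1e-9)


def test_mcp_interior_point_invariance():
    rng = np.random.default_rng(9)
    xy = rng.uniform(-20, 20, (50, 2))
    base = mcp_estimate(_pts(xy)).area_km2
    centroid = xy.mean(axis=0)
    with_interior = np.vstack([xy, centroid])
    assert mcp_estimate(_pts(with_interior)).area_km2 == pytest.approx(base, rel=1e-9)


def test_mcp_ineligible_below_five_points():
    est = mcp_estimate(_pts([(0, 0), (1, 0), (0, 1), (1, 1)]))
    assert not est.eligible


def test_mcp_collinear_raises():
    with pytest.raises(DegenerateGeometryError):
        mcp_estimate(_pts([(i, 0) for i in range(6)]))


# ------------------------------------------------------- alpha-hull


def _brute_force_alpha_hull(xy, alpha):
    """Independent triangle filter: direct edge enumeration, shared edges
    counted once in the global mean."""
    tri = Delaunay(xy)
    edges = set()
    for s in tri.simplices:
        for a, b in ((s[0], s[1]), (s[1], s[2]), (s[0], s[2])):
            edges.add((min(a, b), max(a, b)))
    gmean = np.mean([np.linalg.norm(xy[a] - xy[b]) for a, b in edges])
    kept = []
    for s in tri.simplices:
        ls = [np.linalg.norm(xy[s[i]] - xy[s[j]]) for i, j in ((0, 1), (1, 2), (0, 2))]
        if np.mean(ls) <= alpha * gmean:
            kept.append(s)
    return kept, len(tri.simplices)


def test_alpha_hull_matches_brute_force_filter():
    rng = np.random.default_rng(10)
    for _ in range(10):
        raw = rng.normal(0, 10, (50, 2))
        pts = _pts(raw)
        est = alpha_hull_estimate(pts, 1.5)
        px, py = est.proj.forward(pts["lon"].to_numpy(), pts["lat"].to_numpy())
        xy = np.column_stack([px, py])
        kept, ntri = _brute_force_alpha_hull(xy, 1.5)
        oracle_frac = 1.0 - len(kept) / ntri
        assert est.extras["fraction_triangles_removed"] == pytest.approx(
            oracle_frac, abs=1e-12)
        oracle_area = shapely.union_all([Polygon(xy[s]) for s in kept]).area
        assert est.area_km2 == pytest.approx(oracle_area, rel=1e-6)


def test_alpha_hull_large_alpha_equals_mcp():
    rng = np.random.default_rng(11)
    for _ in range(5):
        xy = rng.uniform(-25, 25, (60, 2))
        ah = alpha_hull_estimate(_pts(xy), 1e6)
        mcp = mcp_estimate(_pts(xy))
        assert ah.area_km2 == pytest.approx(mcp.area_km2, rel=1e-9)


def test_alpha_hull_two_clusters_splits_and_shrinks():
    rng = np.random.default_rng(12)
    a = rng.normal(0, 1.5, (8, 2))
    b = rng.normal(0, 1.5, (8, 2)) + [100.0, 0.0]
    pts = _pts(np.vstack([a, b]))
    ah = alpha_hull_estimate(pts, 1.5)
    mcp = mcp_estimate(pts)
    assert ah.polygons_xy.geom_type == "MultiPolygon"
    assert len(ah.polygons_xy.geoms) == 2
    assert ah.area_km2 < mcp.area_km2


def test_alpha_hull_monotone_in_alpha():
    rng = np.random.default_rng(13)
    xy = rng.normal(0, 8, (60, 2))
    areas = [alpha_hull_estimate(_pts(xy), a).area_km2
             for a in (1.0, 1.5, 2.0, 3.0, 10.0)]
    assert all(a2 >= a1 - 1e-9 for a1, a2 in zip(areas, areas[1:]))


def test_alpha_hull_all_removed_raises():
    # alpha ~ 0 removes every triangle
    rng = np.random.default_rng(14)
    xy = rng.normal(0, 5, (30, 2))
    with pytest.raises(DegenerateGeometryError, match="alpha"):
        alpha_hull_estimate(_pts(xy), 1e-9)


# ------------------------------------------------------- LSCV / KDE


def test_lscv_close_to_reference_on_large_normal_sample():
    rng = np.random.default_rng(15)
    xy = rng.normal(0, 1.0, (400, 2))
    h, failed = lscv_bandwidth(xy)
    assert not failed
    h_opt = 1.0 * 400 ** (-1.0 / 6.0)
    assert abs(h - h_opt) / h_opt < 0.30


def test_lscv_scale_equivariance():
    rng = np.random.default_rng(16)
    xy = rng.normal(0, 1.0, (150, 2))
    h1, _ = lscv_bandwidth(xy)
    h2, _ = lscv_bandwidth(2.0 * xy)
    assert h2 / h1 == pytest.approx(2.0, rel=0.03)   # up to grid granularity


def test_lscv_boundary_minimum_falls_back(recwarn):
    # two distant tight clusters push LSCV toward tiny h (grid boundary)
    rng = np.random.default_rng(17)
    xy = np.vstack([rng.normal(0, 0.001, (15, 2)),
                    rng.normal(0, 0.001, (15, 2)) + [200.0, 0.0]])
    h, failed = lscv_bandwidth(xy)
    assert failed
    assert h == pytest.approx(reference_bandwidth(xy))
    assert any("LSCV" in str(w.message) for w in recwarn.list)


def test_lscv_identical_points_raise():
    with pytest.raises(DegenerateGeometryError):
        lscv_bandwidth(np.zeros((25, 2)))


@pytest.fixture(scope="module")
def kde_normal_fixture():
    rng = np.random.default_rng(18)
    xy = rng.normal(0, 1.0, (500, 2))
    # standardize to exactly unit empirical variance so the analytic target
    # tests the contour machinery, not the draw's sampling variance
    xy = (xy - xy.mean(axis=0)) / xy.std(axis=0)
    daily = _pts(xy)
    h_oracle = 1.0 * 500 ** (-1.0 / 6.0)
    return kde_estimate(daily, KdeConfig(min_days=20), bandwidth_km=h_oracle)


def test_kde_mass_normalized(kde_normal_fixture):
    _, _, grid = kde_normal_fixture
    mass = grid["density"].sum() * grid["cell_km"] ** 2
    assert mass == pytest.approx(1.0, abs=1e-6)


def test_kde_core_nested_in_home_range(kde_normal_fixture):
    k95, k50, _ = kde_normal_fixture
    assert k50.area_km2 < k95.area_km2
    assert k95.polygons_xy.buffer(1e-9).contains(k50.polygons_xy)


def test_kde_50_contour_matches_analytic_gaussian_area(kde_normal_fixture):
    _, k50, _ = kde_normal_fixture
    analytic = 2 * np.pi * np.log(2)             # 50% mass disc of unit normal
    assert abs(k50.area_km2 - analytic) / analytic < 0.15


def test_kde_ineligible_below_min_days():
    rng = np.random.default_rng(19)
    daily = _pts(rng.normal(0, 5, (12, 2)))
    k95, k50, grid = kde_estimate(daily, KdeConfig(min_days=20))
    assert not k95.eligible and not k50.eligible and grid is None


def test_kde_sd_ratio_rescaling_engages():
    rng = np.random.default_rng(20)
    xy = rng.normal(0, 1.0, (60, 2)) * [30.0, 1.0]    # extreme x/y skew
    k95, _, grid = kde_estimate(_pts(xy), KdeConfig(min_days=20))
    assert grid["rescaled"] and k95.extras["rescaled"]
    assert k95.eligible and k95.area_km2 > 0


# ------------------------------------------------------- centroids


def _shoelace_centroid(poly_xy):
    xy = np.asarray(poly_xy.exterior.coords)
    x, y = xy[:-1, 0], xy[:-1, 1]
    xn, yn = xy[1:, 0], xy[1:, 1]
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    cx = np.sum((x + xn) * cross) / (6 * a)
    cy = np.sum((y + yn) * cross) / (6 * a)
    return cx, cy


def test_polygon_centroid_unit_square():
    from internesting.geometry import LambertAzimuthalEqualArea

    proj = LambertAzimuthalEqualArea(0.0, 0.0)
    sq = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
    lon, lat = polygon_centroid(sq, proj)
    x, y = proj.forward(lon, lat)
    assert (x, y) == pytest.approx((0.5, 0.5), abs=1e-9)


def test_polygon_centroid_two_equal_squares_midpoint():
    from internesting.geometry import LambertAzimuthalEqualArea

    proj = LambertAzimuthalEqualArea(0.0, 0.0)
    two = shapely.union_all([
        Polygon([(0, 0), (2, 0), (2, 2), (0, 2)]),
        Polygon([(10, 0), (12, 0), (12, 2), (10, 2)])])
    lon, lat = polygon_centroid(two, proj)
    x, y = proj.forward(lon, lat)
    assert (x, y) == pytest.approx((6.0, 1.0), abs=1e-9)


def test_polygon_centroid_matches_shoelace_oracle():
    from internesting.geometry import LambertAzimuthalEqualArea

    proj = LambertAzimuthalEqualArea(0.0, 0.0)
    rng = np.random.default_rng(21)
    for _ in range(10):
        pts = rng.uniform(-20, 20, (12, 2))
        poly = shapely.MultiPoint(pts).convex_hull       # random simple polygon
        lon, lat = polygon_centroid(poly, proj)
        x, y = proj.forward(lon, lat)
        ox, oy = _shoelace_centroid(poly)
        assert (x, y) == pytest.approx((ox, oy), abs=1e-9)


def test_polygon_centroid_zero_area_raises():
    from internesting.geometry import LambertAzimuthalEqualArea

    with pytest.raises(DegenerateGeometryError):
        polygon_centroid(Polygon(), LambertAzimuthalEqualArea(0.0, 0.0))
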