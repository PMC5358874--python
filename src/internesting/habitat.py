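"""Habitat characterization of inter-nesting areas.

Summaries that turn per-period tracks and home ranges into the quantities a
conservation assessment needs: centroid depth and distance to the nearest
land, total distance moved (TDM) and its daily rate, distances between
successive home-range centroids and successive nests, nest-site fidelity
(mean successive-nest distance at most 13.5 km), 10 x 10 km occupancy grids
of turtle-days and turtle counts, and chi-square tests of habitat-category
use against an even distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import box

from .config import AnalysisParameters
from .environment import LAND_DEPTH_SENTINEL, Environment
from .geometry import haversine_km
from .homerange import HomeRangeEstimate
from .segmentation import InterNestingPeriod

#: distance-to-shore categories (km), half-open [lo, hi)
DISTANCE_CATEGORY_EDGES_KM = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, np.inf)
#: depth categories (m): <= 15, 15-24, 25-34, 35-49, >= 50
DEPTH_CATEGORY_EDGES_M = (0.0, 15.0, 25.0, 35.0, 50.0, np.inf)


@dataclass
class CentroidCharacterization:
    turtle_id: str
    period_id: str
    method: str
    lon: float
    lat: float
    depth_m: float
    dist_to_land_km: float
    on_land: bool = False


def characterize_centroid(lon: float, lat: float, env: Environment,
                          turtle_id: str = "", period_id: str = "",
                          method: str = "") -> CentroidCharacterization:
    """Depth and distance-to-land of a home-range centroid.

    Depth is a bilinear bathymetry sample; distance is the minimum distance
    to the coastline geometry. A centroid on land (an occasional artifact
    of error-prone nearshore fixes) is flagged, with distance 0 and the
    land-depth sentinel.
    """
    if not np.all(env.covers(np.atleast_1d(lon), np.atleast_1d(lat))):
        raise ValueError("centroid outside environment extent")
    on_land = bool(env.is_land(lon, lat))
    if on_land:
        depth, dist = LAND_DEPTH_SENTINEL, 0.0
    else:
        depth = float(np.asarray(env.depth_m(np.atleast_1d(lon), np.atleast_1d(lat)))[0])
        dist = float(np.asarray(env.distance_to_land_km(np.atleast_1d(lon),
                                                        np.atleast_1d(lat)))[0])
    return CentroidCharacterization(turtle_id, period_id, method,
                                    float(lon), float(lat), depth, dist, on_land)


def total_distance_moved(period: InterNestingPeriod):
    """TDM (km) over successive filtered fixes and its per-day rate.

    The rate divides by the period's inclusive day count; a single-fix
    period has TDM 0 and an undefined (NaN) rate.
    """
    fixes = period.fixes
    if len(fixes) < 2:
        return 0.0, float("nan")
    lon = fixes["lon"].to_numpy()
    lat = fixes["lat"].to_numpy()
    tdm = float(np.sum(haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])))
    return tdm, tdm / period.n_days


def successive_centroid_distances(centroids: pd.DataFrame) -> pd.DataFrame:
    """Distances between successive centroids per turtle-season.

    ``centroids`` needs columns turtle_id, lon, lat and is assumed
    time-ordered within each turtle. Returns one row per turtle with
    d_1_2, d_2_3, d_3_4 (km, NaN where absent) and their total; turtles
    with fewer than two centroids yield no row.
    """
    rows = []
    for tid, grp in centroids.groupby("turtle_id", sort=True):
        if len(grp) < 2:
            continue
        lon = grp["lon"].to_numpy()
        lat = grp["lat"].to_numpy()
        d = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
        row = {"turtle_id": tid, "n_centroids": len(grp)}
        for k in range(3):
            row[f"d_{k + 1}_{k + 2}"] = float(d[k]) if k < len(d) else np.nan
        row["total_km"] = float(np.sum(d[:3]))
        rows.append(row)
    return pd.DataFrame(rows, columns=["turtle_id", "n_centroids",
                                       "d_1_2", "d_2_3", "d_3_4", "total_km"])


def summarize_centroid_transitions(table: pd.DataFrame) -> pd.DataFrame:
    """Cohort mean/SD/n for each centroid transition of the successive-
    distance table (pure aggregation of the per-turtle rows)."""
    rows = []
    for col in ("d_1_2", "d_2_3", "d_3_4"):
        v = table[col].dropna()
        rows.append({"transition": col.replace("d_", "centroid ").replace("_", "-"),
                     "mean_km": float(v.mean()) if len(v) else np.nan,
                     "sd_km": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
                     "n": int(len(v))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# occupancy grids


class OccupancyGrid:
    """Axis-aligned 10 x 10 km cells in the environment's equal-area frame.

    Cell (row, col) covers [x0 + col*s, x0 + (col+1)*s) x
    [y0 + row*s, y0 + (row+1)*s) with the origin anchored at the projection
    origin's south-west domain corner.
    """

    def __init__(self, env: Environment, cell_km: float = 10.0):
        self.env = env
        self.cell_km = float(cell_km)
        minx, miny, maxx, maxy = env.ocean.bounds
        self.x0 = np.floor(minx / cell_km) * cell_km
        self.y0 = np.floor(miny / cell_km) * cell_km
        self.ncols = int(np.ceil((maxx - self.x0) / cell_km))
        self.nrows = int(np.ceil((maxy - self.y0) / cell_km))

    def cell_of(self, lon, lat):
        x, y = self.env.to_xy(lon, lat)
        col = np.floor((np.asarray(x) - self.x0) / self.cell_km).astype(int)
        row = np.floor((np.asarray(y) - self.y0) / self.cell_km).astype(int)
        return row, col

    def in_grid(self, row, col):
        return ((row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols))

    def cell_polygon_xy(self, row, col):
        s = self.cell_km
        return box(self.x0 + col * s, self.y0 + row * s,
                   self.x0 + (col + 1) * s, self.y0 + (row + 1) * s)


def grid_turtle_days(periods: list[InterNestingPeriod], grid: OccupancyGrid,
                     one_cell_per_day: bool = False) -> pd.DataFrame:
    """Turtle-days per grid cell from all filtered fixes.

    Default crediting: for each turtle and UTC day, every cell containing
    at least one of that day's fixes gains one turtle-day (so a day split
    across cells credits each). ``one_cell_per_day=True`` instead assigns
    the day to the cell of the day's mean location, conserving the total
    exactly.
    """
    counts: dict = {}
    for p in periods:
        fixes = p.fixes
        if len(fixes) == 0:
            continue
        row, col = grid.cell_of(fixes["lon"].to_numpy(), fixes["lat"].to_numpy())
        if not np.all(grid.in_grid(row, col)):
            raise ValueError(f"{p.period_id}: fix outside occupancy grid")
        df = pd.DataFrame({"date": fixes["timestamp"].dt.date, "row": row, "col": col,
                           "lon": fixes["lon"], "lat": fixes["lat"]})
        if one_cell_per_day:
            daily = df.groupby("date")[["lon", "lat"]].mean()
            r2, c2 = grid.cell_of(daily["lon"].to_numpy(), daily["lat"].to_numpy())
            cells = pd.DataFrame({"row": r2, "col": c2})
        else:
            cells = df.drop_duplicates(["date", "row", "col"])[["row", "col"]]
        for _, r in cells.iterrows():
            key = (p.turtle_id, int(r["row"]), int(r["col"]))
            counts[key] = counts.get(key, 0) + 1
    agg: dict = {}
    for (tid, row, col), n in counts.items():
        agg[(row, col)] = agg.get((row, col), 0) + n
    rows = [{"row": rc[0], "col": rc[1], "turtle_days": n}
            for rc, n in sorted(agg.items())]
    return pd.DataFrame(rows, columns=["row", "col", "turtle_days"])


def grid_turtle_counts(estimates: list[HomeRangeEstimate], grid: OccupancyGrid,
                       method: str) -> pd.DataFrame:
    """Turtles-per-cell for one home-range method.

    All of a turtle's polygons for the method are merged first, so each
    turtle increments a cell at most once however many periods it had.
    """
    per_turtle: dict = {}
    for est in estimates:
        if est.method != method or not est.eligible or est.polygons is None:
            continue
        geom_xy = _to_env_frame(est, grid.env)
        per_turtle.setdefault(est.turtle_id, []).append(geom_xy)
    counts: dict = {}
    for tid, geoms in per_turtle.items():
        merged = shapely.union_all(geoms)
        minx, miny, maxx, maxy = merged.bounds
        c0 = int(np.floor((minx - grid.x0) / grid.cell_km))
        c1 = int(np.floor((maxx - grid.x0) / grid.cell_km))
        r0 = int(np.floor((miny - grid.y0) / grid.cell_km))
        r1 = int(np.floor((maxy - grid.y0) / grid.cell_km))
        for row in range(r0, r1 + 1):
            for col in range(c0, c1 + 1):
                if merged.intersects(grid.cell_polygon_xy(row, col)):
                    counts[(row, col)] = counts.get((row, col), 0) + 1
    rows = [{"row": rc[0], "col": rc[1], f"n_turtles_{method.lower()}": n}
            for rc, n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["row", "col", f"n_turtles_{method.lower()}"])


def _to_env_frame(est: HomeRangeEstimate, env: Environment):
    """Re-project an estimate's lon/lat polygons into the environment frame."""
    return shapely.transform(
        est.polygons, lambda a: np.column_stack(env.to_xy(a[:, 0], a[:, 1])))


# ---------------------------------------------------------------------------
# category tests and nest metrics


def categorize(values, edges) -> np.ndarray:
    """Counts per half-open category [edges[i], edges[i+1])."""
    values = np.asarray(values, dtype=float)
    edges = np.asarray(edges, dtype=float)
    counts, _ = np.histogram(values, bins=edges)
    return counts.astype(int)


def category_chisq(counts) -> tuple[float, int, float]:
    """Chi-square of observed category counts against an even distribution.

    chi2 = sum (O_i - E_i)^2 / E_i with E_i = total / k; df = k - 1; the
    p-value from the chi-square distribution.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 categories")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    k = counts.size
    expected = total / k
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def nest_fidelity_metrics(nests: pd.DataFrame,
                          params: AnalysisParameters = AnalysisParameters()
                          ) -> pd.DataFrame:
    """Per-turtle successive-nest distances, intervals and the fidelity flag.

    ``nests`` needs turtle_id, date, lon, lat (time-sorted within turtle).
    A turtle shows nest-site fidelity when its mean successive-nest distance
    is at most the 13.5-km rule. Single-nest turtles are flagged without
    metrics.
    """
    rows = []
    for tid, grp in nests.groupby("turtle_id", sort=True):
        grp = grp.sort_values("date")
        n = len(grp)
        if n < 2:
            rows.append({"turtle_id": tid, "n_nests": n, "mean_distance_km": np.nan,
                         "mean_interval_days": np.nan, "fidelity": pd.NA,
                         "flag": "single nest"})
            continue
        lon = grp["lon"].to_numpy()
        lat = grp["lat"].to_numpy()
        d = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
        dates = pd.to_datetime(grp["date"]).to_numpy()
        ivals = np.diff(dates).astype("timedelta64[D]").astype(float)
        mean_d = float(np.mean(d))
        rows.append({"turtle_id": tid, "n_nests": n,
                     "mean_distance_km": mean_d,
                     "mean_interval_days": float(np.mean(ivals)),
                     "fidelity": bool(mean_d <= params.nest_fidelity_km),
                     "flag": ""})
    return pd.DataFrame(rows, columns=["turtle_id", "n_nests", "mean_distance_km",
                                       "mean_interval_days", "fidelity", "flag"])


# ---------------------------------------------------------------------------
# standard statistical comparisons


def dunn_all_pairwise(groups: dict, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based all-pairwise comparison after Kruskal-Wallis.

    Standard z statistic on mean ranks with the tie correction, two-sided
    normal p-values, Bonferroni-adjusted by default.
    """
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for g, v in zip(names, values):
        mean_ranks[g] = float(np.mean(ranks[start:start + len(v)]))
        sizes[g] = len(v)
        start += len(v)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (n_total - 1))
    rows = []
    n_pairs = len(names) * (len(names) - 1) // 2
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            se = np.sqrt((n_total * (n_total + 1) / 12.0 - tie_term)
                         * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            if adjust == "bonferroni":
                p = min(1.0, p * n_pairs)
            rows.append({"group_a": a, "group_b": b, "z": float(z), "p": float(p)})
    return pd.DataFrame(rows)


def compare_groups(samples, test: str):
    """Thin wrappers over the standard tests used for cohort comparisons.

    test = "mann_whitney": samples is (a, b); returns (U, p).
    test = "kruskal_wallis_dunn": samples is {name: values}; returns
    (H, p, dunn table).
    test = "pearson": samples is (x, y); returns (r, p).
    """
    if test == "mann_whitney":
        a, b = samples
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if test == "kruskal_wallis_dunn":
        values = list(samples.values())
        h = stats.kruskal(*values)
        return float(h.statistic), float(h.pvalue), dunn_all_pairwise(samples)
    if test == "pearson":
        x, y = (np.asarray(v, dtype=float) for v in samples)
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError("constant vector in correlation")
        res = stats.pearsonr(x, y)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test: {test}")


def cohort_summary(per_period: pd.DataFrame,
                   value_columns=("area_km2", "depth_m", "dist_to_land_km")
                   ) -> pd.DataFrame:
    """Mean/SD/n per method over per-period records (pure aggregation)."""
    rows = []
    for method, grp in per_period.groupby("method", sort=True):
        row = {"method": method, "n": int(len(grp))}
        for c in value_columns:
            v = grp[c].dropna()
            row[f"mean_{c}"] = float(v.mean()) if len(v) else np.nan
            row[f"sd_{c}"] = float(v.std(ddof=1)) if len(v) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
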