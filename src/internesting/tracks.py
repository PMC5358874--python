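"""Argos fix tables and the track-cleaning filters.

A :class:`Track` is one deployment's time-ordered Argos fixes. The filters
implement the standard cleaning sequence for nearshore marine telemetry:
reject LC Z, drop points more than 1 km inland (Argos error tolerance),
drop biologically implausible depths (> 100 m) and swim speeds (> 5 km/h),
and — for display tracks only — drop spike-like turning angles (< 25 deg).

Filters are pure (new Track out), idempotent, and optionally append one
record per removed fix to a shared report list.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import LOCATION_CLASSES, AnalysisParameters
from .environment import Environment
from .geometry import AzimuthalEquidistant, haversine_km, interior_angles_deg

#: ordering used for duplicate-timestamp resolution: LC 3 best ... B worst, Z last
LC_QUALITY_ORDER = {lc: i for i, lc in enumerate(LOCATION_CLASSES)}

REQUIRED_COLUMNS = ("turtle_id", "timestamp", "lon", "lat", "lc")


class IngestError(ValueError):
    pass


class CoverageError(ValueError):
    pass


@dataclass
class Track:
    """Time-ordered Argos fixes for one deployment."""

    turtle_id: str
    fixes: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.fixes = self.fixes.reset_index(drop=True)

    def __len__(self):
        return len(self.fixes)

    @property
    def lon(self):
        return self.fixes["lon"].to_numpy(dtype=float)

    @property
    def lat(self):
        return self.fixes["lat"].to_numpy(dtype=float)

    @property
    def times(self):
        return self.fixes["timestamp"]

    def with_fixes(self, fixes: pd.DataFrame) -> "Track":
        return replace(self, fixes=fixes.reset_index(drop=True))


def _validate_fixes(df: pd.DataFrame, source: str = "<memory>"):
    bad_lat = df[(df["lat"] < -90) | (df["lat"] > 90)]
    bad_lon = df[(df["lon"] < -180) | (df["lon"] > 180)]
    if len(bad_lat) or len(bad_lon):
        row = (bad_lat.index[0] if len(bad_lat) else bad_lon.index[0])
        raise IngestError(f"{source}: coordinate out of range at row {row}")
    unknown = set(df["lc"].astype(str)) - set(LOCATION_CLASSES)
    if unknown:
        row = df.index[df["lc"].astype(str).isin(unknown)][0]
        raise IngestError(f"{source}: unknown location class at row {row}: {sorted(unknown)}")


def read_argos_csv(path) -> list[Track]:
    """Read an Argos fix table into per-turtle tracks.

    Tracks are grouped by id and time-sorted; duplicate timestamps within a
    turtle are resolved by keeping the better location class (LC 3 best),
    then the first occurrence.
    """
    df = pd.read_csv(path, dtype={"turtle_id": str, "lc": str})
    if df.empty and not set(REQUIRED_COLUMNS) <= set(df.columns):
        return []
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise IngestError(f"{path}: missing columns {sorted(missing)}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise IngestError(f"{path}: unparseable timestamp ({exc})") from exc
    _validate_fixes(df, str(path))

    tracks = []
    for tid, grp in df.groupby("turtle_id", sort=True):
        grp = grp.assign(_q=grp["lc"].map(LC_QUALITY_ORDER))
        grp = (grp.sort_values(["timestamp", "_q"], kind="stable")
               .drop_duplicates("timestamp", keep="first")
               .drop(columns="_q")
               .reset_index(drop=True))
        tracks.append(Track(turtle_id=str(tid), fixes=grp.drop(columns=["turtle_id"])))
    return tracks


def write_argos_csv(tracks, path):
    frames = []
    for t in tracks:
        df = t.fixes.copy()
        df.insert(0, "turtle_id", t.turtle_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=REQUIRED_COLUMNS)
    if "timestamp" in out.columns and len(out):
        out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def _log(report, track, mask_removed, rule, reason):
    if report is None:
        return
    for idx in np.flatnonzero(mask_removed):
        report.append({"turtle_id": track.turtle_id,
                       "timestamp": track.fixes["timestamp"].iloc[idx],
                       "rule": rule, "reason": reason})


def filter_location_class(track: Track, report: list | None = None) -> Track:
    """Remove LC Z fixes (no usable accuracy estimate)."""
    bad = (track.fixes["lc"].astype(str) == "Z").to_numpy()
    _log(report, track, bad, "lc", "location class Z")
    out = track.with_fixes(track.fixes[~bad])
    if len(out) == 0 and bad.any():
        out.meta = dict(out.meta, warning="all fixes rejected by LC filter")
    return out


def extent_filter(track: Track, env: Environment,
                  report: list | None = None) -> Track:
    """Clip to the study area: drop fixes outside the environment extent.

    Large Argos errors can throw a fix beyond the mapped domain; such fixes
    cannot be evaluated by the land or depth rules and are removed first.
    """
    if len(track) == 0:
        return track
    inside = np.asarray(env.covers(track.lon, track.lat))
    _log(report, track, ~inside, "extent", "outside study area")
    return track.with_fixes(track.fixes[inside])


def land_filter(track: Track, env: Environment,
                params: AnalysisParameters = AnalysisParameters(),
                report: list | None = None) -> Track:
    """Remove fixes on land farther than the 1-km buffer from the ocean."""
    if len(track) == 0:
        return track
    if not np.all(env.covers(track.lon, track.lat)):
        raise CoverageError(f"track {track.turtle_id}: fix outside environment extent")
    inland = env.inland_distance_km(track.lon, track.lat)
    bad = inland > params.land_buffer_km
    _log(report, track, bad, "land", f"> {params.land_buffer_km} km inland")
    return track.with_fixes(track.fixes[~bad])


def depth_filter(track: Track, env: Environment,
                 params: AnalysisParameters = AnalysisParameters(),
                 report: list | None = None) -> Track:
    """Remove fixes at depths greater than the plausibility cap (strict >)."""
    if len(track) == 0:
        return track
    if not np.all(env.covers(track.lon, track.lat)):
        raise CoverageError(f"track {track.turtle_id}: fix outside bathymetry extent")
    depth = np.asarray(env.depth_m(track.lon, track.lat))
    bad = depth > params.max_depth_m
    _log(report, track, bad, "depth", f"> {params.max_depth_m} m")
    return track.with_fixes(track.fixes[~bad])


def speed_filter(track: Track,
                 params: AnalysisParameters = AnalysisParameters(),
                 report: list | None = None) -> Track:
    """Remove fixes implying implausible swim speed from the last retained fix.

    Forward pass: the first fix is always retained; each later fix is kept
    only if the great-circle speed from the previously retained fix is
    <= the cap (strict > removes). A fix at zero time gap from the retained
    one (after duplicate resolution this means distinct positions at one
    instant) is dropped and flagged.
    """
    n = len(track)
    if n < 2:
        return track
    lon, lat = track.lon, track.lat
    t = track.fixes["timestamp"].astype("int64").to_numpy() / 3.6e12  # hours
    keep = np.zeros(n, dtype=bool)
    keep[0] = True
    last = 0
    for i in range(1, n):
        dt = t[i] - t[last]
        if dt <= 0:
            _log(report, track, np.eye(1, n, i, dtype=bool)[0], "speed", "zero time gap")
            continue
        speed = haversine_km(lon[last], lat[last], lon[i], lat[i]) / dt
        if speed > params.max_speed_kmh:
            _log(report, track, np.eye(1, n, i, dtype=bool)[0], "speed",
                 f"{speed:.2f} km/h > {params.max_speed_kmh}")
            continue
        keep[i] = True
        last = i
    return track.with_fixes(track.fixes[keep])


def turning_angle_filter(track: Track,
                         params: AnalysisParameters = AnalysisParameters(),
                         report: list | None = None) -> Track:
    """Remove spike-like interior fixes (turning angle < 25 deg); display use.

    Single pass over interior fixes in a local distance-preserving
    projection; fixes adjacent to a zero-length segment are left in place.
    """
    n = len(track)
    if n < 3:
        return track
    proj = AzimuthalEquidistant(float(np.median(track.lon)), float(np.median(track.lat)))
    x, y = proj.forward(track.lon, track.lat)
    ang = interior_angles_deg(x, y)
    bad = np.zeros(n, dtype=bool)
    interior_bad = np.where(np.isnan(ang), False, ang < params.min_turn_angle_deg)
    bad[1:-1] = interior_bad
    _log(report, track, bad, "angle", f"turning angle < {params.min_turn_angle_deg} deg")
    return track.with_fixes(track.fixes[~bad])


STANDARD_FILTER_ORDER = ("lc", "extent", "land", "depth", "speed")


def apply_standard_filters(track: Track, env: Environment,
                           params: AnalysisParameters = AnalysisParameters()):
    """LC -> extent -> land -> depth -> speed, returning (track, report)."""
    report: list = []
    out = filter_location_class(track, report)
    out = extent_filter(out, env, report)
    out = land_filter(out, env, params, report)
    out = depth_filter(out, env, params, report)
    out = speed_filter(out, params, report)
    rep = pd.DataFrame(report, columns=["turtle_id", "timestamp", "rule", "reason"])
    return out, rep


def max_consecutive_speed_kmh(track: Track) -> float:
    """Largest implied speed between consecutive fixes (0 for < 2 fixes)."""
    if len(track) < 2:
        return 0.0
    t = track.fixes["timestamp"].astype("int64").to_numpy() / 3.6e12
    d = haversine_km(track.lon[:-1], track.lat[:-1], track.lon[1:], track.lat[1:])
    dt = np.diff(t)
    with np.errstate(divide="ignore"):
        return float(np.max(np.where(dt > 0, d / np.where(dt > 0, dt, 1.0), np.inf)))
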