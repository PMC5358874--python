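"""Ground-truthed synthetic cohorts: world, trajectories, Argos observation.

The generator emulates the data-generating process behind a satellite-tagged
nesting cohort: a two-mode switching correlated random walk (directed
"migration" vs. restricted "inter-nesting" movement) confined to the ocean,
observed through an Argos-like channel — duty-cycled fix times, location
classes drawn from a configured mix, and isotropic positional error scaled
by class. Known outliers can be planted with labels so filter precision and
recall are exactly measurable, and threat layers (platforms with removal
dates, an effort-polygon partition of the shelf) complete the world.

Determinism contract: everything derives from ``SimConfig.seed`` through
one ``numpy`` SeedSequence per turtle, so identical configs give identical
cohorts and per-turtle streams survive reordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, box
from shapely.ops import nearest_points

from .config import LOCATION_CLASSES, SimConfig
from .environment import Environment, build_environment
from .geometry import AzimuthalEquidistant
from .threats import ThreatLayer
from .tracks import Track

MODE_MIGRATION = 0
MODE_INTERNESTING = 1
MODE_NAMES = {MODE_MIGRATION: "migration", MODE_INTERNESTING: "internesting"}


class SimulationError(RuntimeError):
    pass


class FixtureError(ValueError):
    pass


@dataclass
class TrueTrajectory:
    """Ground truth for one turtle on the 8-h step grid."""

    turtle_id: str
    times: pd.DatetimeIndex
    x_km: np.ndarray
    y_km: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    modes: np.ndarray           # 0 migration, 1 internesting
    env: Environment
    nest_events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["date", "lon", "lat"]))

    def __len__(self):
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.times, "lon": self.lon, "lat": self.lat,
                             "mode": [MODE_NAMES[m] for m in self.modes]})


def _turtle_rng(config: SimConfig, turtle_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), int(turtle_index)]))


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def simulate_trajectory(config: SimConfig, env: Environment,
                        turtle_index: int = 0) -> TrueTrajectory:
    """Simulate one turtle's two-mode correlated random walk in the ocean.

    Process model (first-difference CRW): the step vector is
    d_t = gamma_m R(theta_m) d_{t-1} + e_t with isotropic Gaussian process
    noise, the mode m following the configured Markov chain. Candidate
    steps leaving the ocean are re-drawn (noise only); exhausting the
    re-draw budget raises ``SimulationError`` naming the step.
    """
    rng = _turtle_rng(config, turtle_index)
    sp = np.asarray(config.switch_probs, dtype=float)
    shapely.prepare(env.ocean)

    # deployment point: configured distance offshore at a latitude drawn
    # from the central third of the domain
    ys0 = float(env.coastline.bounds[1]), float(env.coastline.bounds[3])
    span = ys0[1] - ys0[0]
    y_start = rng.uniform(ys0[0] + span * 0.35, ys0[0] + span * 0.65)
    coast_pt = nearest_points(Point(0.0, y_start), env.coastline)[1]
    start = np.array([coast_pt.x + config.deploy_offshore_km, coast_pt.y])
    if not env.in_ocean_xy([start[0]], [start[1]])[0]:
        raise SimulationError("deployment point not in ocean")

    n = int(config.n_steps)
    xy = np.empty((n, 2))
    modes = np.empty(n, dtype=int)
    xy[0] = start
    modes[0] = config.start_mode
    d_prev = rng.normal(scale=0.5, size=2)
    batch = 8

    for t in range(1, n):
        modes[t] = rng.choice(2, p=sp[modes[t - 1]])
        mp = config.mode_params[modes[t]]
        drift = mp.gamma * (_rot(mp.theta) @ d_prev)
        placed = False
        n_rounds = max(config.max_redraws // batch, 1)
        for rnd in range(n_rounds):
            # re-draw noise; past half the budget progressively damp the
            # persistent component (the animal turns along the coast)
            damp = 1.0 if rnd < n_rounds // 2 else 0.5 ** (rnd - n_rounds // 2 + 1)
            noise = rng.normal(scale=mp.step_scale_km, size=(batch, 2))
            cand = xy[t - 1] + damp * drift + noise
            ok = env.in_ocean_xy(cand[:, 0], cand[:, 1]) & \
                env.bathymetry.in_extent(cand[:, 0], cand[:, 1])
            hit = np.flatnonzero(ok)
            if hit.size:
                xy[t] = cand[hit[0]]
                placed = True
                break
        if not placed:
            raise SimulationError(
                f"turtle {turtle_index}: no legal step at index {t} after "
                f"{config.max_redraws} re-draws")
        d_prev = xy[t] - xy[t - 1]

    t0 = datetime(config.start_date.year, config.start_date.month,
                  config.start_date.day, tzinfo=timezone.utc)
    times = pd.DatetimeIndex([t0 + timedelta(hours=config.step_hours * i)
                              for i in range(n)])
    lon, lat = env.to_lonlat(xy[:, 0], xy[:, 1])

    # nesting emergences: on configured day offsets, a turtle close enough
    # to shore emerges at the nearest beach point
    nests = []
    day_idx = ((times - times[0]).total_seconds() // 86400).astype(int)
    for off in config.nest_day_offsets:
        sel = np.flatnonzero(day_idx == off)
        for i in sel:
            p = Point(xy[i, 0], xy[i, 1])
            d_shore = p.distance(env.coastline)
            if d_shore <= config.nest_shore_km:
                bp = nearest_points(p, env.coastline)[1]
                blon, blat = env.to_lonlat(np.array([bp.x]), np.array([bp.y]))
                nests.append({"date": times[i].date(), "lon": float(blon[0]),
                              "lat": float(blat[0])})
                break

    return TrueTrajectory(turtle_id=f"T{turtle_index:03d}", times=times,
                          x_km=xy[:, 0], y_km=xy[:, 1],
                          lon=np.asarray(lon), lat=np.asarray(lat),
                          modes=modes, env=env,
                          nest_events=pd.DataFrame(nests, columns=["date", "lon", "lat"]))


def observe_argos(traj: TrueTrajectory, config: SimConfig,
                  turtle_index: int = 0) -> Track:
    """Pass a true trajectory through the Argos observation channel.

    Fix times are drawn only inside duty-cycle on-windows (Poisson count per
    window at the configured rate, uniform within the window); each fix gets
    a location class from ``lc_mix`` and isotropic Gaussian positional error
    with that class's scale. The truth interpolates linearly between steps.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(config.seed), int(turtle_index), 1]))
    t0 = traj.times[0]
    total_h = (traj.times[-1] - t0).total_seconds() / 3600.0
    period = config.duty_on_hours + config.duty_off_hours
    lcs = [lc for lc in LOCATION_CLASSES]
    mix = np.array([config.lc_mix.get(lc, 0.0) for lc in lcs])

    rows = []
    w0 = 0.0
    while w0 < total_h:
        w1 = min(w0 + config.duty_on_hours, total_h)
        k = rng.poisson(config.fixes_per_on_window * (w1 - w0) / config.duty_on_hours)
        for th in np.sort(rng.uniform(w0, w1, size=k)):
            # linear interpolation of the true path
            g = th / config.step_hours
            i = min(int(g), len(traj) - 2)
            w = g - i
            x = (1 - w) * traj.x_km[i] + w * traj.x_km[i + 1]
            y = (1 - w) * traj.y_km[i] + w * traj.y_km[i + 1]
            lc = lcs[rng.choice(len(lcs), p=mix)]
            scale = config.lc_error_km.get(lc, 0.0)
            if scale > 0:
                x, y = x + rng.normal(scale=scale), y + rng.normal(scale=scale)
            lon, lat = traj.env.to_lonlat(np.array([x]), np.array([y]))
            rows.append({"timestamp": t0 + timedelta(hours=float(th)),
                         "lon": float(lon[0]), "lat": float(lat[0]),
                         "lc": lc, "label": "true"})
        w0 += period

    fixes = pd.DataFrame(rows, columns=["timestamp", "lon", "lat", "lc", "label"])
    fixes = fixes.sort_values("timestamp").reset_index(drop=True)
    return Track(turtle_id=traj.turtle_id, fixes=fixes,
                 meta={"deploy_date": t0.date(), "site": "SYN",
                       "scl_cm": float(np.round(rng.normal(63.1, 2.4), 1))})


# ---------------------------------------------------------------------------
# planted artifacts


def _gap_indices(track: Track, specs: list[dict], min_dt_h: float = 0.2,
                 max_dt_h: float = 24.0, max_spike_km: float = 40.0):
    """One gap index per artifact; spike gaps are short enough that the
    implied displacement stays within ``max_spike_km`` of the anchor."""
    t = track.fixes["timestamp"].astype("int64").to_numpy() / 3.6e12
    dt = np.diff(t)
    good = [i for i in np.argsort(dt)[::-1]
            if min_dt_h <= dt[i] <= max_dt_h]
    picks, used = [], set()
    for spec in specs:
        cap = max_dt_h
        if spec.get("kind") == "spike":
            cap = min(max_dt_h, 2.0 * max_spike_km / float(spec["speed_kmh"]))
        eligible = [i for i in good if i not in used and dt[i] <= cap]
        # keep artifacts apart so neighbouring insertions don't interact
        spaced = [i for i in eligible
                  if all(abs(i - u) >= 3 for u in used)]
        pool = spaced or eligible
        if not pool:
            raise FixtureError("not enough inter-fix gaps for requested artifacts")
        chosen = pool[0]
        used.add(chosen)
        picks.append(chosen)
    return picks


def plant_known_artifacts(track: Track, artifacts: list[dict],
                          env: Environment) -> Track:
    """Insert labeled outlier fixes for filter testing.

    Each artifact spec is a dict with ``kind`` in
    {"inland", "deep", "spike", "turn"} and one magnitude key:
    ``inland_km``, ``depth_m``, ``speed_kmh`` or ``angle_deg``. Inserted
    fixes carry label ``"artifact:<kind>"``; clean fixes are labeled
    ``"true"``. Timestamp collisions with existing fixes raise
    ``FixtureError``.
    """
    if not artifacts:
        return track
    fixes = track.fixes.copy()
    if "label" not in fixes.columns:
        fixes["label"] = "true"
    gaps = _gap_indices(track, artifacts)
    existing = set(fixes["timestamp"])
    new_rows = []

    for spec, gi in zip(artifacts, gaps):
        kind = spec["kind"]
        a = fixes.iloc[gi]
        b = fixes.iloc[gi + 1]
        t_mid = a["timestamp"] + (b["timestamp"] - a["timestamp"]) / 2
        if t_mid in existing:
            raise FixtureError(f"artifact time collides with existing fix at {t_mid}")
        ax, ay = env.to_xy(a["lon"], a["lat"])
        bx, by = env.to_xy(b["lon"], b["lat"])

        if kind == "inland":
            target = float(spec["inland_km"])
            # bisection on westward offset from the coast abeam the anchor
            cp = nearest_points(Point(float(ax), float(ay)), env.coastline)[1]
            lo, hi = 0.0, target * 3.0 + 5.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                p = (cp.x - mid, cp.y)
                d = float(shapely.distance(Point(p), env.ocean))
                if d < target:
                    lo = mid
                else:
                    hi = mid
            px, py = cp.x - 0.5 * (lo + hi), cp.y
        elif kind == "deep":
            depth = float(spec["depth_m"])
            off = depth / env.shelf_slope_m_per_km
            cp = nearest_points(Point(float(ax), float(ay)), env.coastline)[1]
            px, py = cp.x + off, cp.y
        elif kind == "spike":
            v = float(spec["speed_kmh"])
            dt_h = (t_mid - a["timestamp"]).total_seconds() / 3600.0
            dist = v * dt_h
            # place at an exact great-circle distance using a projection
            # centred on the anchor (AEQD preserves radial distance)
            aeqd = AzimuthalEquidistant(float(a["lon"]), float(a["lat"]))
            px_a, py_a = dist, 0.0  # due east
            plon, plat = aeqd.inverse(np.array([px_a]), np.array([py_a]))
            new_rows.append({"timestamp": t_mid, "lon": float(plon[0]),
                             "lat": float(plat[0]), "lc": "1",
                             "label": f"artifact:{kind}"})
            existing.add(t_mid)
            continue
        elif kind == "turn":
            ang = np.radians(float(spec["angle_deg"]))
            s = float(np.hypot(bx - ax, by - ay))
            h = s / (2.0 * np.tan(max(ang, 1e-6) / 2.0))
            mx, my = (ax + bx) / 2.0, (ay + by) / 2.0
            ux, uy = (by - ay) / max(s, 1e-9), -(bx - ax) / max(s, 1e-9)
            if ux < 0:   # prefer the offshore (eastward) side
                ux, uy = -ux, -uy
            px, py = mx + ux * h, my + uy * h
        else:
            raise FixtureError(f"unknown artifact kind: {kind}")

        plon, plat = env.to_lonlat(np.array([px]), np.array([py]))
        new_rows.append({"timestamp": t_mid, "lon": float(plon[0]),
                         "lat": float(plat[0]), "lc": "1",
                         "label": f"artifact:{kind}"})
        existing.add(t_mid)

    out = pd.concat([fixes, pd.DataFrame(new_rows)], ignore_index=True)
    out = out.sort_values("timestamp").reset_index(drop=True)
    return track.with_fixes(out)


# ---------------------------------------------------------------------------
# threat layers


def simulate_threat_layers(env: Environment, config: SimConfig) -> ThreatLayer:
    """Platform points (some with past removal dates) and an effort partition.

    Platforms fall uniformly over the shallow-shelf region; a configured
    fraction carries a removal date before the simulation start. Effort
    polygons tile the shelf region with ``effort_tile_km`` squares (clipped),
    each holding an integer effort-days attribute.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 7]))
    region = env.isobath_region.intersection(env.ocean)
    minx, miny, maxx, maxy = region.bounds

    pts = []
    while len(pts) < config.n_platforms:
        cand = np.column_stack([rng.uniform(minx, maxx, 64), rng.uniform(miny, maxy, 64)])
        ok = shapely.contains(region, shapely.points(cand))
        for x, y in cand[ok]:
            if len(pts) < config.n_platforms:
                pts.append((x, y))
    rows = []
    for x, y in pts:
        lon, lat = env.to_lonlat(np.array([x]), np.array([y]))
        removed = rng.random() < config.platform_removed_frac
        rem_date = (config.start_date - timedelta(days=int(rng.integers(30, 1000)))
                    if removed else None)
        rows.append({"lon": float(lon[0]), "lat": float(lat[0]), "removal_date": rem_date})
    platforms = pd.DataFrame(rows, columns=["lon", "lat", "removal_date"])

    tiles = []
    step = config.effort_tile_km
    x = minx
    while x < maxx:
        y = miny
        while y < maxy:
            cell = box(x, y, x + step, y + step).intersection(region)
            if not cell.is_empty and cell.area > 1e-9:
                ring_ll = _densified_lonlat(env, cell)
                tiles.append((ring_ll, int(rng.integers(1000, 45000))))
            y += step
        x += step
    return ThreatLayer(platforms=platforms, effort_polygons=tiles)


def _densified_lonlat(env: Environment, geom, max_seg_km: float = 2.0):
    """Convert a km-frame polygon to lon/lat with densified edges."""
    geom = shapely.segmentize(geom, max_seg_km)

    def conv_poly(p):
        ext = np.asarray(p.exterior.coords)
        lon, lat = env.to_lonlat(ext[:, 0], ext[:, 1])
        holes = []
        for i in p.interiors:
            c = np.asarray(i.coords)
            hlon, hlat = env.to_lonlat(c[:, 0], c[:, 1])
            holes.append(np.column_stack([hlon, hlat]))
        return shapely.Polygon(np.column_stack([lon, lat]), holes)

    if geom.geom_type == "Polygon":
        return conv_poly(geom)
    return shapely.MultiPolygon([conv_poly(g) for g in geom.geoms
                                 if g.geom_type == "Polygon"])


# ---------------------------------------------------------------------------
# cohort convenience


@dataclass
class SyntheticCohort:
    config: SimConfig
    env: Environment
    trajectories: list
    tracks: list
    threats: ThreatLayer

    @property
    def nest_events(self) -> pd.DataFrame:
        frames = []
        for tr in self.trajectories:
            if len(tr.nest_events):
                df = tr.nest_events.copy()
                df.insert(0, "turtle_id", tr.turtle_id)
                frames.append(df)
        cols = ["turtle_id", "date", "lon", "lat"]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=cols)


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """World + trajectories + Argos tracks + threat layers for one config."""
    env = build_environment(config)
    trajectories = [simulate_trajectory(config, env, i) for i in range(config.n_turtles)]
    tracks = [observe_argos(tr, config, i) for i, tr in enumerate(trajectories)]
    threats = simulate_threat_layers(env, config)
    return SyntheticCohort(config=config, env=env, trajectories=trajectories,
                           tracks=tracks, threats=threats)
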