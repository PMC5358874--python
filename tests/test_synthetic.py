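"""Synthetic cohort generator: determinism, observation model, artifacts,
threat layers, mode-chain occupancy."""

import numpy as np
import pandas as pd
import pytest
import shapely

from internesting.config import ModeParams, SimConfig
from internesting.environment import build_environment
from internesting.synthetic import (
    FixtureError,
    observe_argos,
    plant_known_artifacts,
    simulate_threat_layers,
    simulate_trajectory,
)
from internesting.threats import active_platforms
from internesting.geometry import haversine_km


def test_same_seed_identical_trajectory_and_track(flat_cfg, flat_env):
    t1 = simulate_trajectory(flat_cfg, flat_env, 0)
    t2 = simulate_trajectory(flat_cfg, flat_env, 0)
    assert np.array_equal(t1.x_km, t2.x_km)
    assert np.array_equal(t1.modes, t2.modes)
    o1 = observe_argos(t1, flat_cfg, 0)
    o2 = observe_argos(t2, flat_cfg, 0)
    assert o1.fixes.equals(o2.fixes)


def test_identity_switch_matrix_keeps_start_mode(flat_env, flat_cfg):
    cfg = flat_cfg.with_(switch_probs=((1.0, 0.0), (0.0, 1.0)), start_mode=1,
                         n_steps=60)
    tr = simulate_trajectory(cfg, flat_env, 0)
    assert np.all(tr.modes == 1)


def test_trajectory_stays_in_ocean(flat_cfg, flat_env):
    tr = simulate_trajectory(flat_cfg, flat_env, 1)
    assert np.all(flat_env.in_ocean_xy(tr.x_km, tr.y_km))


def test_zero_gamma_gives_uncorrelated_step_directions(flat_env, flat_cfg):
    # gamma 0: successive headings independent -> circular correlation ~ 0
    cfg = flat_cfg.with_(
        n_steps=5000, start_mode=1,
        switch_probs=((0.0, 1.0), (0.0, 1.0)),
        mode_params=(ModeParams(gamma=0.9, step_scale_km=2.0),
                     ModeParams(gamma=0.0, step_scale_km=2.0)),
        domain_offshore_km=600, domain_lat_span_deg=10, raster_cell_km=4.0)
    env = build_environment(cfg)
    tr = simulate_trajectory(cfg, env, 0)
    d = np.column_stack([np.diff(tr.x_km), np.diff(tr.y_km)])
    head = np.arctan2(d[:, 1], d[:, 0])
    turn = np.diff(head)
    # mean resultant of turn angles should be near 0 (uniform turns)
    resultant = np.hypot(np.mean(np.cos(turn)), np.mean(np.sin(turn)))
    assert resultant < 3.0 / np.sqrt(len(turn))


def test_mode_occupancy_matches_stationary_distribution(flat_cfg, flat_env):
    p01, p10 = 0.04, 0.06   # migration->internesting, internesting->migration
    cfg = flat_cfg.with_(n_steps=10_000, raster_cell_km=4.0,
                         switch_probs=((1 - p01, p01), (p10, 1 - p10)),
                         mode_params=(ModeParams(gamma=0.5, step_scale_km=1.0),
                                      ModeParams(gamma=0.2, step_scale_km=1.0)))
    env = build_environment(cfg)
    tr = simulate_trajectory(cfg, env, 0)
    pi1 = p01 / (p01 + p10)                       # stationary internesting share
    lam = 1.0 - p01 - p10                         # chain autocorrelation
    se = np.sqrt(pi1 * (1 - pi1) / cfg.n_steps * (1 + lam) / (1 - lam))
    assert abs(tr.modes.mean() - pi1) < 3 * se


def test_duty_cycle_no_fixes_in_off_windows(flat_cfg, flat_env):
    tr = simulate_trajectory(flat_cfg, flat_env, 2)
    trk = observe_argos(tr, flat_cfg, 2)
    rel_h = (trk.fixes["timestamp"] - tr.times[0]).dt.total_seconds() / 3600.0
    phase = rel_h % (flat_cfg.duty_on_hours + flat_cfg.duty_off_hours)
    assert np.all(phase <= flat_cfg.duty_on_hours)


def test_zero_error_lc3_fixes_on_true_path(flat_cfg, flat_env):
    cfg = flat_cfg.with_(lc_mix={"3": 1.0}, lc_error_km={"3": 0.0})
    tr = simulate_trajectory(cfg, flat_env, 0)
    trk = observe_argos(tr, cfg, 0)
    # every fix lies on the linearly interpolated true path
    rel_h = (trk.fixes["timestamp"] - tr.times[0]).dt.total_seconds().to_numpy() / 3600.0
    g = rel_h / cfg.step_hours
    i = np.minimum(g.astype(int), len(tr.x_km) - 2)
    w = g - i
    x_true = (1 - w) * tr.x_km[i] + w * tr.x_km[i + 1]
    y_true = (1 - w) * tr.y_km[i] + w * tr.y_km[i + 1]
    fx, fy = flat_env.to_xy(trk.lon, trk.lat)
    assert np.allclose(np.hypot(fx - x_true, fy - y_true), 0.0, atol=1e-6)


def test_lc_frequencies_within_binomial_bounds(flat_cfg, flat_env):
    cfg = flat_cfg.with_(n_steps=2500, fixes_per_on_window=4.0,
                         raster_cell_km=4.0)
    env = build_environment(cfg)
    tr = simulate_trajectory(cfg, env, 0)
    trk = observe_argos(tr, cfg, 0)
    n = len(trk)
    assert n >= 5000
    freq = trk.fixes["lc"].value_counts(normalize=True)
    for lc, p in cfg.lc_mix.items():
        if p == 0:
            continue
        se = np.sqrt(p * (1 - p) / n)
        assert abs(freq.get(lc, 0.0) - p) < 3 * se, lc


# ------------------------------------------------------------- artifacts

@pytest.fixture(scope="module")
def base_track(flat_cfg):
    env = build_environment(flat_cfg)
    tr = simulate_trajectory(flat_cfg, env, 3)
    return env, observe_argos(tr, flat_cfg, 3)


def test_empty_artifact_spec_is_identity(base_track):
    env, trk = base_track
    assert plant_known_artifacts(trk, [], env) is trk


def test_spike_artifact_implies_requested_speed(base_track):
    env, trk = base_track
    out = plant_known_artifacts(trk, [{"kind": "spike", "speed_kmh": 50.0}], env)
    row = out.fixes[out.fixes["label"] == "artifact:spike"]
    assert len(row) == 1
    i = row.index[0]
    prev = out.fixes.iloc[i - 1]
    dt_h = (row["timestamp"].iloc[0] - prev["timestamp"]).total_seconds() / 3600.0
    d = haversine_km(prev["lon"], prev["lat"], row["lon"].iloc[0], row["lat"].iloc[0])
    assert d / dt_h == pytest.approx(50.0, abs=0.1)


def test_inland_artifact_at_requested_distance(base_track):
    env, trk = base_track
    out = plant_known_artifacts(trk, [{"kind": "inland", "inland_km": 2.0}], env)
    row = out.fixes[out.fixes["label"] == "artifact:inland"]
    d = env.inland_distance_km(float(row["lon"].iloc[0]), float(row["lat"].iloc[0]))
    assert d == pytest.approx(2.0, abs=0.05)


def test_artifact_labels_recoverable(base_track):
    env, trk = base_track
    spec = [{"kind": "inland", "inland_km": 3.0}, {"kind": "deep", "depth_m": 150.0},
            {"kind": "spike", "speed_kmh": 40.0}, {"kind": "turn", "angle_deg": 5.0}]
    out = plant_known_artifacts(trk, spec, env)
    labels = out.fixes["label"].value_counts()
    for s in spec:
        assert labels[f"artifact:{s['kind']}"] == 1
    assert labels["true"] == len(trk)


def test_artifact_errors(base_track, track_factory):
    env, trk = base_track
    with pytest.raises(FixtureError, match="unknown artifact kind"):
        plant_known_artifacts(trk, [{"kind": "wormhole"}], env)
    # a 2-fix track has a single usable gap; 3 artifacts cannot be placed
    two = track_factory(["2011-05-01T00:00Z", "2011-05-01T01:00Z"],
                        [-96.5, -96.51], [24.5, 24.5])
    two.fixes["label"] = "true"
    with pytest.raises(FixtureError, match="gaps"):
        plant_known_artifacts(two, [{"kind": "deep", "depth_m": 120.0}] * 3, env)


# ------------------------------------------------------------- threats

def test_zero_platforms_empty_layer(flat_cfg, flat_env):
    layer = simulate_threat_layers(flat_env, flat_cfg.with_(n_platforms=0))
    assert len(layer.platforms) == 0


def test_all_platforms_removed_leaves_none_active(flat_cfg, flat_env):
    layer = simulate_threat_layers(flat_env, flat_cfg.with_(platform_removed_frac=1.0))
    act = active_platforms(layer, flat_cfg.start_date)
    assert len(act) == 0


def test_effort_tiles_partition_shelf(flat_cfg, flat_env):
    layer = simulate_threat_layers(flat_env, flat_cfg)
    polys = [p for p, _ in layer.effort_polygons]
    union = shapely.union_all(polys)
    # pairwise overlaps are negligible relative to the union
    overlap = sum(polys[i].intersection(polys[j]).area
                  for i in range(len(polys)) for j in range(i + 1, len(polys))
                  if polys[i].intersects(polys[j]))
    assert overlap < 1e-6 * union.area
    # union covers the shelf region (compare in the km frame via area)
    region = flat_env.isobath_region.intersection(flat_env.ocean)
    # convert union (lon/lat) back to km for an area comparison
    import numpy as np
    km_union = shapely.transform(
        union, lambda a: np.column_stack(flat_env.to_xy(a[:, 0], a[:, 1])))
    assert km_union.area == pytest.approx(region.area, rel=1e-3)
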