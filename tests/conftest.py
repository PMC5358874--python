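"""Shared fixtures: a flat-coast world for exact-ramp checks and a default
sinusoidal-coast world, both session-scoped (environment construction is the
slow part)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from internesting.config import ModeParams, SimConfig
from internesting.environment import build_environment
from internesting.tracks import Track

#: location-class mix of a modern (Kalman-processed) tag: mostly good classes
CLEAN_LC_MIX = {"3": 0.25, "2": 0.25, "1": 0.25, "0": 0.15,
                "A": 0.05, "B": 0.05, "Z": 0.0}


@pytest.fixture(scope="session")
def flat_cfg():
    return SimConfig(seed=0, coast_amplitude_km=0.0)


@pytest.fixture(scope="session")
def flat_env(flat_cfg):
    return build_environment(flat_cfg)


@pytest.fixture(scope="session")
def default_cfg():
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def default_env(default_cfg):
    return build_environment(default_cfg)


@pytest.fixture(scope="session")
def ssm_sim_cfg():
    """Two-mode simulation at the parameter-recovery settings: persistent
    migration (gamma 0.85) vs restricted inter-nesting (gamma 0.15),
    balanced switching, a large open shelf."""
    return SimConfig(
        seed=0, n_steps=200, lc_mix=dict(CLEAN_LC_MIX), fixes_per_on_window=2.5,
        mode_params=(ModeParams(gamma=0.85, step_scale_km=4.0),
                     ModeParams(gamma=0.15, step_scale_km=2.0)),
        switch_probs=((0.95, 0.05), (0.05, 0.95)),
        domain_offshore_km=400, domain_lat_span_deg=6)


@pytest.fixture(scope="session")
def ssm_sim_env(ssm_sim_cfg):
    return build_environment(ssm_sim_cfg)


def make_track(times, lons, lats, lcs=None, turtle_id="T"):
    """Build a Track from plain sequences (times as ISO strings or datetimes)."""
    ts = pd.to_datetime(list(times), utc=True)
    n = len(ts)
    fixes = pd.DataFrame({
        "timestamp": ts,
        "lon": np.asarray(lons, dtype=float),
        "lat": np.asarray(lats, dtype=float),
        "lc": list(lcs) if lcs is not None else ["3"] * n,
    })
    return Track(turtle_id=turtle_id, fixes=fixes)


@pytest.fixture
def track_factory():
    return make_track
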