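"""Monte-Carlo site-fidelity test against constrained correlated random walks.

A track shows site fidelity when its spatial spread — the mean squared
distance (r^2) of relocations about their mean centre — is smaller than
expected under random walks built from the track's own steps: each
replicate re-uses the observed step lengths and turning angles in an
independently shuffled order, starts at the observed start point, and is
constrained to the shallow-shelf region (ocean within the 100-m isobath
plus a 1-km coastal buffer). With 100 replicates, fidelity is declared when
the fraction of replicates with r^2 at or above the observed value exceeds
0.95 — i.e. at least 96 of 100 random walks spread more than the turtle did.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .config import AnalysisParameters
from .environment import Environment
from .geometry import LambertAzimuthalEqualArea


class ConstraintError(RuntimeError):
    pass


@dataclass
class FidelityResult:
    turtle_id: str
    period_id: str
    r2_observed_km2: float
    r2_replicates_km2: np.ndarray
    p: float                      # fraction of replicates with r2 >= observed
    fidelity: bool
    n_redraws: int = 0
    n_restarts: int = 0


def msd_statistic(xy: np.ndarray) -> float:
    """Mean squared distance (km^2) of relocations about their mean centre."""
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 3:
        raise ValueError("need at least 3 relocations")
    c = xy.mean(axis=0)
    return float(np.mean(np.sum((xy - c) ** 2, axis=1)))


def msd_successive(xy: np.ndarray) -> float:
    """Alternative statistic: mean squared successive displacement (km^2)."""
    xy = np.asarray(xy, dtype=float)
    d = np.diff(xy, axis=0)
    return float(np.mean(np.sum(d ** 2, axis=1)))


def _steps_polar(xy: np.ndarray):
    """Step lengths and turning angles of a planar path."""
    d = np.diff(xy, axis=0)
    lengths = np.hypot(d[:, 0], d[:, 1])
    headings = np.arctan2(d[:, 1], d[:, 0])
    turns = np.diff(headings)
    turns = (turns + np.pi) % (2 * np.pi) - np.pi
    return lengths, turns, headings[0]


def _build_path(start, heading0, lengths, turns):
    headings = heading0 + np.concatenate([[0.0], np.cumsum(turns)])
    steps = lengths[:, None] * np.column_stack([np.cos(headings), np.sin(headings)])
    return start + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])


def constrained_random_walks(xy: np.ndarray, region, n: int = 100,
                             seed: int = 0, max_redraws: int = 100,
                             max_restarts: int = 10):
    """Shuffled-step correlated random walks confined to a region.

    ``xy`` is the observed path in km; ``region`` a shapely polygon in the
    same frame (None for unconstrained). Step lengths and turning angles
    are shuffled independently; the initial heading is drawn uniformly.
    A step landing outside the region has its (length, turn) pair re-drawn
    from the remaining pool up to ``max_redraws`` times, after which the
    replicate restarts (up to ``max_restarts``); exhausting restarts raises
    ``ConstraintError``. Returns (list of replicate paths, n_redraws,
    n_restarts).
    """
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 3:
        raise ValueError("need at least 3 relocations")
    start = xy[0]
    if region is not None:
        shapely.prepare(region)
        if not region.contains(shapely.Point(start)):
            raise ConstraintError("start point outside constraint region")
    lengths, turns, _ = _steps_polar(xy)
    n_steps = len(lengths)
    n_turns = len(turns)
    rng = np.random.default_rng(seed)
    reps, total_redraws, total_restarts = [], 0, 0

    for _ in range(n):
        for attempt in range(max_restarts + 1):
            Ls = rng.permutation(lengths)
            Ts = rng.permutation(turns)
            heading = rng.uniform(-np.pi, np.pi)
            path = np.empty((n_steps + 1, 2))
            path[0] = start
            ok = True
            ti = 0
            for i in range(n_steps):
                placed = False
                for _try in range(max_redraws):
                    turn = 0.0 if i == 0 else Ts[min(ti, n_turns - 1)]
                    cand_heading = heading + turn
                    cand = path[i] + Ls[i] * np.array([np.cos(cand_heading),
                                                       np.sin(cand_heading)])
                    if region is None or region.contains(shapely.Point(cand)):
                        path[i + 1] = cand
                        heading = cand_heading
                        placed = True
                        if i > 0:
                            ti += 1
                        break
                    total_redraws += 1
                    # re-draw: swap in another (length, turn) pair from the pool
                    j = rng.integers(i, n_steps)
                    Ls[i], Ls[j] = Ls[j], Ls[i]
                    if i > 0 and n_turns > ti:
                        k = rng.integers(ti, n_turns)
                        Ts[ti], Ts[k] = Ts[k], Ts[ti]
                if not placed:
                    ok = False
                    break
            if ok:
                reps.append(path)
                break
            total_restarts += 1
        else:
            raise ConstraintError(
                f"replicate failed after {max_restarts} restarts; region too tight")
    return reps, total_redraws, total_restarts


def fidelity_test(lon, lat, env: Environment | None = None,
                  params: AnalysisParameters = AnalysisParameters(),
                  turtle_id: str = "", period_id: str = "",
                  seed: int = 0, statistic=msd_statistic,
                  max_redraws: int = 100, max_restarts: int = 10) -> FidelityResult:
    """Monte-Carlo site-fidelity test for one inter-nesting track.

    Coordinates are projected to a local equal-area frame (or the
    environment's frame when an Environment with its shallow-shelf
    constraint region is supplied); p is the fraction of replicate random
    walks whose r^2 meets or exceeds the observed r^2, ties counting toward
    the null.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if env is not None:
        x, y = env.to_xy(lon, lat)
        region = env.isobath_region
    else:
        proj = LambertAzimuthalEqualArea(float(np.mean(lon)), float(np.mean(lat)))
        x, y = proj.forward(lon, lat)
        region = None
    xy = np.column_stack([x, y])
    r2_obs = statistic(xy)
    reps, n_redraws, n_restarts = constrained_random_walks(
        xy, region, n=params.fidelity_nreps, seed=seed,
        max_redraws=max_redraws, max_restarts=max_restarts)
    r2_reps = np.array([statistic(p) for p in reps])
    p = float(np.mean(r2_reps >= r2_obs))
    return FidelityResult(turtle_id, period_id, r2_obs, r2_reps, p,
                          fidelity=p > params.fidelity_p,
                          n_redraws=n_redraws, n_restarts=n_restarts)
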