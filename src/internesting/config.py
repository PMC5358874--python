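"""Configuration objects: analysis thresholds, simulation settings, MCMC settings.

``AnalysisParameters`` gathers every numeric rule the pipeline applies
(filter thresholds, eligibility rules, buffer radii, season dates) so that a
study's conventions live in one auditable place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np

LOCATION_CLASSES = ("3", "2", "1", "0", "A", "B", "Z")

#: Nominal Argos one-sigma positional accuracy per location class, km.
#: LC Z positions carry no usable accuracy estimate.
DEFAULT_LC_ERROR_KM = {
    "3": 0.25, "2": 0.5, "1": 1.5, "0": 5.0, "A": 8.0, "B": 15.0, "Z": 30.0,
}

#: Empirically plausible mix of location classes for a nearshore marine tag.
DEFAULT_LC_MIX = {
    "3": 0.08, "2": 0.12, "1": 0.18, "0": 0.14, "A": 0.20, "B": 0.24, "Z": 0.04,
}


@dataclass(frozen=True)
class AnalysisParameters:
    """Numeric conventions of the inter-nesting analysis.

    Defaults follow the published Kemp's ridley study design: swim-speed
    cap 5 km/h, biologically plausible depth cap 100 m, 1-km inland
    tolerance for Argos error, 25-degree turning-angle display filter,
    13.5-km nest-site-fidelity rule, 15-km platform buffer, 10-km occupancy
    cells, alpha-hull pruning factor 1.5, >= 20 daily locations for KDE,
    SD-ratio rescale band (0.5, 2), 100 random-walk replicates with the
    p > 0.95 fidelity rule, 8-h state grid, 31 August season end and the
    29 June default inter-nesting end for tracks that never depart.
    """

    max_speed_kmh: float = 5.0
    max_depth_m: float = 100.0
    land_buffer_km: float = 1.0
    min_turn_angle_deg: float = 25.0
    nest_fidelity_km: float = 13.5
    platform_buffer_km: float = 15.0
    grid_cell_km: float = 10.0
    alpha: float = 1.5
    kde_min_days: int = 20
    sd_ratio_bounds: tuple[float, float] = (0.5, 2.0)
    fidelity_nreps: int = 100
    fidelity_p: float = 0.95
    ssm_step_hours: float = 8.0
    season_end_month_day: tuple[int, int] = (8, 31)
    default_internest_end_month_day: tuple[int, int] = (6, 29)
    earth_radius_km: float = 6371.0
    mcp_min_points: int = 5
    # heuristic departure detector: sustained directional movement, made explicit
    departure_net_km: float = 50.0
    departure_consecutive_days: int = 3
    departure_rate_min_kmday: float = 5.0
    nesting_site_radius_km: float = 50.0

    def __post_init__(self):
        for name in ("max_speed_kmh", "max_depth_m", "land_buffer_km",
                     "min_turn_angle_deg", "nest_fidelity_km",
                     "platform_buffer_km", "grid_cell_km", "alpha",
                     "ssm_step_hours", "earth_radius_km"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.sd_ratio_bounds
        if not (lo < 1.0 < hi):
            raise ValueError("sd_ratio_bounds must bracket 1")

    def season_end(self, year: int) -> date:
        return date(year, *self.season_end_month_day)

    def default_internest_end(self, year: int) -> date:
        return date(year, *self.default_internest_end_month_day)


@dataclass(frozen=True)
class ModeParams:
    """Per-mode correlated-random-walk settings.

    gamma is the move persistence (autocorrelation of successive step
    vectors) in [0, 1]; theta the mean turn per step in radians;
    step_scale_km the process noise scale per 8-h step.
    """

    gamma: float
    theta: float = 0.0
    step_scale_km: float = 2.0

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.step_scale_km <= 0:
            raise ValueError("step_scale_km must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Settings for the synthetic world and turtle cohort.

    Modes are indexed 0 = migration (directed, persistent) and
    1 = inter-nesting (restricted). ``switch_probs`` is the row-stochastic
    mode transition matrix per 8-h step. The Argos emulation draws each
    fix's location class from ``lc_mix`` and adds isotropic error with the
    class's scale; fixes only occur inside duty-cycle on-windows
    (default 6 h on / 6 h off).
    """

    seed: int = 0
    n_turtles: int = 5
    start_date: date = date(2011, 4, 15)
    n_steps: int = 180                       # 8-h steps (= 60 days)
    mode_params: tuple[ModeParams, ModeParams] = (
        ModeParams(gamma=0.85, theta=0.0, step_scale_km=4.0),   # migration
        ModeParams(gamma=0.15, theta=0.0, step_scale_km=2.0),   # inter-nesting
    )
    switch_probs: tuple[tuple[float, float], tuple[float, float]] = (
        (0.95, 0.05),
        (0.025, 0.975),
    )
    start_mode: int = 1
    lc_mix: dict = field(default_factory=lambda: dict(DEFAULT_LC_MIX))
    lc_error_km: dict = field(default_factory=lambda: dict(DEFAULT_LC_ERROR_KM))
    duty_on_hours: float = 6.0
    duty_off_hours: float = 6.0
    fixes_per_on_window: float = 2.0
    step_hours: float = 8.0
    # environment geometry
    shelf_slope_m_per_km: float = 2.0
    coast_amplitude_km: float = 8.0
    coast_wavelength_km: float = 120.0
    domain_lat_span_deg: float = 3.0
    domain_offshore_km: float = 120.0
    raster_cell_km: float = 1.0
    center_lon: float = -97.0
    center_lat: float = 24.5
    deploy_offshore_km: float = 8.0
    nest_shore_km: float = 3.0
    nest_day_offsets: tuple = (0, 25, 50)
    max_redraws: int = 200
    # threat layers
    n_platforms: int = 40
    platform_removed_frac: float = 0.3
    effort_tile_km: float = 30.0

    def __post_init__(self):
        sp = np.asarray(self.switch_probs, dtype=float)
        if sp.shape != (2, 2) or np.any(sp < 0) or np.any(np.abs(sp.sum(axis=1) - 1) > 1e-12):
            raise ValueError("switch_probs must be 2x2 row-stochastic")
        mix = np.array([self.lc_mix.get(lc, 0.0) for lc in LOCATION_CLASSES])
        if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-12:
            raise ValueError("lc_mix must be a probability distribution over LCs")
        for lc, scale in self.lc_error_km.items():
            if scale < 0:
                raise ValueError(f"lc_error_km[{lc}] must be >= 0")
        if self.shelf_slope_m_per_km <= 0 or self.domain_offshore_km <= 0:
            raise ValueError("invalid shelf slope or extent")
        if self.start_mode not in (0, 1):
            raise ValueError("start_mode must be 0 (migration) or 1 (internesting)")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class McmcConfig:
    """MCMC settings for the switching-state-space fit.

    Defaults mirror the study design: two independent chains, posterior
    samples from 10,000 iterations after a 7,000-iteration burn-in,
    thinned by five.
    """

    n_chains: int = 2
    n_iter: int = 10_000
    burn_in: int = 7_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.burn_in + self.n_iter:
            raise ValueError("n_iter must be positive")
        if self.thin < 1 or self.n_chains < 1 or self.n_iter < 1:
            raise ValueError("invalid MCMC configuration")
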