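"""Inter-nesting period extraction.

An inter-nesting period is a maximal run of consecutive inter-nesting
locations not interrupted by another behavioural mode, confined to the
nesting season (ending 31 August). Tracks with a successful state-space fit
are segmented from the fitted mode labels; tracks without one fall back to
a heuristic: the period runs from the first valid fix to the last fix
before sustained directional movement away from the nesting area, with a
29 June default end for tracks that never leave the tagging site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .config import AnalysisParameters
from .geometry import haversine_km
from .tracks import Track


@dataclass
class InterNestingPeriod:
    """One contiguous inter-nesting segment of a track."""

    turtle_id: str
    start_date: date
    end_date: date
    method: str                      # ssm | heuristic | default_end
    fixes: pd.DataFrame
    period_index: int = 0
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.start_date > self.end_date:
            raise ValueError("period start after end")

    @property
    def n_days(self) -> int:
        """Inclusive calendar-day count (UTC dates)."""
        return (self.end_date - self.start_date).days + 1

    @property
    def period_id(self) -> str:
        return f"{self.turtle_id}-P{self.period_index + 1}"


def _utc_dates(fixes: pd.DataFrame) -> pd.Series:
    return fixes["timestamp"].dt.date


def truncate_season(obj, params: AnalysisParameters = AnalysisParameters()):
    """Drop fixes after the 31 August season end (inclusive retention).

    Accepts a Track or an InterNestingPeriod; the season year is the year
    of the first fix.
    """
    fixes = obj.fixes
    if len(fixes) == 0:
        return obj
    year = fixes["timestamp"].iloc[0].year
    end = params.season_end(year)
    keep = _utc_dates(fixes) <= end
    if isinstance(obj, InterNestingPeriod):
        out_fixes = fixes[keep].reset_index(drop=True)
        if len(out_fixes) == 0:
            raise ValueError("season truncation removed every fix in period")
        return InterNestingPeriod(obj.turtle_id, obj.start_date,
                                  min(obj.end_date, end), obj.method,
                                  out_fixes, obj.period_index, obj.flags)
    return obj.with_fixes(fixes[keep])


def extract_periods_ssm(track: Track,
                        params: AnalysisParameters = AnalysisParameters()
                        ) -> list[InterNestingPeriod]:
    """Segment a mode-labeled track into inter-nesting periods.

    Maximal runs of inter-nesting-labeled fixes become periods; a final
    inter-nesting run that follows the last migration bout *and* sits away
    from the deployment site (no return toward the nesting region) is
    excluded as foraging. Fixes after the season end are dropped first.
    """
    if "mode" not in track.fixes.columns:
        raise ValueError("track has no mode labels; fit the SSM first")
    track = truncate_season(track, params)
    fixes = track.fixes
    if len(fixes) == 0:
        return []
    is_in = (fixes["mode"] == "internesting").to_numpy()
    # run-length encode
    change = np.flatnonzero(np.diff(is_in.astype(int)) != 0) + 1
    bounds = np.concatenate([[0], change, [len(fixes)]])
    runs = [(bounds[i], bounds[i + 1], is_in[bounds[i]])
            for i in range(len(bounds) - 1)]

    in_runs = [(a, b) for a, b, v in runs if v]
    if not in_runs:
        return []

    # foraging exclusion: last inter-nesting run, preceded by migration,
    # with its median location far from the deployment site
    dep_lon, dep_lat = fixes["lon"].iloc[0], fixes["lat"].iloc[0]
    a, b = in_runs[-1]
    if a > 0:
        seg = fixes.iloc[a:b]
        med_d = haversine_km(dep_lon, dep_lat,
                             float(seg["lon"].median()), float(seg["lat"].median()))
        if med_d > params.nesting_site_radius_km:
            in_runs = in_runs[:-1]

    periods = []
    for k, (a, b) in enumerate(in_runs):
        seg = fixes.iloc[a:b].reset_index(drop=True)
        dates = _utc_dates(seg)
        periods.append(InterNestingPeriod(
            turtle_id=track.turtle_id, start_date=dates.iloc[0],
            end_date=dates.iloc[-1], method="ssm", fixes=seg, period_index=k))
    return periods


def detect_departure_day(track: Track,
                         params: AnalysisParameters = AnalysisParameters()):
    """First day of sustained directional movement away from the deployment site.

    Daily mean net displacement from the deployment site is scanned for the
    first day exceeding ``departure_net_km`` at the end of a run of at least
    ``departure_consecutive_days`` strictly increasing days. The departure
    day is then found by backtracking from that crossing through days whose
    displacement increment is at least ``departure_rate_min_kmday`` (a
    migration-like rate, distinguishing true departure from slow
    pre-departure wandering). Returns a date or None.
    """
    fixes = track.fixes
    if len(fixes) < 2:
        return None
    dep_lon, dep_lat = fixes["lon"].iloc[0], fixes["lat"].iloc[0]
    df = pd.DataFrame({
        "date": _utc_dates(fixes),
        "r": haversine_km(dep_lon, dep_lat, fixes["lon"], fixes["lat"]),
    })
    daily = df.groupby("date")["r"].mean()
    r = daily.to_numpy()
    days = list(daily.index)
    inc = 0
    for i in range(1, len(r)):
        inc = inc + 1 if r[i] > r[i - 1] else 0
        if r[i] > params.departure_net_km and inc >= params.departure_consecutive_days:
            j = i
            while j > 1 and r[j - 1] - r[j - 2] >= params.departure_rate_min_kmday:
                j -= 1
            return days[j]
    return None


def extract_period_heuristic(track: Track,
                             params: AnalysisParameters = AnalysisParameters()
                             ) -> InterNestingPeriod:
    """Fallback segmentation for tracks without a successful state-space fit.

    The period starts at the first valid fix. If a departure is detected,
    it ends on the last fix date before the departure day; if the turtle
    never departs and every fix stays within the nesting-site radius, the
    29 June default end applies; otherwise it ends at the last fix.
    """
    track = truncate_season(track, params)
    fixes = track.fixes
    if len(fixes) == 0:
        raise ValueError("empty track after season truncation")
    dates = _utc_dates(fixes)
    start = dates.iloc[0]
    flags = {}
    if len(fixes) == 1:
        return InterNestingPeriod(track.turtle_id, start, start, "heuristic",
                                  fixes, flags={"single_fix": True})

    departure = detect_departure_day(track, params)
    method = "heuristic"
    if departure is not None:
        before = dates[dates < departure]
        end = before.iloc[-1] if len(before) else start
    else:
        dep_lon, dep_lat = fixes["lon"].iloc[0], fixes["lat"].iloc[0]
        r = haversine_km(dep_lon, dep_lat, fixes["lon"], fixes["lat"])
        if np.max(np.asarray(r)) <= params.nesting_site_radius_km:
            default_end = params.default_internest_end(start.year)
            if default_end >= start:
                end = default_end
                method = "default_end"
            else:
                end = dates.iloc[-1]
                flags["late_start"] = True
        else:
            end = dates.iloc[-1]
            flags["no_departure_detected"] = True

    keep = (dates >= start) & (dates <= end)
    return InterNestingPeriod(track.turtle_id, start, end, method,
                              fixes[keep].reset_index(drop=True), flags=flags)


def periods_table(periods: list[InterNestingPeriod]) -> pd.DataFrame:
    rows = [{"turtle_id": p.turtle_id, "period_id": p.period_id,
             "start": p.start_date.isoformat(), "end": p.end_date.isoformat(),
             "method": p.method, "n_days": p.n_days, "n_fixes": len(p.fixes)}
            for p in periods]
    return pd.DataFrame(rows, columns=["turtle_id", "period_id", "start", "end",
                                       "method", "n_days", "n_fixes"])
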