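"""Coastal meteorology: solar geometry, sea-breeze day classification, and
wind recirculation.

Sea-breeze (SB) days are identified from surface winds and land-sea thermal
contrast with the four-criterion surface filter:

(a) offshore or calm wind for the majority of hours from six hours before
    sunrise to two hours after sunrise (the nocturnal land-breeze phase);
(b) at least two consecutive onshore hours between two hours after sunrise
    and two hours after sunset (the onshore reversal);
(c) offshore or calm wind for the majority of hours in the post-breeze
    evening window (default: two to eight hours after sunset);
(d) daytime (sunrise-to-sunset) mean land temperature exceeding the daily
    sea-surface temperature by more than 3 degC (thermal forcing).

The recirculation factor RF compares net vector displacement with total wind
run over a daytime window: RF = 1 - sqrt(X^2 + Y^2) / WR with
X = T*sum(u_i), Y = T*sum(v_i) and WR = T*sum(sqrt(u_i^2 + v_i^2)).
RF = 0 for straight-line transport, RF = 1 for a closed loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .station_io import wind_components

__all__ = [
    "SolarTimes", "CoastGeometry", "SeaBreezeDay", "RecirculationResult",
    "solar_times", "classify_sea_breeze_day", "sb_penetration",
    "recirculation_factor", "in_sector",
]


@dataclass(frozen=True)
class SolarTimes:
    """Local sunrise/sunset for one date (minutes resolution)."""

    date: Date
    sunrise: datetime
    sunset: datetime

    def __post_init__(self) -> None:
        if not self.sunrise < self.sunset:
            raise ValueError("sunrise must precede sunset")


def solar_times(lat: float, lon: float, date: Date, utc_offset: float) -> SolarTimes:
    """Sunrise and sunset in local time from solar declination and hour angle.

    Uses the standard low-precision solar-position equations (Fourier series
    in fractional year for declination and the equation of time) with the
    -0.833 deg altitude convention for atmospheric refraction and the solar
    disc radius. Accurate to about +-3 minutes, which is immaterial to hourly
    wind criteria. Raises for polar day/night (|lat| >= 66 is rejected
    upstream of the hour-angle singularity).
    """
    if abs(lat) >= 66.0:
        raise ValueError("solar_times is limited to |lat| < 66 degrees")
    doy = date.timetuple().tm_yday
    # fractional year (radians), evaluated at local noon
    gamma = 2.0 * math.pi / 365.0 * (doy - 1 + (12.0 - 12.0) / 24.0)
    eqtime = 229.18 * (0.000075 + 0.001868 * math.cos(gamma)
                       - 0.032077 * math.sin(gamma)
                       - 0.014615 * math.cos(2 * gamma)
                       - 0.040849 * math.sin(2 * gamma))  # minutes
    decl = (0.006918 - 0.399912 * math.cos(gamma) + 0.070257 * math.sin(gamma)
            - 0.006758 * math.cos(2 * gamma) + 0.000907 * math.sin(2 * gamma)
            - 0.002697 * math.cos(3 * gamma) + 0.00148 * math.sin(3 * gamma))
    lat_r = math.radians(lat)
    zenith = math.radians(90.833)
    cos_ha = (math.cos(zenith) / (math.cos(lat_r) * math.cos(decl))
              - math.tan(lat_r) * math.tan(decl))
    if not -1.0 < cos_ha < 1.0:
        raise ValueError(f"polar day or night at lat {lat} on {date}")
    ha = math.degrees(math.acos(cos_ha))
    sunrise_utc_min = 720.0 - 4.0 * (lon + ha) - eqtime
    sunset_utc_min = 720.0 - 4.0 * (lon - ha) - eqtime
    base = datetime(date.year, date.month, date.day)
    off = utc_offset * 60.0
    sunrise = base + timedelta(minutes=round(sunrise_utc_min + off))
    sunset = base + timedelta(minutes=round(sunset_utc_min + off))
    return SolarTimes(date, sunrise, sunset)


@dataclass(frozen=True)
class CoastGeometry:
    """Wind-direction sectors defined by the coastline orientation.

    Sectors are half-open intervals ``[lo, hi)`` of wind-FROM directions in
    degrees, wrapping through north when ``lo > hi``. ``coast_normal_deg`` is
    the compass bearing pointing inland (the direction onshore air moves
    toward). Defaults suit a coastline to the south of the city: onshore wind
    blows from the sea sector 135-255 deg, offshore from the land sector
    315-75 deg; sectors were chosen subjectively from the coastline direction
    and are fully configurable.
    """

    onshore_sector: tuple[float, float] = (135.0, 255.0)
    offshore_sector: tuple[float, float] = (315.0, 75.0)
    coast_normal_deg: float = 15.0
    calm_ms: float = 0.5

    def __post_init__(self) -> None:
        for d in np.arange(0.0, 360.0, 1.0):
            if in_sector(d, self.onshore_sector) and in_sector(d, self.offshore_sector):
                raise ValueError("onshore and offshore sectors overlap")


def in_sector(wd: float, sector: tuple[float, float]) -> bool:
    """Whether a wind-FROM direction lies in a half-open sector [lo, hi)."""
    lo, hi = sector
    wd = wd % 360.0
    if lo <= hi:
        return lo <= wd < hi
    return wd >= lo or wd < hi


@dataclass
class SeaBreezeDay:
    """Per-day sea-breeze classification with criterion diagnostics."""

    date: Date
    is_sb: bool
    classifiable: bool
    criterion_a: bool | None = None
    criterion_b: bool | None = None
    criterion_c: bool | None = None
    criterion_d: bool | None = None
    onset: datetime | None = None
    end: datetime | None = None
    duration_h: float | None = None
    penetration_km: float | None = None
    delta_t: float | None = None


@dataclass
class RecirculationResult:
    """Daytime wind-run budget: net displacement vs total run, in km."""

    date: Date
    X: float | None
    Y: float | None
    wind_run: float | None
    rf: float | None
    n_hours: int
    T: float = 1.0


def _window_hours(df: pd.DataFrame, t0: datetime, t1: datetime) -> pd.DataFrame:
    """Hourly samples with timestamps in [t0, t1] inclusive."""
    return df[(df.index >= t0) & (df.index <= t1)]


def _expected_hours(t0: datetime, t1: datetime) -> int:
    first = pd.Timestamp(t0).ceil("h")
    last = pd.Timestamp(t1).floor("h")
    return max(0, int((last - first) / pd.Timedelta("1h")) + 1)


def _onshore_runs(sub: pd.DataFrame, geom: CoastGeometry) -> list[pd.DatetimeIndex]:
    """Maximal runs of consecutive valid onshore hours within a window."""
    runs: list[list[pd.Timestamp]] = []
    current: list[pd.Timestamp] = []
    prev = None
    for ts, row in sub.iterrows():
        onshore = (np.isfinite(row["ws"]) and np.isfinite(row["wd"])
                   and row["ws"] >= geom.calm_ms
                   and in_sector(row["wd"], geom.onshore_sector))
        contiguous = prev is not None and (ts - prev) == pd.Timedelta("1h")
        if onshore:
            if current and contiguous:
                current.append(ts)
            else:
                if current:
                    runs.append(current)
                current = [ts]
        else:
            if current:
                runs.append(current)
            current = []
        prev = ts
    if current:
        runs.append(current)
    return [pd.DatetimeIndex(r) for r in runs]


def classify_sea_breeze_day(winds: pd.DataFrame,
                            land_temp: pd.Series,
                            sst: float,
                            geom: CoastGeometry,
                            sun: SolarTimes,
                            criterion_c_window: tuple[float, float] = (2.0, 8.0),
                            min_valid_fraction: float = 0.75) -> SeaBreezeDay:
    """Classify one day against the four sea-breeze criteria.

    ``winds`` is an hourly frame with columns ``ws`` and ``wd`` covering the
    criterion windows (which extend before sunrise and past midnight);
    ``land_temp`` is the hourly land temperature, ``sst`` the day's sea
    surface temperature. "Majority" is strictly more than half of the valid
    hours; calm is ``ws`` below the configured threshold. A day with fewer
    than ``min_valid_fraction`` valid wind hours in any criterion window is
    unclassifiable. The onshore run reported is the longest consecutive run
    in the criterion (b) window (first on ties).
    """
    sr, ss = sun.sunrise, sun.sunset
    h = pd.Timedelta("1h")

    def offshore_or_calm_majority(t0, t1):
        sub = _window_hours(winds, t0, t1)
        ok = sub["ws"].notna() & sub["wd"].notna()
        n_expected = _expected_hours(t0, t1)
        if n_expected == 0 or ok.sum() < min_valid_fraction * n_expected:
            return None
        calm = sub["ws"] < geom.calm_ms
        off = sub["wd"].map(lambda d: in_sector(d, geom.offshore_sector))
        good = (ok & (calm | off)).sum()
        return bool(good > ok.sum() / 2.0)

    crit_a = offshore_or_calm_majority(sr - 6 * h, sr + 2 * h)
    crit_c = offshore_or_calm_majority(ss + criterion_c_window[0] * h,
                                       ss + criterion_c_window[1] * h)

    b0, b1 = sr + 2 * h, ss + 2 * h
    sub_b = _window_hours(winds, b0, b1)
    ok_b = sub_b["ws"].notna() & sub_b["wd"].notna()
    n_exp_b = _expected_hours(b0, b1)
    if n_exp_b == 0 or ok_b.sum() < min_valid_fraction * n_exp_b:
        crit_b = None
        runs = []
    else:
        runs = _onshore_runs(sub_b[ok_b], geom)
        crit_b = any(len(r) >= 2 for r in runs)

    t_sub = land_temp[(land_temp.index >= sr) & (land_temp.index <= ss)]
    n_exp_t = _expected_hours(sr, ss)
    if (np.isnan(sst) or n_exp_t == 0
            or t_sub.notna().sum() < min_valid_fraction * n_exp_t):
        crit_d = None
        delta_t = None
    else:
        delta_t = float(t_sub.mean() - sst)
        crit_d = bool(delta_t > 3.0)

    classifiable = None not in (crit_a, crit_b, crit_c, crit_d)
    result = SeaBreezeDay(date=sun.date,
                          is_sb=bool(classifiable and crit_a and crit_b
                                     and crit_c and crit_d),
                          classifiable=classifiable,
                          criterion_a=crit_a, criterion_b=crit_b,
                          criterion_c=crit_c, criterion_d=crit_d,
                          delta_t=delta_t)
    if runs:
        longest = max(runs, key=len)
        if len(longest) >= 2:
            result.onset = longest[0].to_pydatetime()
            result.end = longest[-1].to_pydatetime()
            result.duration_h = float(len(longest))
            run_winds = winds.loc[longest]
            result.penetration_km = sb_penetration(run_winds,
                                                   geom.coast_normal_deg)
    return result


def sb_penetration(run_winds: pd.DataFrame, coast_normal_deg: float) -> float:
    """Inland penetration of an onshore run, km.

    Cumulative displacement of the hourly wind vectors projected on the
    inland-pointing coast normal (negative projections contribute zero):
    ``sum(max(0, u*sin(n) + v*cos(n)) * 3600 / 1000)``.
    """
    u, v = wind_components(run_winds["ws"], run_winds["wd"])
    rad = math.radians(coast_normal_deg)
    proj = u * math.sin(rad) + v * math.cos(rad)
    proj = proj.clip(lower=0.0)
    return float(proj.sum() * 3.6)


def recirculation_factor(winds: pd.DataFrame,
                         date: Date,
                         window: tuple[int, int] = (10, 18),
                         T: float = 1.0,
                         min_valid_fraction: float = 0.75) -> RecirculationResult:
    """Daytime recirculation factor for one day.

    Over the local hours ``window`` (inclusive; default 10:00-18:00, nine
    hourly samples): X = T*sum(u_i), Y = T*sum(v_i), WR = T*sum(|V_i|), all
    in km, and RF = 1 - sqrt(X^2+Y^2)/WR. RF is absent when fewer than
    ``min_valid_fraction`` of window hours are valid or the wind run is zero.
    """
    day = pd.Timestamp(date)
    t0 = day + pd.Timedelta(hours=window[0])
    t1 = day + pd.Timedelta(hours=window[1])
    sub = _window_hours(winds, t0, t1)
    ok = sub["ws"].notna() & sub["wd"].notna()
    n_expected = window[1] - window[0] + 1
    n = int(ok.sum())
    if n < min_valid_fraction * n_expected:
        return RecirculationResult(date, None, None, None, None, n, T)
    u, v = wind_components(sub.loc[ok, "ws"], sub.loc[ok, "wd"])
    # m/s over T hours -> km: * 3600 * T / 1000
    x = float(u.sum()) * 3.6 * T
    y = float(v.sum()) * 3.6 * T
    wr = float(np.hypot(u, v).sum()) * 3.6 * T
    if wr == 0.0:
        return RecirculationResult(date, x, y, wr, None, n, T)
    rf = 1.0 - math.hypot(x, y) / wr
    rf = min(max(rf, 0.0), 1.0)  # guard FP round-off at the bounds
    return RecirculationResult(date, x, y, wr, rf, n, T)
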