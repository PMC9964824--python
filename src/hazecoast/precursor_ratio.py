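"""Secondary-aerosol screening via CO-normalized precursor ratios.

CO is a near-inert tracer of primary combustion emissions, so normalizing
PM2.5 and its gaseous precursors by CO removes much of the common dilution
and emission-strength signal. On days when photochemical conversion of gas
to particle matters, PM2.5/CO rises while NOx/CO and/or SO2/CO fall (the
precursors are consumed into nitrate and sulfate). An episode is therefore
flagged as potentially secondary-aerosol affected when its mean PM2.5/CO
exceeds the same-season clean-day baseline AND at least one precursor ratio
falls below it; which precursor(s) fall determines the category
(sulfate+nitrate, nitrate-only, sulfate-only).

Daily ratios use daytime hours only (default 06-18 LT) and are ratios of
daytime means (not means of hourly ratios), which is robust to hour-level
CO noise. All inequalities are strict; a tie is "no change".
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date

import numpy as np
import pandas as pd

from .haze_detection import HazeCalendar, HazeEpisode

__all__ = [
    "RatioDay", "RatioMeans", "RatioComparison", "daytime_ratio",
    "season_year", "season_clean_baseline", "compare_ratio_means",
    "compare_episode_ratios",
]

RATIO_VARS = ("pm25_co", "nox_co", "so2_co")


@dataclass(frozen=True)
class RatioDay:
    """One day's daytime CO-normalized ratios for the reference station.

    Units: pm25_co in ug m-3 per ppm; nox_co and so2_co in ppb per ppm.
    Individual ratios may be absent (None) when the numerator has too few
    valid hours; the day is invalid when CO itself is unusable.
    """

    date: Date
    pm25_co: float | None
    nox_co: float | None
    so2_co: float | None
    valid: bool


@dataclass(frozen=True)
class RatioMeans:
    """Mean ratios over a set of days (clean baseline or episodic)."""

    pm25_co: float | None
    nox_co: float | None
    so2_co: float | None
    n_days: int = 0


@dataclass(frozen=True)
class RatioComparison:
    """Episode-vs-clean ratio comparison and the resulting screening call."""

    episode_id: int
    season_year: int
    clean: RatioMeans
    episodic: RatioMeans
    pm_up: bool
    nox_down: bool
    so2_down: bool
    secondary_flag: bool
    category: str  # sulfate+nitrate | nitrate-only | sulfate-only | none


def daytime_ratio(data: pd.DataFrame, date: Date,
                  window: tuple[int, int] = (6, 18),
                  min_valid_fraction: float = 0.75) -> RatioDay:
    """Daytime CO-normalized ratios for one day.

    ``data`` is the reference station's hourly frame with pm25, nox, so2 and
    co columns. Each ratio is (daytime mean of numerator) / (daytime mean of
    CO) over the inclusive local-hour window. A pollutant with fewer than
    ``min_valid_fraction`` valid window hours yields an absent ratio; an
    unusable CO mean (too few hours, or <= 0) invalidates the day.
    """
    day = pd.Timestamp(date)
    t0 = day + pd.Timedelta(hours=window[0])
    t1 = day + pd.Timedelta(hours=window[1])
    sub = data[(data.index >= t0) & (data.index <= t1)]
    n_expected = window[1] - window[0] + 1

    def day_mean(var):
        if var not in sub.columns:
            return None
        col = sub[var]
        if col.notna().sum() < min_valid_fraction * n_expected:
            return None
        return float(col.mean())

    co = day_mean("co")
    if co is None or co <= 0:
        return RatioDay(date, None, None, None, valid=False)

    def ratio(var):
        m = day_mean(var)
        return None if m is None else m / co

    return RatioDay(date, ratio("pm25"), ratio("nox"), ratio("so2"), valid=True)


def season_year(date: Date) -> int:
    """Season year of a date: November and December belong to the next year.

    The season year N spans November of calendar year N-1 through October of
    calendar year N, so the DJF winter of season year 2020 is December 2019
    through February 2020.
    """
    return date.year + 1 if date.month >= 11 else date.year


def _djf_dates_of_season(sy: int) -> pd.DatetimeIndex:
    feb_end = pd.Timestamp(f"{sy}-03-01") - pd.Timedelta(days=1)
    return pd.date_range(f"{sy - 1}-12-01", feb_end, freq="D")


def season_clean_baseline(ratio_days: dict[Date, RatioDay],
                          haze_cal: HazeCalendar,
                          sy: int,
                          excluded_days: set[Date] | None = None,
                          min_clean_days: int = 10) -> RatioMeans:
    """Mean ratios over the DJF clean days of one season year.

    Clean days are DJF days of the season year that are neither haze days
    nor episode days (``excluded_days`` should carry bridged episode days).
    Requires at least ``min_clean_days`` valid clean days.
    """
    excluded = set(excluded_days or ())
    haze = set(haze_cal.haze_dates)
    djf = {t.date() for t in _djf_dates_of_season(sy)}
    pool = [ratio_days[d] for d in sorted(djf)
            if d in ratio_days and ratio_days[d].valid
            and d not in haze and d not in excluded]
    if len(pool) < min_clean_days:
        raise ValueError(
            f"season year {sy}: only {len(pool)} valid clean days "
            f"(need >= {min_clean_days})")

    def mean_of(attr):
        vals = [getattr(r, attr) for r in pool if getattr(r, attr) is not None]
        return float(np.mean(vals)) if vals else None

    return RatioMeans(mean_of("pm25_co"), mean_of("nox_co"),
                      mean_of("so2_co"), n_days=len(pool))


def compare_ratio_means(clean: RatioMeans, episodic: RatioMeans,
                        episode_id: int = 0, sy: int = 0,
                        rel_tol: float = 1e-9) -> RatioComparison:
    """Screening decision from clean vs episodic mean ratios.

    ``pm_up`` requires a strict increase of PM2.5/CO; each precursor is
    "down" only on a strict decrease (ties and absent values are no change).
    Differences within ``rel_tol`` (relative) are treated as ties so that
    floating-point round-off in otherwise identical ratios never counts as a
    change. secondary_flag = pm_up AND (nox_down OR so2_down); the category
    names the precursor(s) that fell.
    """
    def strictly_above(a, b):
        if a is None or b is None:
            return False
        return a - b > rel_tol * max(abs(a), abs(b), 1.0)

    pm_up = strictly_above(episodic.pm25_co, clean.pm25_co)
    nox_down = strictly_above(clean.nox_co, episodic.nox_co)
    so2_down = strictly_above(clean.so2_co, episodic.so2_co)
    if nox_down and so2_down:
        category = "sulfate+nitrate"
    elif nox_down:
        category = "nitrate-only"
    elif so2_down:
        category = "sulfate-only"
    else:
        category = "none"
    return RatioComparison(
        episode_id=episode_id, season_year=sy, clean=clean, episodic=episodic,
        pm_up=pm_up, nox_down=nox_down, so2_down=so2_down,
        secondary_flag=bool(pm_up and (nox_down or so2_down)),
        category=category)


def compare_episode_ratios(ep: HazeEpisode,
                           ratio_days: dict[Date, RatioDay],
                           baseline: RatioMeans) -> RatioComparison:
    """Compare an episode's mean daytime ratios against a clean baseline."""
    pool = [ratio_days[d] for d in ep.span_days()
            if d in ratio_days and ratio_days[d].valid]
    if not pool:
        raise ValueError(f"episode {ep.episode_id}: no valid ratio day")

    def mean_of(attr):
        vals = [getattr(r, attr) for r in pool if getattr(r, attr) is not None]
        return float(np.mean(vals)) if vals else None

    episodic = RatioMeans(mean_of("pm25_co"), mean_of("nox_co"),
                          mean_of("so2_co"), n_days=len(pool))
    return compare_ratio_means(baseline, episodic,
                               episode_id=ep.episode_id,
                               sy=season_year(ep.start))
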