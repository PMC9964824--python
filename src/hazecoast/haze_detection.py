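"""Haze-day identification and episode segmentation from multi-station daily PM2.5.

A haze day is a calendar day whose 24 h mean PM2.5 strictly exceeds the
threshold (default 50 ug m-3) at a minimum number of stations (default two).
Consecutive haze days form an episode; two runs separated by a short gap of
non-haze days (default at most two) are merged into one episode, with the
gap days recorded as bridged. Episode statistics (mean, sample standard
deviation and coefficient of variation of the daily cross-station mean
PM2.5) are computed over all span days including bridged days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import timedelta

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HazeCalendar", "HazeEpisode", "compute_haze_days", "segment_episodes",
    "episode_stats", "duration_frequency",
]


@dataclass
class HazeCalendar:
    """Per-date haze flags with station-count diagnostics.

    ``table`` is indexed by date with columns ``n_valid`` (stations reporting
    a valid daily PM2.5), ``n_exceed`` (stations strictly above threshold),
    ``haze`` and ``data_poor`` (fewer valid stations than ``min_stations``).
    """

    table: pd.DataFrame
    threshold: float
    min_stations: int

    @property
    def haze_dates(self) -> list[Date]:
        return [d.date() for d in self.table.index[self.table["haze"]]]


@dataclass
class HazeEpisode:
    """A contiguous date span of haze days, possibly bridging short clean gaps."""

    episode_id: int
    start: Date
    end: Date
    bridged_days: list[Date] = field(default_factory=list)
    mean_pm25: float | None = None
    sd_pm25: float | None = None
    cv_pm25: float | None = None
    type_label: str | None = None

    @property
    def duration(self) -> int:
        return (self.end - self.start).days + 1

    @property
    def haze_day_count(self) -> int:
        return self.duration - len(self.bridged_days)

    @property
    def persistent(self) -> bool:
        return self.duration > 7

    def span_days(self) -> list[Date]:
        return [self.start + timedelta(days=i) for i in range(self.duration)]


def compute_haze_days(daily_pm25: pd.DataFrame,
                      threshold: float = 50.0,
                      min_stations: int = 2) -> HazeCalendar:
    """Build the haze calendar from the dates x stations daily PM2.5 matrix.

    A date is a haze day iff at least ``min_stations`` stations report a
    valid daily mean strictly greater than ``threshold``. Dates where fewer
    than ``min_stations`` stations report at all are non-haze and flagged
    data-poor.
    """
    if daily_pm25.empty:
        raise ValueError("empty daily PM2.5 input")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_stations < 1:
        raise ValueError("min_stations must be >= 1")
    if daily_pm25.shape[1] < min_stations:
        raise ValueError(
            f"{daily_pm25.shape[1]} stations supplied, need >= {min_stations}")
    n_valid = daily_pm25.notna().sum(axis=1)
    n_exceed = (daily_pm25 > threshold).sum(axis=1)
    haze = n_exceed >= min_stations
    data_poor = n_valid < min_stations
    table = pd.DataFrame({"n_valid": n_valid, "n_exceed": n_exceed,
                          "haze": haze, "data_poor": data_poor})
    table.index = pd.DatetimeIndex(table.index)
    return HazeCalendar(table.sort_index(), threshold, min_stations)


def segment_bool(flags, max_bridge: int = 2) -> list[tuple[int, int, list[int]]]:
    """Segment a boolean haze sequence into episodes on positional indices.

    Returns ``(start, end, bridged_positions)`` triples; ``start``/``end``
    always fall on haze positions, and runs separated by a gap of at most
    ``max_bridge`` non-haze positions are merged with the gap recorded as
    bridged. The date-based :func:`segment_episodes` wraps this core.
    """
    episodes: list[tuple[int, int, list[int]]] = []
    n = len(flags)
    i = 0
    while i < n:
        if not flags[i]:
            i += 1
            continue
        start = i
        end = i
        bridged: list[int] = []
        j = i + 1
        while j < n:
            if flags[j]:
                end = j
                j += 1
                continue
            # candidate gap
            g = j
            while g < n and not flags[g]:
                g += 1
            gap_len = g - j
            if g < n and gap_len <= max_bridge:
                bridged.extend(range(j, g))
                end = g
                j = g + 1
            else:
                break
        episodes.append((start, end, bridged))
        i = end + 1
    return episodes


def segment_episodes(cal: HazeCalendar, max_bridge: int = 2) -> list[HazeEpisode]:
    """Segment the haze calendar into episodes with clean-day bridging.

    The calendar is placed on a contiguous daily grid (dates missing from the
    calendar count as non-haze), maximal runs of haze days are found, and
    runs separated by at most ``max_bridge`` non-haze days are merged.
    Episodes never start or end on a bridged day; duration counts every day
    in the span.
    """
    if max_bridge < 0:
        raise ValueError("max_bridge must be >= 0")
    if cal.table.empty:
        return []
    grid = pd.date_range(cal.table.index[0], cal.table.index[-1], freq="D")
    haze = cal.table["haze"].reindex(grid, fill_value=False).to_numpy()
    out = []
    for k, (s, e, bridged) in enumerate(segment_bool(haze, max_bridge), start=1):
        out.append(HazeEpisode(
            episode_id=k,
            start=grid[s].date(), end=grid[e].date(),
            bridged_days=[grid[b].date() for b in bridged]))
    return out


def episode_stats(ep: HazeEpisode, daily_pm25: pd.DataFrame) -> HazeEpisode:
    """Attach pollution statistics to an episode.

    The daily cross-station mean PM2.5 is taken over every span day
    (bridged days included); the episode mean, sample (n-1) standard
    deviation and coefficient of variation cv = sd/mean are computed over
    those daily means. Days with no valid station are dropped with a warning;
    a single-day episode has sd = cv = 0 by convention.
    """
    days = pd.DatetimeIndex([pd.Timestamp(d) for d in ep.span_days()])
    sub = daily_pm25.reindex(days)
    daily_mean = sub.mean(axis=1)
    missing = daily_mean.isna()
    if missing.any():
        logger.warning("episode %d: %d day(s) with no valid station PM2.5",
                       ep.episode_id, int(missing.sum()))
        daily_mean = daily_mean.dropna()
    ep.mean_pm25 = float(daily_mean.mean())
    ep.sd_pm25 = float(daily_mean.std(ddof=1)) if len(daily_mean) > 1 else 0.0
    ep.cv_pm25 = ep.sd_pm25 / ep.mean_pm25 if ep.mean_pm25 else 0.0
    return ep


def duration_frequency(episodes: list[HazeEpisode],
                       types: dict[int, str] | None = None) -> pd.DataFrame:
    """Duration-frequency table: episode counts (overall and per type) and
    mean coefficient of variation, by episode duration, plus a Total row.
    """
    types = types or {ep.episode_id: (ep.type_label or "?") for ep in episodes}
    rows = {}
    for ep in episodes:
        d = ep.duration
        row = rows.setdefault(d, {"duration": d, "n_episodes": 0,
                                  "I": 0, "II": 0, "III": 0, "IV": 0,
                                  "_cv": []})
        row["n_episodes"] += 1
        t = types.get(ep.episode_id, "?")
        if t in row:
            row[t] += 1
        if ep.cv_pm25 is not None:
            row["_cv"].append(ep.cv_pm25)
    records = []
    for d in sorted(rows):
        r = rows[d]
        cvs = r.pop("_cv")
        r["mean_cv"] = float(np.mean(cvs)) if cvs else np.nan
        records.append(r)
    df = pd.DataFrame.from_records(records)
    if df.empty:
        df = pd.DataFrame(columns=["duration", "n_episodes", "I", "II", "III",
                                   "IV", "mean_cv"])
    total = {"duration": "Total",
             "n_episodes": int(df["n_episodes"].sum()) if len(df) else 0,
             "I": int(df["I"].sum()) if len(df) else 0,
             "II": int(df["II"].sum()) if len(df) else 0,
             "III": int(df["III"].sum()) if len(df) else 0,
             "IV": int(df["IV"].sum()) if len(df) else 0,
             "mean_cv": np.nan}
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
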