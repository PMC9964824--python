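"""Meteorology-based haze-episode typing from cold-surge and sea-breeze coverage.

Each episode receives exactly one of four types from the truth table over two
influences:

=========  ===========  ===========
type       cold surge   sea breeze
=========  ===========  ===========
I          yes          no
II         no           yes
III        yes          yes
IV         no           no
=========  ===========  ===========

Cold-surge (CS) influence means at least one CS day falls in the window from
``pre_haze_window`` days before the episode start through the first
``cs_scan`` fraction of the episode (CS days can arrive a few days ahead of
the haze buildup, and in some synergistic episodes only after the sea breeze
phase starts). Sea-breeze (SB) influence means the fraction of episode days
classified as SB days reaches ``sb_fraction_threshold``. These thresholds
make an otherwise narrative classification explicit and reproducible; all
are configuration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import timedelta

import numpy as np
import pandas as pd

from .coastal_met import SeaBreezeDay
from .haze_detection import HazeEpisode

__all__ = ["TypingConfig", "EpisodeType", "classify_episode", "type_summary"]


@dataclass(frozen=True)
class TypingConfig:
    """Thresholds turning narrative influence criteria into decisions.

    ``pre_haze_window``: days before episode start scanned for CS arrival.
    ``cs_scan``: fraction of the episode (from its start) also scanned for
    CS days. ``sb_fraction_threshold``: minimum SB-day fraction for
    sea-breeze influence. ``sb_type2_threshold``: SB fraction below which a
    Type II call is annotated low-confidence ("most of the days" not met).
    """

    pre_haze_window: int = 3
    cs_scan: float = 0.5
    sb_fraction_threshold: float = 1.0 / 3.0
    sb_type2_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.pre_haze_window < 1:
            raise ValueError("pre_haze_window must be >= 1")
        for name in ("cs_scan", "sb_fraction_threshold", "sb_type2_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class EpisodeType:
    """Type assignment with the evidence that produced it."""

    episode_id: int
    type: str  # "I" | "II" | "III" | "IV"
    cs_influenced: bool
    sb_influenced: bool
    cs_days_found: list[Date] = field(default_factory=list)
    sb_day_fraction: float = 0.0
    rationale: str = ""


def _as_cs_lookup(cs_calendar) -> "callable":
    if isinstance(cs_calendar, pd.Series):
        idx = {pd.Timestamp(t).date() for t, v in cs_calendar.items() if bool(v)}
        return idx.__contains__
    if isinstance(cs_calendar, (set, frozenset, list, tuple)):
        return set(cs_calendar).__contains__
    raise TypeError("cs_calendar must be a boolean Series or a set of dates")


def classify_episode(ep: HazeEpisode,
                     cs_calendar,
                     sb_days: dict[Date, SeaBreezeDay],
                     cfg: TypingConfig | None = None) -> EpisodeType:
    """Assign one of the four haze types to an episode.

    ``cs_calendar`` is a date-indexed boolean Series (or set of CS dates);
    ``sb_days`` maps dates to per-day sea-breeze classifications. Days left
    unclassifiable by the SB detector are excluded from the SB fraction; if
    they exceed a quarter of the episode the type is still computed but a
    warning is issued.
    """
    cfg = cfg or TypingConfig()
    is_cs = _as_cs_lookup(cs_calendar)

    scan_end = ep.start + timedelta(
        days=math.ceil(ep.duration * cfg.cs_scan) - 1)
    d = ep.start - timedelta(days=cfg.pre_haze_window)
    cs_found = []
    while d <= scan_end:
        if is_cs(d):
            cs_found.append(d)
        d += timedelta(days=1)
    cs_influenced = bool(cs_found)

    span = ep.span_days()
    sb_flags = []
    n_unclassifiable = 0
    for day in span:
        sbd = sb_days.get(day)
        if sbd is None or not sbd.classifiable:
            n_unclassifiable += 1
        else:
            sb_flags.append(sbd.is_sb)
    if n_unclassifiable > 0.25 * len(span):
        warnings.warn(
            f"episode {ep.episode_id}: {n_unclassifiable}/{len(span)} days "
            "unclassifiable for sea breeze; type computed on remaining days",
            stacklevel=2)
    sb_fraction = (sum(sb_flags) / len(sb_flags)) if sb_flags else 0.0
    sb_influenced = sb_fraction >= cfg.sb_fraction_threshold

    if cs_influenced and sb_influenced:
        type_label = "III"
        why = "cold-surge day(s) in scan window and sea-breeze coverage"
    elif cs_influenced:
        type_label = "I"
        why = "cold-surge day(s) in scan window, no sea-breeze coverage"
    elif sb_influenced:
        type_label = "II"
        why = "sea-breeze coverage without cold surge"
        if sb_fraction < cfg.sb_type2_threshold:
            why += " (low confidence: sea breeze on under half of the days)"
    else:
        type_label = "IV"
        why = "neither cold-surge nor sea-breeze influence"
    return EpisodeType(episode_id=ep.episode_id, type=type_label,
                       cs_influenced=cs_influenced, sb_influenced=sb_influenced,
                       cs_days_found=cs_found, sb_day_fraction=sb_fraction,
                       rationale=why)


def type_summary(episodes: list[HazeEpisode],
                 types: dict[int, str],
                 daily_met: pd.DataFrame,
                 rf_by_date: pd.Series | None = None,
                 sb_days: dict[Date, SeaBreezeDay] | None = None,
                 clean_dates: list[Date] | None = None) -> pd.DataFrame:
    """Per-type mean +- sd of pollution and meteorology over episode days.

    ``daily_met`` is date-indexed with whatever of pm25, temp, rh, cc, gr is
    available (cross-station or reference-station daily means). RF and the
    sea-breeze duration/penetration columns are added when supplied; SB
    statistics are taken over the SB days among each group's days and are
    absent (NaN) for groups containing none. The optional ``clean_dates``
    produce a "Clean" reference column. The sd is over days, not episodes.
    """
    sb_days = sb_days or {}
    groups: dict[str, list[Date]] = {"I": [], "II": [], "III": [], "IV": []}
    for ep in episodes:
        t = types.get(ep.episode_id)
        if t in groups:
            groups[t].extend(ep.span_days())
    columns = {}
    if clean_dates is not None:
        columns["Clean"] = clean_dates
    columns.update({f"Type {k}": v for k, v in groups.items()})

    rows = {}
    for label, days in columns.items():
        idx = pd.DatetimeIndex([pd.Timestamp(d) for d in days])
        sub = daily_met.reindex(idx)
        cell = {}
        for var in daily_met.columns:
            cell[f"{var}_mean"] = float(sub[var].mean()) if len(sub) else np.nan
            cell[f"{var}_sd"] = (float(sub[var].std(ddof=1))
                                 if sub[var].notna().sum() > 1 else np.nan)
        if rf_by_date is not None:
            rf = rf_by_date.reindex(idx)
            cell["rf_mean"] = float(rf.mean()) if rf.notna().any() else np.nan
            cell["rf_sd"] = (float(rf.std(ddof=1))
                             if rf.notna().sum() > 1 else np.nan)
        sb_dur = [sb_days[d].duration_h for d in days
                  if d in sb_days and sb_days[d].is_sb
                  and sb_days[d].duration_h is not None]
        sb_pen = [sb_days[d].penetration_km for d in days
                  if d in sb_days and sb_days[d].is_sb
                  and sb_days[d].penetration_km is not None]
        cell["sb_duration_mean"] = float(np.mean(sb_dur)) if sb_dur else np.nan
        cell["sb_duration_sd"] = (float(np.std(sb_dur, ddof=1))
                                  if len(sb_dur) > 1 else np.nan)
        cell["sb_penetration_mean"] = float(np.mean(sb_pen)) if sb_pen else np.nan
        cell["sb_penetration_sd"] = (float(np.std(sb_pen, ddof=1))
                                     if len(sb_pen) > 1 else np.nan)
        cell["n_days"] = len(days)
        rows[label] = cell
    return pd.DataFrame(rows)
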