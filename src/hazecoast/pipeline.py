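"""End-to-end orchestration: from station CSVs to episode, typing and ratio tables.

The pipeline is deterministic given its inputs: read and quality-screen the
hourly stations, optionally gap-fill a target station's wind from a donor,
aggregate to daily means, detect haze days and segment episodes within the
analysis months, classify sea-breeze days and daytime recirculation on the
reference meteorology station, type each episode from the cold-surge
calendar and sea-breeze coverage, and screen episodes for secondary-aerosol
influence with the precursor-ratio method. Outputs are plain CSVs plus a
JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coastal_met import (CoastGeometry, RecirculationResult, SeaBreezeDay,
                          classify_sea_breeze_day, recirculation_factor,
                          solar_times)
from .episode_typing import TypingConfig, classify_episode, type_summary
from .haze_detection import (HazeCalendar, compute_haze_days,
                             duration_frequency, episode_stats,
                             segment_episodes)
from .precursor_ratio import (RatioComparison, compare_episode_ratios,
                              daytime_ratio, season_clean_baseline,
                              season_year)
from .station_io import (DailyTable, HourlyStationSeries, QCRanges,
                         apply_qc, daily_aggregate, daily_pm25_panel,
                         gap_fill_wind_from_donor, read_station_csv,
                         read_station_metadata_csv)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; every analyst-judgment threshold is
    explicit here with its default."""

    station_files: dict[str, str]
    stations_csv: str
    sst_csv: str
    cs_calendar_csv: str
    outdir: str = "out"
    analysis_months: tuple[int, ...] = (12, 1, 2)
    haze_threshold: float = 50.0
    min_stations: int = 2
    max_bridge: int = 2
    min_completeness: float = 0.75
    geometry: CoastGeometry = field(default_factory=CoastGeometry)
    typing: TypingConfig = field(default_factory=TypingConfig)
    met_station: str | None = None     # winds/temp for SB and RF; default: first
    ratio_station: str | None = None   # pollutant suite for ratios; default: first
    gap_fill_target: str | None = None
    gap_fill_donor: str | None = None
    ratio_window: tuple[int, int] = (6, 18)
    rf_window: tuple[int, int] = (10, 18)
    criterion_c_window: tuple[float, float] = (2.0, 8.0)
    utc_offset: float = 7.0
    seed: int = 0


def load_config(path) -> PipelineConfig:
    """Load a pipeline config from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    geom = CoastGeometry(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in raw.pop("geometry", {}).items()})
    typing_cfg = TypingConfig(**raw.pop("typing", {}))
    for key in ("analysis_months", "ratio_window", "rf_window",
                "criterion_c_window"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(geometry=geom, typing=typing_cfg, **raw)


def config_for_scenario_dir(scenario_dir, outdir=None, **overrides) -> PipelineConfig:
    """Config pointing at a directory written by ``write_scenario``."""
    d = Path(scenario_dir)
    files = {p.stem.replace("station_", ""): str(p)
             for p in sorted(d.glob("station_*.csv"))}
    return PipelineConfig(
        station_files=files,
        stations_csv=str(d / "stations.csv"),
        sst_csv=str(d / "sst.csv"),
        cs_calendar_csv=str(d / "cs_calendar.csv"),
        outdir=str(outdir if outdir is not None else d / "out"),
        **overrides)


@dataclass
class PipelineResult:
    """All stage outputs of one run."""

    stations: dict[str, HourlyStationSeries]
    daily: dict[str, DailyTable]
    panel: pd.DataFrame
    calendar: HazeCalendar
    episodes: list
    sb_days: dict[Date, SeaBreezeDay]
    rf_days: dict[Date, RecirculationResult]
    types: dict[int, str]
    type_details: dict[int, object]
    ratio_comparisons: list[RatioComparison]
    skipped_ratio_episodes: list[int]


def _read_daily_series(path, value_col) -> pd.Series:
    df = pd.read_csv(path)
    s = pd.Series(df[value_col].values,
                  index=pd.to_datetime(df["date"]))
    return s.sort_index()


def run_pipeline(cfg: PipelineConfig, write: bool = True) -> PipelineResult:
    """Run every stage; write report tables unless ``write`` is False."""
    metas = read_station_metadata_csv(cfg.stations_csv, cfg.utc_offset)
    stations: dict[str, HourlyStationSeries] = {}
    for sid, path in cfg.station_files.items():
        series = read_station_csv(path, metas[sid])
        stations[sid] = apply_qc(series, QCRanges())
    logger.info("read %d stations", len(stations))

    if cfg.gap_fill_target and cfg.gap_fill_donor:
        stations[cfg.gap_fill_target] = gap_fill_wind_from_donor(
            stations[cfg.gap_fill_target], stations[cfg.gap_fill_donor])

    daily = {sid: daily_aggregate(s, cfg.min_completeness)
             for sid, s in stations.items()}
    panel = daily_pm25_panel(daily)

    cal = compute_haze_days(panel, cfg.haze_threshold, cfg.min_stations)
    outside = ~cal.table.index.month.isin(cfg.analysis_months)
    cal.table.loc[outside, "haze"] = False
    episodes = segment_episodes(cal, cfg.max_bridge)
    episodes = [episode_stats(ep, panel) for ep in episodes]
    logger.info("%d haze days, %d episodes",
                int(cal.table["haze"].sum()), len(episodes))

    met_sid = cfg.met_station or sorted(stations)[0]
    met = stations[met_sid]
    sst = _read_daily_series(cfg.sst_csv, "sst")
    sb_days: dict[Date, SeaBreezeDay] = {}
    rf_days: dict[Date, RecirculationResult] = {}
    winds = met.data[["ws", "wd"]]
    for day in panel.index:
        d0 = day.date()
        sun = solar_times(met.meta.latitude, met.meta.longitude, d0,
                          met.meta.utc_offset)
        sst_val = float(sst.get(day, float("nan")))
        sb_days[d0] = classify_sea_breeze_day(
            winds, met.data["temp"], sst_val, cfg.geometry, sun,
            criterion_c_window=cfg.criterion_c_window)
        rf_days[d0] = recirculation_factor(winds, d0, window=cfg.rf_window)
    n_sb = sum(r.is_sb for r in sb_days.values())
    logger.info("sea-breeze days: %d of %d", n_sb, len(sb_days))

    cs = _read_daily_series(cfg.cs_calendar_csv, "cs_flag").astype(bool)
    types: dict[int, str] = {}
    details = {}
    for ep in episodes:
        et = classify_episode(ep, cs, sb_days, cfg.typing)
        ep.type_label = et.type
        types[ep.episode_id] = et.type
        details[ep.episode_id] = et

    ratio_sid = cfg.ratio_station or sorted(stations)[0]
    ratio_data = stations[ratio_sid].data
    ratio_days = {day.date(): daytime_ratio(ratio_data, day.date(),
                                            cfg.ratio_window)
                  for day in panel.index}
    episode_days = {d for ep in episodes for d in ep.span_days()}
    comparisons: list[RatioComparison] = []
    skipped: list[int] = []
    baselines: dict[int, object] = {}
    for ep in episodes:
        sy = season_year(ep.start)
        if sy not in baselines:
            try:
                baselines[sy] = season_clean_baseline(
                    ratio_days, cal, sy, excluded_days=episode_days)
            except ValueError as exc:
                logger.warning("season %d baseline unavailable: %s", sy, exc)
                baselines[sy] = None
        if baselines[sy] is None:
            skipped.append(ep.episode_id)
            continue
        try:
            comparisons.append(
                compare_episode_ratios(ep, ratio_days, baselines[sy]))
        except ValueError as exc:
            logger.warning("episode %d ratios skipped: %s", ep.episode_id, exc)
            skipped.append(ep.episode_id)

    result = PipelineResult(stations, daily, panel, cal, episodes, sb_days,
                            rf_days, types, details, comparisons, skipped)
    if write:
        write_reports(cfg, result)
    return result


def episodes_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for ep in result.episodes:
        rows.append({
            "episode_id": ep.episode_id, "start": ep.start, "end": ep.end,
            "duration": ep.duration, "haze_days": ep.haze_day_count,
            "bridged_days": ";".join(str(d) for d in ep.bridged_days),
            "mean_pm25": ep.mean_pm25, "sd_pm25": ep.sd_pm25,
            "cv": ep.cv_pm25, "persistent": ep.persistent,
            "type": result.types.get(ep.episode_id, ""),
        })
    return pd.DataFrame(rows)


def ratios_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for c in result.ratio_comparisons:
        rows.append({
            "episode_id": c.episode_id, "season_year": c.season_year,
            "clean_pm25_co": c.clean.pm25_co, "episodic_pm25_co": c.episodic.pm25_co,
            "clean_nox_co": c.clean.nox_co, "episodic_nox_co": c.episodic.nox_co,
            "clean_so2_co": c.clean.so2_co, "episodic_so2_co": c.episodic.so2_co,
            "pm_up": c.pm_up, "nox_down": c.nox_down, "so2_down": c.so2_down,
            "secondary_flag": c.secondary_flag, "category": c.category,
        })
    return pd.DataFrame(rows)


def write_reports(cfg: PipelineConfig, result: PipelineResult) -> dict[str, str]:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    ep_df = episodes_frame(result)
    paths["episodes"] = str(outdir / "episodes.csv")
    ep_df.to_csv(paths["episodes"], index=False)

    df_freq = duration_frequency(result.episodes, result.types)
    paths["duration_frequency"] = str(outdir / "duration_frequency.csv")
    df_freq.to_csv(paths["duration_frequency"], index=False)

    met_sid = cfg.met_station or sorted(result.stations)[0]
    dmeans = result.daily[met_sid].means
    met_cols = [c for c in ("temp", "rh", "cc", "gr") if c in dmeans.columns]
    daily_met = pd.concat([result.panel.mean(axis=1).rename("pm25"),
                           dmeans[met_cols]], axis=1)
    rf_series = pd.Series({pd.Timestamp(d): (r.rf if r.rf is not None else
                                             float("nan"))
                           for d, r in result.rf_days.items()})
    analysis = result.calendar.table.index.month.isin(cfg.analysis_months)
    clean = [d.date() for d in
             result.calendar.table.index[analysis
                                         & ~result.calendar.table["haze"]]]
    summary = type_summary(result.episodes, result.types, daily_met,
                           rf_by_date=rf_series, sb_days=result.sb_days,
                           clean_dates=clean)
    paths["type_summary"] = str(outdir / "type_summary.csv")
    summary.to_csv(paths["type_summary"])

    ratio_df = ratios_frame(result)
    paths["ratio_comparisons"] = str(outdir / "ratio_comparisons.csv")
    ratio_df.to_csv(paths["ratio_comparisons"], index=False)

    sb_rows = [{"date": d, "is_sb": r.is_sb, "classifiable": r.classifiable,
                "a": r.criterion_a, "b": r.criterion_b, "c": r.criterion_c,
                "d": r.criterion_d, "duration_h": r.duration_h,
                "penetration_km": r.penetration_km, "delta_t": r.delta_t}
               for d, r in sorted(result.sb_days.items())]
    paths["sea_breeze_days"] = str(outdir / "sea_breeze_days.csv")
    pd.DataFrame(sb_rows).to_csv(paths["sea_breeze_days"], index=False)

    cfg_text = json.dumps({k: str(v) for k, v in vars(cfg).items()
                           if k != "outdir"}, sort_keys=True)
    manifest = {
        "version": __version__,
        "config_sha1": hashlib.sha1(cfg_text.encode()).hexdigest(),
        "n_stations": len(result.stations),
        "n_haze_days": int(result.calendar.table["haze"].sum()),
        "n_episodes": len(result.episodes),
        "n_sb_days": int(sum(r.is_sb for r in result.sb_days.values())),
        "n_secondary_flagged": int(sum(c.secondary_flag
                                       for c in result.ratio_comparisons)),
        "type_counts": {t: sum(1 for v in result.types.values() if v == t)
                        for t in ("I", "II", "III", "IV")},
    }
    paths["manifest"] = str(outdir / "manifest.json")
    Path(paths["manifest"]).write_text(json.dumps(manifest, indent=1))
    return paths
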