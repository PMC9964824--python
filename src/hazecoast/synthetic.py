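"""Synthetic multi-station scenarios with planted ground truth.

The generator emulates the statistical structure of winter air quality in a
tropical coastal city: a diurnal temperature/radiation cycle, mild synoptic
wind, cold-surge events (one to two cool windy days followed by calm
stagnation), sea-breeze days (nocturnal offshore flow reversing to a daytime
onshore run under a land-sea thermal contrast), and pollutant buildup under
a first-order box model

    C(t+1) = C(t) + E - k_vent * ws(t) * (C(t) - background),

floored at the background. CO is co-emitted in proportion to the PM emission
rate; NOx and SO2 are proportional to CO, with planted depletions (and a PM
boost) on secondary-aerosol episode days. This is the simplest mechanism
that yields stagnation buildup and sea-breeze persistence; it is not a model
of the real atmosphere.

Ground truth (cold-surge days, sea-breeze days, haze days and episodes,
episode types, secondary flags) is derived from the noiseless series and the
planted calendars, so every pipeline stage can be scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import coastal_met, episode_typing, haze_detection, station_io
from .coastal_met import CoastGeometry, SeaBreezeDay, solar_times
from .station_io import HourlyStationSeries, StationMeta

__all__ = [
    "CSEvent", "SBDayPlan", "SecondaryPlan", "ScenarioConfig", "Scenario",
    "GroundTruth", "generate_scenario", "default_scenario_config",
    "write_scenario", "evaluate_recovery",
]

#: Default hourly noise standard deviations per variable (generator units).
DEFAULT_NOISE = {
    "pm25": 1.5, "co": 0.02, "nox": 1.0, "so2": 0.1,
    "temp": 0.2, "rh": 1.0, "ws": 0.05, "wd": 0.0, "gr": 10.0, "cc": 0.0,
}


@dataclass(frozen=True)
class CSEvent:
    """A cold-surge event: windy cool arrival days, then calm stagnation."""

    start: Date
    surge_days: int = 2
    stagnation_days: int = 4
    dt_drop: float = 4.0       # degC temperature drop on surge days
    drh_drop: float = 15.0     # % RH drop on surge days
    surge_ws: float = 5.0      # m/s northerly wind on surge days
    stagnation_ws: float = 0.4  # m/s during stagnation (below calm threshold)


@dataclass(frozen=True)
class SBDayPlan:
    """A planted sea-breeze day: offshore night, onshore daytime run."""

    date: Date
    onset_offset_h: float = 2.0   # onset, hours after (sunrise + 2 h)
    run_length_h: int = 7
    onshore_ws: float = 0.8       # m/s; low enough that pollution persists
    night_offshore_ws: float = 0.6
    delta_t: float = 5.0          # planted daytime land - sea contrast, degC


@dataclass(frozen=True)
class SecondaryPlan:
    """Planted secondary-aerosol perturbation on a set of dates."""

    dates: tuple[Date, ...]
    pm_boost: float = 0.25
    nox_depletion: float = 0.2
    so2_depletion: float = 0.2


@dataclass
class ScenarioConfig:
    """Scenario layout and physical parameters.

    Concentration dynamics: ``emission`` is the PM2.5 source strength in
    ug m-3 h-1 per station (scaled by per-station factors), ``k_vent`` the
    ventilation coefficient per (m s-1 h). At the default emission 8 and
    k_vent 0.3, clean-day steady state sits near 33 ug m-3 and calm
    stagnation near 87 ug m-3, bracketing the 50 ug m-3 haze threshold the
    way the observed winters do.
    """

    start: Date
    n_days: int
    seed: int = 0
    n_stations: int = 5
    lat: float = 13.67
    lon: float = 100.61
    utc_offset: float = 7.0
    geometry: CoastGeometry = field(default_factory=CoastGeometry)
    # meteorology
    temp_mean: float = 28.0
    temp_amplitude: float = 4.0
    rh_mean: float = 65.0
    rh_amplitude: float = 10.0
    synoptic_ws: float = 2.0
    synoptic_wd: float = 30.0       # offshore (land) sector
    onshore_wd: float = 195.0       # sea sector
    default_delta_t: float = 2.0    # land-sea contrast on non-SB days, degC
    # pollution
    background_pm25: float = 20.0
    emission: float = 8.0
    k_vent: float = 0.3
    co_background: float = 0.4
    co_emission_per_pm: float = 0.015  # ppm of CO emitted per ug m-3 of PM
    nox_per_co: float = 55.0           # ppb per ppm
    so2_per_co: float = 2.5            # ppb per ppm
    # events
    cs_events: list[CSEvent] = field(default_factory=list)
    sb_days: list[SBDayPlan] = field(default_factory=list)
    secondary_episodes: list[SecondaryPlan] = field(default_factory=list)
    emission_spikes: dict[Date, float] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE))

    def validate(self) -> None:
        problems = []
        if self.n_days < 1:
            problems.append("n_days must be >= 1")
        if self.n_stations < 1:
            problems.append("n_stations must be >= 1")
        for name in ("emission", "k_vent", "co_emission_per_pm",
                     "nox_per_co", "so2_per_co", "background_pm25"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        span = {self.start + timedelta(days=i) for i in range(self.n_days)}
        for ev in self.cs_events:
            last = ev.start + timedelta(days=ev.surge_days + ev.stagnation_days - 1)
            if ev.start not in span or last not in span:
                problems.append(f"cs_event at {ev.start} extends outside the span")
        for sb in self.sb_days:
            if sb.date not in span:
                problems.append(f"sb_day {sb.date} outside the span")
        for sec in self.secondary_episodes:
            for d in sec.dates:
                if d not in span:
                    problems.append(f"secondary date {d} outside the span")
        for d in self.emission_spikes:
            if d not in span:
                problems.append(f"emission spike {d} outside the span")
        if problems:
            raise ValueError("invalid scenario config: " + "; ".join(problems))


@dataclass
class GroundTruth:
    """Planted labels plus haze structure derived from the noiseless series."""

    cs_dates: list[Date]
    sb_plans: dict[Date, SBDayPlan]
    haze_dates: list[Date]
    episodes: list[tuple[Date, Date]]
    episode_types: dict[int, str]        # 1-based episode id -> I/II/III/IV
    secondary_episode_ids: list[int]
    secondary_dates: list[Date]

    def sb_dates(self) -> list[Date]:
        return sorted(self.sb_plans)


@dataclass
class Scenario:
    """A generated scenario bundle."""

    config: ScenarioConfig
    stations: dict[str, HourlyStationSeries]
    sst: pd.Series                       # daily, degC
    cs_calendar: pd.Series               # daily, bool
    truth: GroundTruth

    @property
    def reference_station(self) -> str:
        return sorted(self.stations)[0]


def default_scenario_config(seed: int = 0,
                            start: Date = Date(2019, 12, 1),
                            n_days: int = 90) -> ScenarioConfig:
    """One winter season containing all four episode types.

    Layout: a cold-surge stagnation episode in December (Type I), a
    five-day sea-breeze spell in early January carrying a planted
    secondary-aerosol perturbation (Type II), a cold surge followed by
    sea-breeze days in late January (Type III), and an isolated
    emission-spike haze day in February (Type IV).
    """
    d = lambda off: start + timedelta(days=off)
    sb_run1 = [SBDayPlan(date=d(k)) for k in range(35, 40) if k < n_days]
    sb_run2 = [SBDayPlan(date=d(k)) for k in range(55, 58) if k < n_days]
    cs_events = [ev for ev in
                 (CSEvent(start=d(9)),                             # Dec 10
                  CSEvent(start=d(50), stagnation_days=3))         # Jan 20
                 if (ev.start - start).days + ev.surge_days
                 + ev.stagnation_days <= n_days]
    secondary = ([SecondaryPlan(dates=tuple(p.date for p in sb_run1))]
                 if sb_run1 else [])
    return ScenarioConfig(
        start=start, n_days=n_days, seed=seed,
        cs_events=cs_events,
        sb_days=sb_run1 + sb_run2,
        secondary_episodes=secondary,
        emission_spikes={d(71): 4.0} if n_days > 71 else {},       # Feb 10
    )


def _regimes(cfg: ScenarioConfig) -> pd.DataFrame:
    """Noiseless shared hourly meteorology for the whole span."""
    idx = pd.date_range(datetime(cfg.start.year, cfg.start.month, cfg.start.day),
                        periods=cfg.n_days * 24, freq="h")
    hours = idx.hour.to_numpy()
    temp = cfg.temp_mean + cfg.temp_amplitude * np.sin(2 * np.pi * (hours - 9) / 24.0)
    rh = cfg.rh_mean - cfg.rh_amplitude * np.sin(2 * np.pi * (hours - 9) / 24.0)
    gr = np.maximum(0.0, 800.0 * np.sin(np.pi * (hours - 6) / 12.0))
    cc = np.full(len(idx), 5.0)
    ws = cfg.synoptic_ws + 0.3 * np.sin(2 * np.pi * hours / 24.0)
    wd = np.full(len(idx), cfg.synoptic_wd)

    df = pd.DataFrame({"temp": temp, "rh": rh, "gr": gr, "cc": cc,
                       "ws": ws, "wd": wd}, index=idx)
    day_of = idx.floor("D")

    for ev in cfg.cs_events:
        for k in range(ev.surge_days + ev.stagnation_days):
            day = pd.Timestamp(ev.start + timedelta(days=k))
            sel = day_of == day
            if k < ev.surge_days:
                df.loc[sel, "ws"] = ev.surge_ws
                df.loc[sel, "temp"] -= ev.dt_drop
                df.loc[sel, "rh"] -= ev.drh_drop
            else:
                df.loc[sel, "ws"] = ev.stagnation_ws
                df.loc[sel, "temp"] -= 0.6 * ev.dt_drop
                df.loc[sel, "rh"] -= 0.6 * ev.drh_drop
            df.loc[sel, "wd"] = 10.0
            df.loc[sel, "cc"] -= 1.0  # surges bring clearer skies
            df.loc[sel, "gr"] *= 1.1

    for plan in cfg.sb_days:
        sun = solar_times(cfg.lat, cfg.lon, plan.date, cfg.utc_offset)
        sr_h = sun.sunrise.hour + sun.sunrise.minute / 60.0
        onset = int(round(sr_h + 2.0 + plan.onset_offset_h))
        day = pd.Timestamp(plan.date)
        sel = day_of == day
        hh = hours[sel]
        ws_day = np.full(len(hh), plan.night_offshore_ws)
        wd_day = np.full(len(hh), cfg.synoptic_wd)
        in_run = (hh >= onset) & (hh < onset + plan.run_length_h)
        pre_run_calm = (hh >= int(np.floor(sr_h + 2.0)) + 1) & (hh < onset)
        ws_day[pre_run_calm] = 0.3
        ws_day[in_run] = plan.onshore_ws
        wd_day[in_run] = cfg.onshore_wd
        df.loc[sel, "ws"] = ws_day
        df.loc[sel, "wd"] = wd_day
    return df


def _simulate_box(ws: np.ndarray, emission: np.ndarray, k_vent: float,
                  background: float) -> np.ndarray:
    """Iterate the hourly first-order ventilation box model."""
    c = np.empty(len(ws))
    c[0] = background
    for t in range(len(ws) - 1):
        c[t + 1] = c[t] + emission[t] - k_vent * ws[t] * (c[t] - background)
        if c[t + 1] < background:
            c[t + 1] = background
    return c


def generate_scenario(cfg: ScenarioConfig) -> Scenario:
    """Generate the full scenario: stations, SST, cold-surge calendar, truth.

    Deterministic given ``cfg`` (including its seed): the same configuration
    always yields bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    met = _regimes(cfg)
    idx = met.index
    day_of = idx.floor("D")
    days = pd.date_range(pd.Timestamp(cfg.start), periods=cfg.n_days, freq="D")

    # per-day emission multipliers and secondary perturbations
    spike = pd.Series(1.0, index=days)
    for d0, f in cfg.emission_spikes.items():
        spike[pd.Timestamp(d0)] = f
    pm_boost = pd.Series(0.0, index=days)
    nox_depl = pd.Series(0.0, index=days)
    so2_depl = pd.Series(0.0, index=days)
    secondary_dates: list[Date] = []
    for sec in cfg.secondary_episodes:
        for d0 in sec.dates:
            pm_boost[pd.Timestamp(d0)] = sec.pm_boost
            nox_depl[pd.Timestamp(d0)] = sec.nox_depletion
            so2_depl[pd.Timestamp(d0)] = sec.so2_depletion
            secondary_dates.append(d0)

    hourly_spike = spike.reindex(day_of).to_numpy()
    hourly_boost = pm_boost.reindex(day_of).to_numpy()
    hourly_noxd = nox_depl.reindex(day_of).to_numpy()
    hourly_so2d = so2_depl.reindex(day_of).to_numpy()

    station_factors = 1.0 + 0.05 * np.array(
        [((-1) ** i) * ((i + 1) // 2) for i in range(cfg.n_stations)])
    ws_arr = met["ws"].to_numpy()

    noiseless: dict[str, pd.DataFrame] = {}
    stations: dict[str, HourlyStationSeries] = {}
    for i in range(cfg.n_stations):
        sid = f"S{i + 1:02d}"
        e_pm = cfg.emission * station_factors[i] * hourly_spike
        pm = _simulate_box(ws_arr, e_pm, cfg.k_vent, cfg.background_pm25)
        co = _simulate_box(ws_arr, cfg.co_emission_per_pm * e_pm,
                           cfg.k_vent, cfg.co_background)
        pm = pm * (1.0 + hourly_boost)
        nox = cfg.nox_per_co * co * (1.0 - hourly_noxd)
        so2 = cfg.so2_per_co * co * (1.0 - hourly_so2d)
        clean = pd.DataFrame({
            "pm25": pm, "co": co, "nox": nox, "so2": so2,
            "temp": met["temp"], "rh": met["rh"], "ws": met["ws"],
            "wd": met["wd"], "gr": met["gr"], "cc": met["cc"],
        }, index=idx)
        noiseless[sid] = clean

        noisy = clean.copy()
        for var, sd in cfg.noise_sd.items():
            if var not in noisy.columns or sd <= 0:
                continue
            pert = rng.normal(0.0, sd, size=len(idx))
            if var == "wd":
                noisy[var] = (noisy[var] + pert) % 360.0
            else:
                noisy[var] = noisy[var] + pert
        noisy["pm25"] = noisy["pm25"].clip(lower=0.0)
        noisy["co"] = noisy["co"].clip(lower=0.001)
        noisy["nox"] = noisy["nox"].clip(lower=0.0)
        noisy["so2"] = noisy["so2"].clip(lower=0.0)
        noisy["rh"] = noisy["rh"].clip(0.0, 100.0)
        noisy["ws"] = noisy["ws"].clip(lower=0.0)
        noisy["gr"] = noisy["gr"].clip(0.0, 1000.0)
        noisy["cc"] = noisy["cc"].clip(0.0, 10.0)

        meta = StationMeta(station_id=sid,
                           latitude=cfg.lat + 0.02 * ((i % 3) - 1),
                           longitude=cfg.lon + 0.03 * ((i % 2) - 0.5),
                           province="synthetic", background="synthetic",
                           utc_offset=cfg.utc_offset)
        flags = pd.DataFrame(np.where(noisy.notna(), station_io.VALID,
                                      station_io.MISSING),
                             index=idx, columns=noisy.columns)
        stations[sid] = HourlyStationSeries(meta, noisy, flags)

    # daily SST from the planted land-sea contrast and the noiseless land temp
    plans = {p.date: p for p in cfg.sb_days}
    sst_vals = []
    land_temp = met["temp"]
    for day in days:
        d0 = day.date()
        sun = solar_times(cfg.lat, cfg.lon, d0, cfg.utc_offset)
        sel = (land_temp.index >= sun.sunrise) & (land_temp.index <= sun.sunset)
        day_mean = float(land_temp[sel].mean())
        delta = plans[d0].delta_t if d0 in plans else cfg.default_delta_t
        sst_vals.append(day_mean - delta)
    sst = pd.Series(sst_vals, index=days, name="sst")

    cs_dates = []
    for ev in cfg.cs_events:
        cs_dates.extend(ev.start + timedelta(days=k) for k in range(ev.surge_days))
    cs_calendar = pd.Series([d.date() in set(cs_dates) for d in days],
                            index=days, name="cs_flag")

    truth = _derive_truth(cfg, noiseless, plans, cs_dates, secondary_dates)
    return Scenario(cfg, stations, sst, cs_calendar, truth)


def _derive_truth(cfg, noiseless, plans, cs_dates, secondary_dates) -> GroundTruth:
    """Haze structure from the noiseless series + planted influence calendars."""
    daily = {}
    for sid, df in noiseless.items():
        day = df.index.floor("D")
        daily[sid] = df["pm25"].groupby(day).mean()
    panel = pd.DataFrame(daily)
    cal = haze_detection.compute_haze_days(
        panel, min_stations=min(2, panel.shape[1]))
    episodes = haze_detection.segment_episodes(cal)

    sb_lookup = {d: SeaBreezeDay(date=d, is_sb=True, classifiable=True)
                 for d in plans}
    all_days = [d.date() for d in panel.index]
    for d in all_days:
        sb_lookup.setdefault(d, SeaBreezeDay(date=d, is_sb=False,
                                             classifiable=True))
    types = {}
    secondary_ids = []
    sec_set = set(secondary_dates)
    for ep in episodes:
        et = episode_typing.classify_episode(ep, set(cs_dates), sb_lookup)
        types[ep.episode_id] = et.type
        if any(d in sec_set for d in ep.span_days()):
            secondary_ids.append(ep.episode_id)
    return GroundTruth(
        cs_dates=sorted(cs_dates),
        sb_plans=dict(plans),
        haze_dates=cal.haze_dates,
        episodes=[(ep.start, ep.end) for ep in episodes],
        episode_types=types,
        secondary_episode_ids=secondary_ids,
        secondary_dates=sorted(sec_set))


def write_scenario(scn: Scenario, outdir) -> dict[str, str]:
    """Write a scenario in the CSV dialects the pipeline reads, plus truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    meta_rows = []
    for sid, series in scn.stations.items():
        p = outdir / f"station_{sid}.csv"
        station_io.write_station_csv(series, p)
        paths[sid] = str(p)
        m = series.meta
        meta_rows.append({"station_id": m.station_id, "lat": m.latitude,
                          "lon": m.longitude, "province": m.province,
                          "background": m.background})
    pd.DataFrame(meta_rows).to_csv(outdir / "stations.csv", index=False)
    sst_df = pd.DataFrame({"date": scn.sst.index.strftime("%Y-%m-%d"),
                           "sst": scn.sst.values})
    sst_df.to_csv(outdir / "sst.csv", index=False)
    cs_df = pd.DataFrame({"date": scn.cs_calendar.index.strftime("%Y-%m-%d"),
                          "cs_flag": scn.cs_calendar.astype(int).values})
    cs_df.to_csv(outdir / "cs_calendar.csv", index=False)

    t = scn.truth
    truth_json = {
        "cs_dates": [str(d) for d in t.cs_dates],
        "sb_dates": [str(d) for d in t.sb_dates()],
        "haze_dates": [str(d) for d in t.haze_dates],
        "episodes": [[str(a), str(b)] for a, b in t.episodes],
        "episode_types": {str(k): v for k, v in t.episode_types.items()},
        "secondary_episode_ids": t.secondary_episode_ids,
        "secondary_dates": [str(d) for d in t.secondary_dates],
    }
    (outdir / "truth.json").write_text(json.dumps(truth_json, indent=1))
    paths["truth"] = str(outdir / "truth.json")
    return paths


def evaluate_recovery(truth: GroundTruth,
                      sb_results: dict[Date, SeaBreezeDay] | None = None,
                      haze_dates: list[Date] | None = None,
                      episodes: list[tuple[Date, Date]] | None = None,
                      episode_types: dict[int, str] | None = None,
                      secondary_episode_ids: list[int] | None = None) -> dict:
    """Score pipeline outputs against ground truth.

    Returns a flat dict of per-stage metrics; stages not supplied are
    omitted. Sea-breeze metrics are over classifiable days only; episode
    agreement is the Jaccard index over episode-member days; type accuracy
    is over episodes matched by identical (start, end) spans.
    """
    report: dict[str, float] = {}
    if sb_results is not None:
        planted = set(truth.sb_plans)
        tp = fn = tn = fp = 0
        for d, res in sb_results.items():
            if not res.classifiable:
                continue
            if d in planted:
                tp += res.is_sb
                fn += not res.is_sb
            else:
                fp += res.is_sb
                tn += not res.is_sb
        report["sb_sensitivity"] = tp / (tp + fn) if tp + fn else float("nan")
        report["sb_specificity"] = tn / (tn + fp) if tn + fp else float("nan")
    if haze_dates is not None:
        got, want = set(haze_dates), set(truth.haze_dates)
        union = got | want
        report["haze_day_jaccard"] = (len(got & want) / len(union)
                                      if union else 1.0)
        report["haze_day_exact"] = float(got == want)
    if episodes is not None:
        def member_days(spans):
            out = set()
            for a, b in spans:
                d = a
                while d <= b:
                    out.add(d)
                    d += timedelta(days=1)
            return out
        got_d = member_days(episodes)
        want_d = member_days(truth.episodes)
        union = got_d | want_d
        report["episode_day_jaccard"] = (len(got_d & want_d) / len(union)
                                         if union else 1.0)
    if episode_types is not None and episodes is not None:
        truth_by_span = {span: truth.episode_types[i + 1]
                         for i, span in enumerate(truth.episodes)}
        matched = correct = 0
        for i, span in enumerate(episodes):
            if span in truth_by_span:
                matched += 1
                correct += episode_types.get(i + 1) == truth_by_span[span]
        report["type_accuracy"] = correct / matched if matched else float("nan")
        report["type_matched_episodes"] = matched
    if secondary_episode_ids is not None:
        got = set(secondary_episode_ids)
        want = set(truth.secondary_episode_ids)
        n = len(truth.episodes)
        correct = sum((i in got) == (i in want) for i in range(1, n + 1))
        report["secondary_flag_accuracy"] = correct / n if n else float("nan")
    return report
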