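"""Hourly station data model: reading, quality screening, gap-filling, daily aggregation.

All downstream analysis consumes :class:`HourlyStationSeries`, a station's
hourly variables on a complete local-time grid with per-value QC flags, and
:class:`DailyTable`, the per-calendar-day aggregation with completeness
accounting.

Wind convention is meteorological: ``wd`` is the compass direction the wind
blows FROM (degrees clockwise from north); the derived components
``u = -ws*sin(wd)`` and ``v = -ws*cos(wd)`` point in the direction air moves
TOWARD (east and north positive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical variable names and units.
#: pm25/pm10 ug m-3, nox/so2 ppb, co ppm, temp degC, rh %, ws m s-1,
#: wd degrees-from-north, gr W m-2, cc tenths (0-10), rain mm h-1.
VARIABLES = ("pm25", "pm10", "nox", "so2", "co", "temp", "rh", "ws", "wd",
             "gr", "cc", "rain")

# QC flag values
VALID = "valid"
MISSING = "missing"
OUT_OF_RANGE = "out_of_range"
GAP_FILLED = "gap_filled"


class IntegrityError(ValueError):
    """Raised when input data violates a structural requirement."""


class FittingError(ValueError):
    """Raised when a gap-filling regression cannot be established."""


@dataclass(frozen=True)
class StationMeta:
    """Identity and location of one monitoring station."""

    station_id: str
    latitude: float
    longitude: float
    province: str = ""
    background: str = ""
    utc_offset: float = 7.0  # local time = UTC + offset; no DST in study region

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")


@dataclass(frozen=True)
class QCRanges:
    """Closed plausibility intervals per variable; values outside are masked."""

    ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "pm25": (0.0, 1000.0),
        "pm10": (0.0, 1000.0),
        "nox": (0.0, 1000.0),
        "so2": (0.0, 1000.0),
        "co": (0.0, 100.0),
        "temp": (-5.0, 50.0),
        "rh": (0.0, 100.0),
        "ws": (0.0, 50.0),
        "wd": (0.0, 360.0),
        "rain": (0.0, 1000.0),
        "gr": (0.0, 1000.0),
        "cc": (0.0, 10.0),
    })

    def __post_init__(self) -> None:
        for var, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"invalid QC range for {var}: [{lo}, {hi}]")


@dataclass
class HourlyStationSeries:
    """One station's hourly variables with per-value QC flags.

    ``data`` and ``flags`` share a strictly-increasing hourly
    :class:`~pandas.DatetimeIndex` in local time and the same columns.
    Values flagged ``missing`` or ``out_of_range`` are NaN in ``data``;
    computation therefore never sees screened-out values.
    """

    meta: StationMeta
    data: pd.DataFrame
    flags: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.flags.index):
            raise IntegrityError("data and flags index mismatch")
        if list(self.data.columns) != list(self.flags.columns):
            raise IntegrityError("data and flags columns mismatch")
        idx = self.data.index
        if len(idx) > 1:
            deltas = np.diff(idx.asi8)
            if not (deltas == 3_600_000_000_000).all():
                raise IntegrityError("timestamps are not a complete hourly grid")

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def copy(self) -> "HourlyStationSeries":
        return HourlyStationSeries(self.meta, self.data.copy(), self.flags.copy())


def wind_components(ws: pd.Series, wd: pd.Series) -> tuple[pd.Series, pd.Series]:
    """East/north components (direction of air motion) from speed/direction-from."""
    rad = np.deg2rad(wd)
    u = -ws * np.sin(rad)
    v = -ws * np.cos(rad)
    return u, v


def wind_from_components(u: pd.Series, v: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Speed and direction-from (degrees in [0, 360)) from east/north components."""
    ws = np.hypot(u, v)
    wd = (np.rad2deg(np.arctan2(-u, -v))) % 360.0
    return pd.Series(ws, index=u.index), pd.Series(wd, index=u.index)


def read_station_csv(path, meta: StationMeta,
                     datetime_format: str | None = None) -> HourlyStationSeries:
    """Read a station CSV onto a complete hourly grid.

    The file must have a ``datetime`` column (local time) plus variable
    columns named as in :data:`VARIABLES`. Rows absent from the grid become
    missing values. Duplicate timestamps are an integrity error.
    """
    df = pd.read_csv(path)
    if "datetime" not in df.columns:
        raise IntegrityError(f"{path}: no 'datetime' column")
    try:
        ts = pd.to_datetime(df["datetime"], format=datetime_format)
    except (ValueError, TypeError) as exc:
        raise IntegrityError(f"{path}: unparseable datetime ({exc})") from exc
    if ts.duplicated().any():
        dups = ts[ts.duplicated()].iloc[0]
        raise IntegrityError(f"{path}: duplicate timestamp {dups}")
    df = df.drop(columns=["datetime"]).set_index(pd.DatetimeIndex(ts)).sort_index()
    keep = [c for c in df.columns if c in VARIABLES]
    df = df[keep].astype(float)
    grid = pd.date_range(df.index[0].floor("h"), df.index[-1].floor("h"), freq="h")
    df = df.reindex(grid)
    flags = pd.DataFrame(np.where(df.notna(), VALID, MISSING),
                         index=df.index, columns=df.columns)
    return HourlyStationSeries(meta, df, flags)


def write_station_csv(series: HourlyStationSeries, path) -> None:
    """Write a series in the dialect :func:`read_station_csv` reads (round-trip safe)."""
    out = series.data.copy()
    out.insert(0, "datetime", out.index.strftime("%Y-%m-%dT%H:%M:%S"))
    out.to_csv(path, index=False, float_format="%.17g")


def read_station_metadata_csv(path, utc_offset: float = 7.0) -> dict[str, StationMeta]:
    """Read a station-metadata CSV (station_id, lat, lon, province, background)."""
    df = pd.read_csv(path)
    metas = {}
    for _, row in df.iterrows():
        metas[str(row["station_id"])] = StationMeta(
            station_id=str(row["station_id"]),
            latitude=float(row["lat"]), longitude=float(row["lon"]),
            province=str(row.get("province", "")),
            background=str(row.get("background", "")),
            utc_offset=utc_offset)
    return metas


def apply_qc(series: HourlyStationSeries,
             ranges: QCRanges | None = None) -> HourlyStationSeries:
    """Mask values outside their plausibility interval.

    Out-of-range values are set to NaN and flagged ``out_of_range``; in-range
    values are untouched. Screening never fails and is idempotent. A wind
    direction of exactly 360 is in range and normalised to 0.
    """
    ranges = ranges or QCRanges()
    out = series.copy()
    n_masked = 0
    for var in out.variables:
        if var not in ranges.ranges:
            continue
        lo, hi = ranges.ranges[var]
        col = out.data[var]
        bad = col.notna() & ((col < lo) | (col > hi))
        n_masked += int(bad.sum())
        out.data.loc[bad, var] = np.nan
        out.flags.loc[bad, var] = OUT_OF_RANGE
        if var == "wd":
            exact = out.data[var] == 360.0
            out.data.loc[exact, var] = 0.0
    if n_masked:
        logger.info("QC %s: masked %d out-of-range values",
                    series.meta.station_id, n_masked)
    return out


def gap_fill_wind_from_donor(target: HourlyStationSeries,
                             donor: HourlyStationSeries,
                             min_overlap: int = 48,
                             max_interp_gap: int = 3) -> HourlyStationSeries:
    """Fill missing target wind from a donor station.

    Wind is converted to u,v components; separate least-squares linear fits of
    target on donor (one per component) over overlapping valid hours fill
    missing target hours where the donor is valid. Remaining isolated gaps of
    at most ``max_interp_gap`` hours are linearly interpolated in u,v. Filled
    hours are flagged ``gap_filled``; speed and direction are recomputed from
    the filled components. Values flagged valid are never altered.
    """
    idx = target.data.index
    d = donor.data.reindex(idx)
    t_ok = target.data["ws"].notna() & target.data["wd"].notna()
    d_ok = d["ws"].notna() & d["wd"].notna()
    overlap = t_ok & d_ok
    if int(overlap.sum()) < min_overlap:
        raise FittingError(
            f"only {int(overlap.sum())} overlapping valid wind hours "
            f"(need >= {min_overlap})")

    tu, tv = wind_components(target.data["ws"], target.data["wd"])
    du, dv = wind_components(d["ws"], d["wd"])

    fits = {}
    for name, tcomp, dcomp in (("u", tu, du), ("v", tv, dv)):
        slope, intercept = np.polyfit(dcomp[overlap], tcomp[overlap], 1)
        fits[name] = (slope, intercept)

    fill_from_donor = (~t_ok) & d_ok
    fu = tu.copy()
    fv = tv.copy()
    fu[fill_from_donor] = fits["u"][0] * du[fill_from_donor] + fits["u"][1]
    fv[fill_from_donor] = fits["v"][0] * dv[fill_from_donor] + fits["v"][1]

    # interpolate remaining short gaps in components
    still = fu.isna()
    interp_mask = _short_gap_mask(still.to_numpy(), max_interp_gap)
    if interp_mask.any():
        iu = fu.interpolate(method="linear", limit_area="inside")
        iv = fv.interpolate(method="linear", limit_area="inside")
        fu[interp_mask] = iu[interp_mask]
        fv[interp_mask] = iv[interp_mask]

    filled = fu.notna() & ~t_ok
    ws_new, wd_new = wind_from_components(fu, fv)
    out = target.copy()
    out.data.loc[filled, "ws"] = ws_new[filled]
    out.data.loc[filled, "wd"] = wd_new[filled]
    out.flags.loc[filled, "ws"] = GAP_FILLED
    out.flags.loc[filled, "wd"] = GAP_FILLED
    logger.info("gap-fill %s<-%s: %d donor-filled/interpolated wind hours",
                target.meta.station_id, donor.meta.station_id, int(filled.sum()))
    return out


def _short_gap_mask(isna: np.ndarray, max_len: int) -> np.ndarray:
    """True for NaN positions lying in an interior run of length <= max_len."""
    mask = np.zeros_like(isna, dtype=bool)
    n = len(isna)
    i = 0
    while i < n:
        if isna[i]:
            j = i
            while j < n and isna[j]:
                j += 1
            if i > 0 and j < n and (j - i) <= max_len:
                mask[i:j] = True
            i = j
        else:
            i += 1
    return mask


@dataclass
class DailyTable:
    """Per-calendar-day aggregation of one station's hourly series.

    ``means`` holds the daily mean per variable (NaN when the day's
    completeness falls below the configured minimum); ``valid_hours`` and
    ``completeness`` (valid hours / 24) carry the accounting.
    """

    station_id: str
    means: pd.DataFrame
    valid_hours: pd.DataFrame
    completeness: pd.DataFrame


def daily_aggregate(series: HourlyStationSeries,
                    min_completeness: float = 0.75) -> DailyTable:
    """Daily means over valid hours of each local calendar day.

    A variable's daily mean is reported only when at least
    ``min_completeness`` of the 24 hours are valid (default 0.75, i.e. 18 h).
    """
    if not 0.0 < min_completeness <= 1.0:
        raise ValueError("min_completeness must be in (0, 1]")
    day = series.data.index.floor("D")
    grouped = series.data.groupby(day)
    means = grouped.mean()
    counts = grouped.count().astype(float)
    completeness = counts / 24.0
    means = means.where(completeness >= min_completeness)
    means.index = pd.DatetimeIndex(means.index)
    return DailyTable(series.meta.station_id, means, counts, completeness)


def daily_pm25_panel(tables: dict[str, DailyTable]) -> pd.DataFrame:
    """Assemble the dates x stations matrix of daily-mean PM2.5."""
    cols = {sid: t.means["pm25"] for sid, t in tables.items() if "pm25" in t.means}
    if not cols:
        raise IntegrityError("no station provides daily PM2.5")
    return pd.DataFrame(cols).sort_index()
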