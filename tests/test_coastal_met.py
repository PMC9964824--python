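import math
from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hazecoast.coastal_met import (CoastGeometry, classify_sea_breeze_day,
                                   in_sector, recirculation_factor,
                                   sb_penetration, solar_times)

GEOM = CoastGeometry()


def winds_frame(ws, wd, start="2020-01-15"):
    idx = pd.date_range(start, periods=len(ws), freq="h")
    return pd.DataFrame({"ws": np.asarray(ws, float),
                         "wd": np.asarray(wd, float)}, index=idx)


class TestSolarTimes:
    def test_bangkok_equinox_matches_ephemeris(self):
        # independent reference: published ephemeris for Bangkok, 2020-03-20
        # sunrise 06:23, sunset 18:29 local (UTC+7)
        st_ = solar_times(13.67, 100.61, date(2020, 3, 20), 7)
        assert abs((st_.sunrise - st_.sunrise.replace(hour=6, minute=23))
                   .total_seconds()) <= 300
        assert abs((st_.sunset - st_.sunset.replace(hour=18, minute=29))
                   .total_seconds()) <= 300

    def test_null_island_equinox_matches_ephemeris(self):
        # published ephemeris for 0N 0E, 2020-03-20: sunrise ~06:03,
        # sunset ~18:12 UTC (equation of time shifts solar noon to ~12:08)
        st_ = solar_times(0.0, 0.0, date(2020, 3, 20), 0)
        assert abs((st_.sunrise - st_.sunrise.replace(hour=6, minute=3))
                   .total_seconds()) <= 300
        assert abs((st_.sunset - st_.sunset.replace(hour=18, minute=12))
                   .total_seconds()) <= 300

    @given(lat=st.floats(-60, 60), lon=st.floats(-180, 180),
           doy=st.integers(0, 364))
    @settings(max_examples=60, deadline=None)
    def test_sunrise_before_sunset(self, lat, lon, doy):
        d = date(2021, 1, 1) + timedelta(days=doy)
        st_ = solar_times(lat, lon, d, 0)
        assert st_.sunrise < st_.sunset

    def test_polar_latitude_rejected(self):
        with pytest.raises(ValueError):
            solar_times(70.0, 0.0, date(2020, 6, 21), 0)


class TestSectors:
    @pytest.mark.parametrize("wd,sector,inside", [
        (200.0, (135.0, 255.0), True),
        (135.0, (135.0, 255.0), True),
        (255.0, (135.0, 255.0), False),  # half-open
        (0.0, (315.0, 75.0), True),      # wrap through north
        (320.0, (315.0, 75.0), True),
        (80.0, (315.0, 75.0), False),
    ])
    def test_membership(self, wd, sector, inside):
        assert in_sector(wd, sector) is inside

    def test_overlapping_sectors_rejected(self):
        with pytest.raises(ValueError):
            CoastGeometry(onshore_sector=(100.0, 200.0),
                          offshore_sector=(150.0, 250.0))


def constructed_day(onshore_hours=range(11, 19), delta_t=5.0,
                    wd_jitter=None, start="2020-01-15"):
    """48 h of winds: offshore at night, onshore during the given hours."""
    ws, wd = [], []
    for day in range(2):
        for h in range(24):
            if day == 0 and h in onshore_hours:
                ws.append(2.0)
                wd.append(195.0)
            elif h >= 22 or h <= 8:
                ws.append(1.5)
                wd.append(30.0)
            else:
                ws.append(0.3)   # calm
                wd.append(30.0)
    w = winds_frame(ws, wd, start=start)
    if wd_jitter is not None:
        w["wd"] = (w["wd"] + wd_jitter) % 360.0
    temp = pd.Series(30.0, index=w.index)
    sun = solar_times(13.67, 100.61, date(2020, 1, 15), 7)
    sst = 30.0 - delta_t
    return w, temp, sst, sun


class TestSeaBreezeClassification:
    def test_textbook_sea_breeze_day(self):
        w, temp, sst, sun = constructed_day()
        r = classify_sea_breeze_day(w, temp, sst, GEOM, sun)
        assert r.is_sb
        assert (r.criterion_a, r.criterion_b, r.criterion_c,
                r.criterion_d) == (True, True, True, True)
        assert r.onset.hour == 11
        assert r.duration_h == 8.0

    def test_weak_thermal_contrast_fails_criterion_d(self):
        w, temp, sst, sun = constructed_day(delta_t=2.0)
        r = classify_sea_breeze_day(w, temp, sst, GEOM, sun)
        assert not r.is_sb
        assert r.criterion_d is False
        assert r.criterion_b is True

    def test_exact_3deg_contrast_is_not_enough(self):
        w, temp, sst, sun = constructed_day(delta_t=3.0)
        r = classify_sea_breeze_day(w, temp, sst, GEOM, sun)
        assert r.criterion_d is False

    def test_single_onshore_hour_fails_criterion_b(self):
        w, temp, sst, sun = constructed_day(onshore_hours=[12])
        r = classify_sea_breeze_day(w, temp, sst, GEOM, sun)
        assert not r.is_sb
        assert r.criterion_b is False

    def test_missing_wind_window_is_unclassifiable(self):
        w, temp, sst, sun = constructed_day()
        w.loc[w.index[:12], "ws"] = np.nan  # wipe the pre-sunrise window
        r = classify_sea_breeze_day(w, temp, sst, GEOM, sun)
        assert not r.classifiable

    def test_deterministic(self):
        w, temp, sst, sun = constructed_day()
        r1 = classify_sea_breeze_day(w, temp, sst, GEOM, sun)
        r2 = classify_sea_breeze_day(w, temp, sst, GEOM, sun)
        assert r1 == r2


class TestPenetration:
    def test_run_along_coast_normal(self):
        # 5 h at 2 m/s exactly along the inland normal: 2*3600*5/1000 = 36 km
        w = winds_frame([2.0] * 5, [(GEOM.coast_normal_deg + 180) % 360] * 5)
        assert sb_penetration(w, GEOM.coast_normal_deg) == pytest.approx(36.0)

    def test_perpendicular_wind_contributes_nothing(self):
        w = winds_frame([3.0] * 4, [(GEOM.coast_normal_deg + 90) % 360] * 4)
        assert sb_penetration(w, GEOM.coast_normal_deg) == pytest.approx(
            0.0, abs=1e-9)

    def test_linear_in_speed(self):
        wd = [(GEOM.coast_normal_deg + 200) % 360] * 6
        full = sb_penetration(winds_frame([2.0] * 6, wd), GEOM.coast_normal_deg)
        half = sb_penetration(winds_frame([1.0] * 6, wd), GEOM.coast_normal_deg)
        assert full == pytest.approx(2 * half)


class TestRecirculationFactor:
    def test_constant_wind_is_straight_line(self):
        w = winds_frame([3.0] * 24, [270.0] * 24)
        r = recirculation_factor(w, date(2020, 1, 15))
        assert r.rf == pytest.approx(0.0, abs=1e-12)

    def test_outandback_is_full_recirculation(self):
        ws = [0.0] * 10 + [2.0] * 8 + [0.0] * 6
        wd = [0.0] * 10 + [270.0] * 4 + [90.0] * 4 + [0.0] * 6
        r = recirculation_factor(winds_frame(ws, wd), date(2020, 1, 15))
        assert r.rf == pytest.approx(1.0)
        assert r.X == pytest.approx(0.0, abs=1e-9)

    def test_closed_loop_with_extra_leg(self):
        # two unit-speed loops plus one extra eastward hour in the 9-h
        # window: RF = 1 - 3.6/(9*3.6) = 8/9
        wd_cycle = [270.0, 180.0, 90.0, 0.0]  # from W,S,E,N -> toward E,N,W,S
        ws = [0.0] * 10 + [1.0] * 9 + [0.0] * 5
        wd = [0.0] * 10 + wd_cycle * 2 + [270.0] + [0.0] * 5
        r = recirculation_factor(winds_frame(ws, wd), date(2020, 1, 15))
        assert r.rf == pytest.approx(1.0 - 1.0 / 9.0)

    def test_too_few_valid_hours_gives_absent(self):
        ws = [np.nan] * 24
        r = recirculation_factor(winds_frame(ws, ws), date(2020, 1, 15))
        assert r.rf is None

    def test_calm_day_has_undefined_rf(self):
        w = winds_frame([0.0] * 24, [0.0] * 24)
        r = recirculation_factor(w, date(2020, 1, 15))
        assert r.rf is None
        assert r.wind_run == 0.0

    @given(data=st.data())
    @settings(max_examples=80, deadline=None)
    def test_bounds_rotation_and_scale_invariance(self, data):
        n = 24
        ws = data.draw(st.lists(st.floats(0.0, 20.0), min_size=n, max_size=n))
        wd = data.draw(st.lists(st.floats(0.0, 359.99), min_size=n, max_size=n))
        rot = data.draw(st.floats(0.0, 360.0))
        scale = data.draw(st.floats(0.1, 10.0))
        r = recirculation_factor(winds_frame(ws, wd), date(2020, 1, 15))
        if r.rf is None or r.wind_run < 1e-9:
            return
        assert 0.0 <= r.rf <= 1.0
        assert math.hypot(r.X, r.Y) <= r.wind_run + 1e-9
        rotated = winds_frame(ws, (np.asarray(wd) + rot) % 360.0)
        scaled = winds_frame(np.asarray(ws) * scale, wd)
        assert recirculation_factor(rotated, date(2020, 1, 15)).rf == \
            pytest.approx(r.rf, abs=1e-9)
        assert recirculation_factor(scaled, date(2020, 1, 15)).rf == \
            pytest.approx(r.rf, abs=1e-9)
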