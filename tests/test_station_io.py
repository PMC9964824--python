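import numpy as np
import pandas as pd
import pytest

from hazecoast.station_io import (GAP_FILLED, MISSING, OUT_OF_RANGE, VALID,
                                  FittingError, IntegrityError, QCRanges,
                                  StationMeta, apply_qc, daily_aggregate,
                                  gap_fill_wind_from_donor, read_station_csv,
                                  write_station_csv)

from conftest import make_series

META = StationMeta("P05", 13.67, 100.61)


class TestReadStationCsv:
    def test_missing_hour_completes_grid(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("datetime,pm25\n"
                     "2020-01-01T00:00:00,10\n"
                     "2020-01-01T01:00:00,11\n"
                     "2020-01-01T03:00:00,13\n")
        s = read_station_csv(p, META)
        assert len(s.data) == 4
        assert np.isnan(s.data["pm25"].iloc[2])
        assert s.flags["pm25"].iloc[2] == MISSING
        assert s.flags["pm25"].iloc[0] == VALID

    def test_full_day_all_variables(self, tmp_path):
        cols = ["pm25", "pm10", "nox", "so2", "co", "temp", "rh", "ws", "wd",
                "gr", "cc"]
        lines = ["datetime," + ",".join(cols)]
        for h in range(24):
            lines.append(f"2020-01-01T{h:02d}:00:00," +
                         ",".join(str(1.0 + h) for _ in cols))
        p = tmp_path / "s.csv"
        p.write_text("\n".join(lines) + "\n")
        s = read_station_csv(p, META)
        assert len(s.data) == 24
        assert not s.data.isna().any().any()

    def test_duplicate_timestamp_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("datetime,pm25\n"
                     "2020-01-01T05:00:00,1\n"
                     "2020-01-01T05:00:00,2\n")
        with pytest.raises(IntegrityError, match="duplicate"):
            read_station_csv(p, META)

    def test_unparseable_datetime_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("datetime,pm25\nnot-a-date,1\n")
        with pytest.raises(IntegrityError):
            read_station_csv(p, META, datetime_format="%Y-%m-%dT%H:%M:%S")

    def test_roundtrip_bit_identical(self, tmp_path):
        s = make_series({"pm25": [10.123456789012345, np.nan, 30.0],
                         "ws": [1.0, 2.0, np.nan]})
        p = tmp_path / "rt.csv"
        write_station_csv(s, p)
        s2 = read_station_csv(p, s.meta)
        pd.testing.assert_frame_equal(s.data, s2.data)


class TestApplyQc:
    @pytest.mark.parametrize("var,value,expect_masked", [
        ("temp", 55.0, True),    # above probable range -5..50
        ("rh", 100.0, False),    # closed interval: boundary retained
        ("ws", -1.0, True),      # below lower bound
        ("pm25", 1000.0, False),
        ("co", 100.5, True),
    ])
    def test_range_screening(self, var, value, expect_masked):
        s = apply_qc(make_series({var: [value]}), QCRanges())
        assert np.isnan(s.data[var].iloc[0]) == expect_masked
        expected_flag = OUT_OF_RANGE if expect_masked else VALID
        assert s.flags[var].iloc[0] == expected_flag

    def test_idempotent(self):
        s = make_series({"temp": [55.0, 20.0, -10.0], "rh": [50.0, 101.0, 0.0]})
        once = apply_qc(s)
        twice = apply_qc(once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        pd.testing.assert_frame_equal(once.flags, twice.flags)

    def test_wd_360_normalised_to_zero(self):
        s = apply_qc(make_series({"wd": [360.0]}))
        assert s.data["wd"].iloc[0] == 0.0
        assert s.flags["wd"].iloc[0] == VALID


class TestGapFillWind:
    def _pair(self, n=100, gaps=(), transform=None):
        rng = np.random.default_rng(42)
        ws = rng.uniform(0.5, 6.0, n)
        wd = rng.uniform(0.0, 360.0, n)
        donor = make_series({"ws": ws, "wd": wd})
        t_ws, t_wd = ws.copy(), wd.copy()
        if transform:
            from hazecoast.station_io import (wind_components,
                                              wind_from_components)
            u, v = wind_components(pd.Series(ws), pd.Series(wd))
            u2, v2 = transform(u, v)
            s, d = wind_from_components(u2, v2)
            t_ws, t_wd = s.to_numpy(), d.to_numpy()
        t_ws, t_wd = t_ws.astype(float), t_wd.astype(float)
        for g in gaps:
            t_ws[g] = np.nan
            t_wd[g] = np.nan
        target = make_series({"ws": t_ws, "wd": t_wd})
        return target, donor

    def test_identity_regression_fills_donor_values(self):
        gaps = [5, 20, 21, 50, 80]
        target, donor = self._pair(gaps=gaps)
        filled = gap_fill_wind_from_donor(target, donor)
        for g in gaps:
            assert filled.data["ws"].iloc[g] == pytest.approx(
                donor.data["ws"].iloc[g], abs=1e-9)
            assert filled.flags["ws"].iloc[g] == GAP_FILLED

    def test_affine_relation_recovered_exactly(self):
        # target components are exactly 2*donor + 1: least squares must
        # recover the line and fill accordingly
        transform = lambda u, v: (2 * u + 1, 2 * v + 1)
        target, donor = self._pair(gaps=[30], transform=transform)
        filled = gap_fill_wind_from_donor(target, donor)
        from hazecoast.station_io import wind_components
        du, dv = wind_components(donor.data["ws"], donor.data["wd"])
        fu, fv = wind_components(filled.data["ws"], filled.data["wd"])
        assert fu.iloc[30] == pytest.approx(2 * du.iloc[30] + 1, abs=1e-8)
        assert fv.iloc[30] == pytest.approx(2 * dv.iloc[30] + 1, abs=1e-8)

    def test_insufficient_overlap_raises(self):
        target, donor = self._pair(n=10)
        with pytest.raises(FittingError):
            gap_fill_wind_from_donor(target, donor)

    def test_valid_values_never_altered(self):
        target, donor = self._pair(gaps=[7, 8])
        before = target.data.copy()
        filled = gap_fill_wind_from_donor(target, donor)
        untouched = before["ws"].notna()
        pd.testing.assert_series_equal(filled.data.loc[untouched, "ws"],
                                       before.loc[untouched, "ws"])


class TestDailyAggregate:
    def test_fully_valid_constant_day(self):
        s = make_series({"pm25": [50.0] * 48})
        t = daily_aggregate(s)
        assert list(t.means["pm25"]) == [50.0, 50.0]
        assert list(t.completeness["pm25"]) == [1.0, 1.0]

    def test_17_hours_below_default_threshold(self):
        vals = [40.0] * 17 + [np.nan] * 7
        t = daily_aggregate(make_series({"pm25": vals}))
        assert np.isnan(t.means["pm25"].iloc[0])
        assert t.valid_hours["pm25"].iloc[0] == 17

    def test_18_hours_alternating_retained(self):
        vals = [40.0, 60.0] * 9 + [np.nan] * 6
        t = daily_aggregate(make_series({"pm25": vals}))
        assert t.means["pm25"].iloc[0] == pytest.approx(50.0)
        assert t.completeness["pm25"].iloc[0] == pytest.approx(0.75)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            daily_aggregate(make_series({"pm25": [1.0]}), min_completeness=0.0)
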