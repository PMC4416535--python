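"""Unit and property tests for the solar ephemeris chain."""

import math
from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from antfield.solar import (
    CivilInstant,
    GeoPosition,
    azimuth_angle,
    compute_ephemeris,
    day_of_year,
    decimal_day,
    decimal_day_of_year,
    declination,
    equation_of_time,
    fractional_year,
    gregorian_day_number,
    hour_angle,
    solar_noon,
    solar_time_offset,
    true_solar_time,
    zenith_angle,
)

GAMMA_GRID = np.linspace(0.0, 2.0 * math.pi, 100_000, endpoint=False)


class TestDomainTypes:
    @pytest.mark.parametrize(
        "lat,lon,tz",
        [(91.0, 0.0, 0.0), (-91.0, 0.0, 0.0), (0.0, 181.0, 0.0), (0.0, -200.0, 0.0),
         (0.0, 0.0, 15.0), (float("nan"), 0.0, 0.0)],
    )
    def test_position_rejects_out_of_range(self, lat, lon, tz):
        with pytest.raises(ValueError):
            GeoPosition(lat, lon, tz)

    def test_position_accepts_fractional_offset(self):
        assert GeoPosition(12.97, 77.59, 5.5).utc_offset == 5.5

    @pytest.mark.parametrize(
        "ymd_hms",
        [(2015, 2, 29, 0, 0, 0), (2015, 13, 1, 0, 0, 0), (2015, 6, 0, 0, 0, 0),
         (2015, 6, 1, 24, 0, 0), (2015, 6, 1, 0, 60, 0)],
    )
    def test_instant_rejects_invalid(self, ymd_hms):
        with pytest.raises(ValueError):
            CivilInstant(*ymd_hms)

    def test_instant_iso_round_trip(self):
        t = CivilInstant(2015, 6, 1, 9, 15, 3)
        assert CivilInstant.from_iso(t.isoformat()) == t


class TestCalendar:
    def test_consecutive_dates_differ_by_one(self):
        a = gregorian_day_number(CivilInstant(2014, 6, 15))
        b = gregorian_day_number(CivilInstant(2014, 6, 16))
        assert b - a == 1

    def test_february_march_boundary_non_leap(self):
        a = gregorian_day_number(CivilInstant(2014, 2, 28))
        b = gregorian_day_number(CivilInstant(2014, 3, 1))
        assert b - a == 1

    def test_continuity_1990_to_2030(self):
        """Brute-force: every consecutive date pair increments the count by 1."""
        d = date(1990, 1, 1)
        previous = gregorian_day_number(CivilInstant(d.year, d.month, d.day))
        while d < date(2030, 12, 31):
            d += timedelta(days=1)
            current = gregorian_day_number(CivilInstant(d.year, d.month, d.day))
            assert current - previous == 1, d
            previous = current

    def test_epoch_anchored_offset_is_constant(self):
        """Day count equals proleptic-Gregorian ordinal plus one fixed constant."""
        anchor = gregorian_day_number(CivilInstant(2000, 3, 1)) - date(2000, 3, 1).toordinal()
        d = date(2000, 3, 1)
        for _ in range(0, 3000, 7):
            assert gregorian_day_number(CivilInstant(d.year, d.month, d.day)) - d.toordinal() == anchor
            d += timedelta(days=7)

    def test_day_of_year_matches_calendar(self):
        assert day_of_year(CivilInstant(2015, 1, 1)) == 1
        assert day_of_year(CivilInstant(2015, 12, 31)) == 365
        assert day_of_year(CivilInstant(2016, 12, 31)) == 366
        assert day_of_year(CivilInstant(2014, 6, 15)) == date(2014, 6, 15).timetuple().tm_yday


class TestDecimalDay:
    @pytest.mark.parametrize(
        "hms,expected",
        [((0, 0, 0), 0.0), ((12, 0, 0), 0.5), ((6, 30, 0), 6 / 24 + 30 / 1440)],
    )
    def test_known_values(self, hms, expected):
        assert decimal_day(CivilInstant(2014, 6, 15, *hms)) == pytest.approx(expected, abs=1e-12)

    def test_seconds_contribute(self):
        t0 = CivilInstant(2014, 6, 15, 6, 30, 0)
        t1 = CivilInstant(2014, 6, 15, 6, 30, 30)
        assert decimal_day(t1) - decimal_day(t0) == pytest.approx(30 / 86400, abs=1e-15)

    def test_day_of_year_composition(self):
        t = CivilInstant(2014, 6, 15, 12, 0, 0)
        assert decimal_day_of_year(t) == day_of_year(t) + 0.5
        midnight = CivilInstant(2014, 6, 15)
        assert decimal_day_of_year(midnight) == day_of_year(midnight)

    def test_continuity_over_24h(self):
        t1 = CivilInstant(2014, 6, 15, 9, 30, 0)
        t2 = CivilInstant(2014, 6, 16, 9, 30, 0)
        assert decimal_day_of_year(t2) - decimal_day_of_year(t1) == pytest.approx(1.0)


class TestSeries:
    def test_equation_of_time_at_gamma_zero(self):
        # series collapses to 229.18 * (0.000075 + 0.001868 - 0.014615)
        assert equation_of_time(0.0) == pytest.approx(-2.9042, abs=1e-4)

    def test_declination_at_gamma_zero(self):
        # 0.006918 - 0.399912 - 0.006758 - 0.002697
        assert declination(0.0) == pytest.approx(-0.402449, abs=1e-6)

    @given(st.floats(min_value=-10.0, max_value=10.0))
    @settings(derandomize=True)
    def test_periodicity(self, gamma):
        two_pi = 2.0 * math.pi
        assert equation_of_time(gamma + two_pi) == pytest.approx(equation_of_time(gamma), abs=1e-9)
        assert declination(gamma + two_pi) == pytest.approx(declination(gamma), abs=1e-9)

    def test_equation_of_time_bound_dense_grid(self):
        values = np.array([equation_of_time(g) for g in GAMMA_GRID])
        assert values.min() >= -15.0 and values.max() <= 18.0

    def test_declination_bound_dense_grid(self):
        values = np.array([declination(g) for g in GAMMA_GRID])
        assert np.abs(values).max() <= 0.4100


class TestTimeChain:
    def test_offset_central_meridian_is_eot(self):
        p = GeoPosition(34.0, 15.0, 1.0)
        assert solar_time_offset(p, -3.3) == pytest.approx(-3.3)

    def test_four_minutes_per_degree(self):
        p = GeoPosition(0.0, 16.0, 1.0)
        assert solar_time_offset(p, 0.0) == pytest.approx(4.0)

    def test_hand_derived_chain(self):
        """The full worked chain at lon 9.97 E, UTC+1, gamma = 0."""
        p = GeoPosition(34.95, 9.97, 1.0)
        eot = equation_of_time(0.0)
        dec = declination(0.0)
        assert eot == pytest.approx(-2.9042, abs=1e-4)
        assert dec == pytest.approx(-0.402449, abs=1e-6)
        offset = solar_time_offset(p, eot)
        assert offset == pytest.approx(-23.0242, abs=1e-4)
        tst = true_solar_time(CivilInstant(2014, 1, 1, 13, 30, 30), offset)
        assert tst == pytest.approx(787.4758, abs=1e-4)
        ha = hour_angle(tst)
        assert ha == pytest.approx(16.8690, abs=1e-4)
        assert solar_noon(p, eot) == pytest.approx(743.0242, abs=1e-4)
        zen = zenith_angle(p, dec, ha)
        expected = math.degrees(
            math.acos(
                math.sin(math.radians(34.95)) * math.sin(dec)
                + math.cos(math.radians(34.95)) * math.cos(dec) * math.cos(math.radians(ha))
            )
        )
        assert zen == pytest.approx(expected, abs=1e-12)

    def test_true_solar_time_wraps(self):
        assert true_solar_time(CivilInstant(2014, 6, 15, 0, 0, 0), -10.0) == pytest.approx(1430.0)
        assert true_solar_time(CivilInstant(2014, 6, 15, 12, 0, 0), 0.0) == pytest.approx(720.0)

    def test_hour_angle_landmarks(self):
        assert hour_angle(720.0) == 0.0
        assert hour_angle(0.0) == -180.0

    @given(st.floats(min_value=-175.0, max_value=175.0), st.floats(min_value=-12.0, max_value=14.0),
           st.floats(min_value=-14.0, max_value=17.0))
    @settings(derandomize=True)
    def test_noon_consistency(self, lon, tz, eot):
        """Clock time = solar noon implies hour angle zero."""
        p = GeoPosition(10.0, lon, tz)
        noon = solar_noon(p, eot)
        tst = (noon + solar_time_offset(p, eot)) % 1440.0
        assert hour_angle(tst) == pytest.approx(0.0, abs=1e-6)


class TestAngles:
    def test_sun_at_zenith_equator_equinox(self):
        assert zenith_angle(GeoPosition(0.0, 0.0, 0.0), 0.0, 0.0) == pytest.approx(0.0, abs=1e-9)

    @given(st.floats(min_value=-88.0, max_value=88.0), st.floats(min_value=-0.41, max_value=0.41))
    @settings(derandomize=True)
    def test_noon_zenith_closed_form(self, lat_deg, dec_rad):
        """At zero hour angle the zenith is |latitude − declination|."""
        zen = zenith_angle(GeoPosition(lat_deg, 0.0, 0.0), dec_rad, 0.0)
        assert zen == pytest.approx(abs(lat_deg - math.degrees(dec_rad)), abs=1e-6)

    def test_noon_azimuth_due_south_for_northern_observer(self):
        assert azimuth_angle(GeoPosition(45.0, 0.0, 0.0), 0.0, 0.0) == pytest.approx(180.0)

    @given(
        st.floats(min_value=-89.0, max_value=89.0),
        st.floats(min_value=-0.41, max_value=0.41),
        st.floats(min_value=0.5, max_value=179.0),
    )
    @settings(derandomize=True)
    def test_azimuth_mirror_symmetry(self, lat_deg, dec_rad, ha):
        """Morning and afternoon bearings mirror about the meridian."""
        p = GeoPosition(lat_deg, 0.0, 0.0)
        total = (azimuth_angle(p, dec_rad, -ha) + azimuth_angle(p, dec_rad, ha)) % 360.0
        assert min(total, 360.0 - total) == pytest.approx(0.0, abs=1e-6)

    def test_azimuth_degenerate_pole_warns(self):
        with pytest.warns(UserWarning):
            assert azimuth_angle(GeoPosition(90.0, 0.0, 0.0), math.pi / 2.0, 30.0) == 0.0


class TestComposition:
    def test_fields_equal_standalone_operations(self):
        t = CivilInstant(2021, 3, 20, 10, 30, 15)
        p = GeoPosition(-23.5, 133.2, 9.5)
        e = compute_ephemeris(t, p)
        gamma = fractional_year(t)
        assert e.gregorian_day_number == gregorian_day_number(t)
        assert e.decimal_day == decimal_day(t)
        assert e.decimal_day_of_year == decimal_day_of_year(t)
        assert e.fractional_year == gamma
        assert e.equation_of_time == equation_of_time(gamma)
        assert e.declination == declination(gamma)
        assert e.solar_time_offset == solar_time_offset(p, e.equation_of_time)
        assert e.true_solar_time == true_solar_time(t, e.solar_time_offset)
        assert e.hour_angle == hour_angle(e.true_solar_time)
        assert e.zenith_angle == zenith_angle(p, e.declination, e.hour_angle)
        assert e.azimuth_angle == azimuth_angle(p, e.declination, e.hour_angle)
        assert e.solar_noon == solar_noon(p, e.equation_of_time)

    def test_deterministic(self):
        t = CivilInstant(2021, 3, 20, 10, 30, 15)
        p = GeoPosition(-23.5, 133.2, 9.5)
        assert compute_ephemeris(t, p) == compute_ephemeris(t, p)

    def test_ranges(self):
        for day in range(1, 360, 30):
            d = date(2015, 1, 1) + timedelta(days=day)
            e = compute_ephemeris(
                CivilInstant(d.year, d.month, d.day, 15, 20, 0), GeoPosition(50.0, -120.0, -8.0)
            )
            assert 0.0 <= e.true_solar_time < 1440.0
            assert -180.0 <= e.hour_angle < 180.0
            assert 0.0 <= e.zenith_angle <= 180.0
            assert 0.0 <= e.azimuth_angle < 360.0


class TestOracleEquivalence:
    """Agreement with the independently coded NOAA reference implementation."""

    def _grid(self):
        from acceptance import evaluation_grid

        return evaluation_grid()

    def test_solar_time_and_azimuth_match_reference(self):
        from noaa_reference import solar_position

        for t, p in self._grid():
            ours = compute_ephemeris(t, p)
            ref = solar_position(
                t.year, t.month, t.day, t.hour, t.minute, t.second,
                p.latitude, p.longitude, p.utc_offset,
            )
            assert abs(ours.true_solar_time - ref["true_solar_time"]) <= 0.25
            if ref["zenith"] >= 1.0:
                diff = abs(ours.azimuth_angle - ref["azimuth"]) % 360.0
                assert min(diff, 360.0 - diff) <= 0.5
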