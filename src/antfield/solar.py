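"""Offline solar ephemeris from civil clock time and geographic position.

Implements the low-precision NOAA solar-position chain (truncated Fourier
series in the fractional year) so that solar time, solar noon, hour angle,
zenith and azimuth can be computed in the field with no network, GPS or
almanac tables.  Accuracy is that of the NOAA "General Solar Position
Calculations" series: equation of time to a few seconds, angles to a few
hundredths of a degree — ample for orienting behavioural observations
(e.g. relating a desert ant's homing direction to the solar azimuth).

Conventions
-----------
* All trigonometry is done in radians; degree-valued quantities (latitude,
  hour angle) are converted at call boundaries.
* True solar time is minutes past local civil midnight, wrapped to
  [0, 1440); the hour angle is therefore in [-180, 180) degrees, negative
  before solar noon.
* Azimuth is reported north-referenced, clockwise, in [0, 360) — the
  convention of the NOAA web calculator (0 = north, 90 = east).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from datetime import date as _date, datetime as _datetime

__all__ = [
    "GeoPosition",
    "CivilInstant",
    "SolarEphemeris",
    "gregorian_day_number",
    "day_of_year",
    "decimal_day",
    "decimal_day_of_year",
    "fractional_year",
    "equation_of_time",
    "declination",
    "solar_time_offset",
    "true_solar_time",
    "hour_angle",
    "zenith_angle",
    "azimuth_angle",
    "solar_noon",
    "compute_ephemeris",
]

PI = math.pi
MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class GeoPosition:
    """Observer location: latitude/longitude in decimal degrees, UTC offset in hours.

    Latitude is positive north, longitude positive east.  The UTC offset is
    hours east of Greenwich (e.g. +1.0 for Tunisia); fractional offsets such
    as +5.5 are accepted.
    """

    latitude: float
    longitude: float
    utc_offset: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.latitude) and -90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude {self.latitude!r} outside [-90, +90]")
        if not (math.isfinite(self.longitude) and -180.0 <= self.longitude <= 180.0):
            raise ValueError(f"longitude {self.longitude!r} outside [-180, +180]")
        if not (math.isfinite(self.utc_offset) and -12.0 <= self.utc_offset <= 14.0):
            raise ValueError(f"utc_offset {self.utc_offset!r} outside [-12, +14]")


@dataclass(frozen=True, order=True)
class CivilInstant:
    """A local civil date and clock time (proleptic Gregorian calendar)."""

    year: int
    month: int
    day: int
    hour: int = 0
    minute: int = 0
    second: int = 0

    def __post_init__(self) -> None:
        try:
            _date(self.year, self.month, self.day)
        except ValueError as exc:
            raise ValueError(f"invalid calendar date {self.year}-{self.month}-{self.day}: {exc}") from exc
        if not (0 <= self.hour <= 23 and 0 <= self.minute <= 59 and 0 <= self.second <= 59):
            raise ValueError(
                f"invalid clock time {self.hour:02d}:{self.minute:02d}:{self.second:02d}"
            )

    @classmethod
    def from_datetime(cls, dt: _datetime) -> "CivilInstant":
        return cls(dt.year, dt.month, dt.day, dt.hour, dt.minute, dt.second)

    @classmethod
    def from_iso(cls, text: str) -> "CivilInstant":
        return cls.from_datetime(_datetime.fromisoformat(text))

    def isoformat(self) -> str:
        return (
            f"{self.year:04d}-{self.month:02d}-{self.day:02d}"
            f"T{self.hour:02d}:{self.minute:02d}:{self.second:02d}"
        )


@dataclass(frozen=True)
class SolarEphemeris:
    """Every quantity of the solar chain for one instant and position.

    Units: day counts in days, ``fractional_year`` and ``declination`` in
    radians, ``equation_of_time``/``solar_time_offset``/``true_solar_time``/
    ``solar_noon`` in minutes (times are minutes past local civil midnight),
    angles in degrees.
    """

    gregorian_day_number: int
    decimal_day: float
    decimal_day_of_year: float
    fractional_year: float
    equation_of_time: float
    declination: float
    solar_time_offset: float
    true_solar_time: float
    hour_angle: float
    zenith_angle: float
    azimuth_angle: float
    solar_noon: float


def gregorian_day_number(t: CivilInstant) -> int:
    """Absolute day count of the proleptic Gregorian calendar.

    365·y + ⌊y/4⌋ − ⌊y/100⌋ + ⌊y/400⌋ + ⌊(m+1)·306/10⌋ + d − 62, after the
    March-based remap that treats January and February as months 13 and 14
    of the previous year.  Consecutive dates differ by exactly one.
    """
    y, m, d = t.year, t.month, t.day
    if m <= 2:
        m += 12
        y -= 1
    return 365 * y + y // 4 - y // 100 + y // 400 + ((m + 1) * 306) // 10 + (d - 62)


def day_of_year(t: CivilInstant) -> int:
    """Day within the calendar year, 1-based (Jan 1 → 1, Dec 31 → 365/366)."""
    return gregorian_day_number(t) - gregorian_day_number(CivilInstant(t.year - 1, 12, 31))


def decimal_day(t: CivilInstant) -> float:
    """Clock time as a fraction of the day in [0, 1)."""
    return t.hour / 24.0 + t.minute / 1440.0 + t.second / 86400.0


def decimal_day_of_year(t: CivilInstant) -> float:
    """Day of the year plus the fraction of the current day."""
    return day_of_year(t) + decimal_day(t)


def fractional_year(t: CivilInstant) -> float:
    """Date-time as an angle through the year (radians, ~0 on Jan 1 noon).

    γ = (2π/365)·(doy − 1 + (h − 12)/24) with the fractional clock hour h;
    equivalently (2π/365)·(decimal_day_of_year − 1.5).  Leap years reuse the
    365-day period, which is part of the low-precision series' error budget.
    """
    return (2.0 * PI / 365.0) * (decimal_day_of_year(t) - 1.5)


def equation_of_time(gamma: float) -> float:
    """Equation of time in minutes: apparent solar time minus mean clock time."""
    return 229.18 * (
        0.000075
        + 0.001868 * math.cos(gamma)
        - 0.032077 * math.sin(gamma)
        - 0.014615 * math.cos(2.0 * gamma)
        - 0.040849 * math.sin(2.0 * gamma)
    )


def declination(gamma: float) -> float:
    """Solar declination in radians (truncated Fourier series, |δ| ≤ 0.41)."""
    return (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2.0 * gamma)
        + 0.000907 * math.sin(2.0 * gamma)
        - 0.002697 * math.cos(3.0 * gamma)
        + 0.00148 * math.sin(3.0 * gamma)
    )


def solar_time_offset(p: GeoPosition, eot: float) -> float:
    """Minutes to add to clock time to obtain true solar time.

    Four minutes per degree of longitude east of the zone's central
    meridian (15°·utc_offset), plus the equation of time.
    """
    return 4.0 * (p.longitude - 15.0 * p.utc_offset) + eot


def true_solar_time(t: CivilInstant, offset: float) -> float:
    """True solar time in minutes past local midnight, wrapped to [0, 1440)."""
    return (t.hour * 60.0 + t.minute + t.second / 60.0 + offset) % MINUTES_PER_DAY


def hour_angle(tst: float) -> float:
    """Solar hour angle in degrees, tst/4 − 180: zero at solar noon, negative before."""
    return tst / 4.0 - 180.0


def zenith_angle(p: GeoPosition, dec: float, ha: float) -> float:
    """Angle between the sun and the local vertical, degrees in [0, 180].

    cos θz = sin φ sin δ + cos φ cos δ cos H; the cosine is clamped to
    [−1, 1] before the arccosine to absorb rounding at grazing geometry.
    """
    phi = math.radians(p.latitude)
    h = math.radians(ha)
    cos_zen = math.sin(phi) * math.sin(dec) + math.cos(phi) * math.cos(dec) * math.cos(h)
    return math.degrees(math.acos(max(-1.0, min(1.0, cos_zen))))


def azimuth_angle(p: GeoPosition, dec: float, ha: float) -> float:
    """Compass bearing of the sun, degrees clockwise from north in [0, 360).

    Computed south-referenced as atan2(sin H, cos H sin φ − tan δ cos φ)
    and rotated by 180°.  At the degenerate pole/solstice geometry
    (φ = ±90° with δ = ±π/2) every bearing is equivalent; 0 is returned
    with a warning.
    """
    phi = math.radians(p.latitude)
    h = math.radians(ha)
    if abs(math.cos(phi)) < 1e-12 and abs(abs(dec) - PI / 2.0) < 1e-12:
        warnings.warn("azimuth undefined at the pole with the sun at the celestial pole; returning 0")
        return 0.0
    south_ref = math.atan2(math.sin(h), math.cos(h) * math.sin(phi) - math.tan(dec) * math.cos(phi))
    return (math.degrees(south_ref) + 180.0) % 360.0


def solar_noon(p: GeoPosition, eot: float) -> float:
    """Clock time of the sun's meridian crossing, minutes past local midnight.

    720 − 4·(longitude − 15·utc_offset) − EoT, so that plugging the result
    back through the chain yields a zero hour angle.
    """
    return 720.0 - 4.0 * (p.longitude - 15.0 * p.utc_offset) - eot


def compute_ephemeris(t: CivilInstant, p: GeoPosition) -> SolarEphemeris:
    """Run the full sequential chain and return every intermediate.

    Order: day number → decimal day of year → fractional year → equation of
    time → solar noon → declination → solar time offset → true solar time →
    hour angle → zenith → azimuth.  Each stage consumes upstream outputs, so
    every field equals the corresponding standalone function applied to them.
    """
    gdn = gregorian_day_number(t)
    dd = decimal_day(t)
    ddoy = decimal_day_of_year(t)
    gamma = fractional_year(t)
    eot = equation_of_time(gamma)
    noon = solar_noon(p, eot)
    dec = declination(gamma)
    offset = solar_time_offset(p, eot)
    tst = true_solar_time(t, offset)
    ha = hour_angle(tst)
    zen = zenith_angle(p, dec, ha)
    az = azimuth_angle(p, dec, ha)
    return SolarEphemeris(
        gregorian_day_number=gdn,
        decimal_day=dd,
        decimal_day_of_year=ddoy,
        fractional_year=gamma,
        equation_of_time=eot,
        declination=dec,
        solar_time_offset=offset,
        true_solar_time=tst,
        hour_angle=ha,
        zenith_angle=zen,
        azimuth_angle=az,
        solar_noon=noon,
    )
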