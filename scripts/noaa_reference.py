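"""Independent reference implementation of the NOAA solar-position equations.

Serves as the cross-check oracle for the package's solar chain.  It follows
NOAA's "General Solar Position Calculations" directly and is deliberately
coded along a different path from ``antfield.solar``:

* day-of-year comes from the standard library calendar (``datetime``),
  not from the package's Gregorian day-number arithmetic;
* the fractional year uses NOAA's published form with the fractional hour;
* trigonometry is organised in degrees with explicit conversions;
* the azimuth uses the arccosine form with a morning/afternoon branch,
  not the package's atan2 form.

The equation-of-time and declination Fourier coefficients are the NOAA
series itself and are therefore necessarily the same numbers.
"""

from __future__ import annotations

import math
from datetime import date as _date


def solar_position(
    year: int,
    month: int,
    day: int,
    hour: int,
    minute: int,
    second: int,
    latitude: float,
    longitude: float,
    utc_offset: float,
) -> dict:
    """Return NOAA-reference solar quantities for one civil instant/position.

    Keys: ``eqtime`` (min), ``declination`` (rad), ``true_solar_time`` (min
    past local midnight, wrapped to [0, 1440)), ``hour_angle`` (deg),
    ``zenith`` (deg), ``azimuth`` (deg clockwise from north, [0, 360)),
    ``solar_noon`` (min past local midnight).
    """
    doy = _date(year, month, day).timetuple().tm_yday
    frac_hour = hour + minute / 60.0 + second / 3600.0
    gamma = 2.0 * math.pi / 365.0 * (doy - 1 + (frac_hour - 12.0) / 24.0)

    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(gamma)
        - 0.032077 * math.sin(gamma)
        - 0.014615 * math.cos(2.0 * gamma)
        - 0.040849 * math.sin(2.0 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2.0 * gamma)
        + 0.000907 * math.sin(2.0 * gamma)
        - 0.002697 * math.cos(3.0 * gamma)
        + 0.00148 * math.sin(3.0 * gamma)
    )

    time_offset = eqtime + 4.0 * longitude - 60.0 * utc_offset
    tst = (hour * 60.0 + minute + second / 60.0 + time_offset) % 1440.0
    ha_deg = tst / 4.0 - 180.0

    lat_rad = math.radians(latitude)
    cos_zenith = math.sin(lat_rad) * math.sin(decl) + math.cos(lat_rad) * math.cos(
        decl
    ) * math.cos(math.radians(ha_deg))
    cos_zenith = min(1.0, max(-1.0, cos_zenith))
    zenith_deg = math.degrees(math.acos(cos_zenith))

    sin_zenith = math.sin(math.radians(zenith_deg))
    if sin_zenith < 1e-12 or abs(math.cos(lat_rad)) < 1e-12:
        azimuth_deg = 0.0
    else:
        cos_az = (math.sin(decl) - math.sin(lat_rad) * cos_zenith) / (
            math.cos(lat_rad) * sin_zenith
        )
        cos_az = min(1.0, max(-1.0, cos_az))
        az_from_north = math.degrees(math.acos(cos_az))
        azimuth_deg = az_from_north if ha_deg < 0.0 else (360.0 - az_from_north) % 360.0

    noon = (720.0 - 4.0 * longitude + 60.0 * utc_offset - eqtime) % 1440.0

    return {
        "eqtime": eqtime,
        "declination": decl,
        "true_solar_time": tst,
        "hour_angle": ha_deg,
        "zenith": zenith_deg,
        "azimuth": azimuth_deg,
        "solar_noon": noon,
    }
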