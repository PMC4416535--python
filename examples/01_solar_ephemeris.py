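"""Compute a full solar ephemeris for one instant and place — no GPS, no network.

Scenario: a field observer on a Tunisian salt pan (34°57' N, 9°58.2' E,
UTC+1) wants the solar timing and angles at 13:30:30 local time on
15 June 2014.
"""

from antfield import CivilInstant, GeoPosition, compute_ephemeris, parse_coordinate

position = GeoPosition(
    latitude=parse_coordinate("34 57"),   # degrees + decimal minutes
    longitude=parse_coordinate("9 58.2"),
    utc_offset=1.0,
)
instant = CivilInstant(2014, 6, 15, 13, 30, 30)

eph = compute_ephemeris(instant, position)

print(f"true solar time : {eph.true_solar_time:9.4f} min past midnight "
      f"({eph.true_solar_time / 60:.2f} solar hours)")
print(f"solar noon      : {eph.solar_noon:9.4f} min  (local clock "
      f"{int(eph.solar_noon // 60):02d}:{int(eph.solar_noon % 60):02d})")
print(f"equation of time: {eph.equation_of_time:9.4f} min")
print(f"declination     : {eph.declination:9.6f} rad")
print(f"hour angle      : {eph.hour_angle:9.4f} deg  (positive: afternoon)")
print(f"zenith angle    : {eph.zenith_angle:9.4f} deg  (0 = sun overhead)")
print(f"azimuth angle   : {eph.azimuth_angle:9.4f} deg clockwise from north")
# The azimuth is the compass bearing an ant's homing direction can be
# referenced against; the hour angle says how far past solar noon we are.
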