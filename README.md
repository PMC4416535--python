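# antfield

Offline solar ephemeris and campaign data management for behavioural field
studies of arthropods.

Field work on visually navigating insects — the motivating case is the
desert ant *Cataglyphis fortis*, which steers by a celestial compass —
needs the sun's position and solar time *at the moment of each
observation*, often in places with no network, no GPS and no time for
almanac tables. `antfield` provides:

* a **solar module** computing the full NOAA-style chain (equation of
  time, declination, true solar time, solar noon, hour angle, zenith and
  azimuth) from nothing but civil date/time, latitude, longitude and UTC
  offset;
* a **campaign datastore** (single-file SQLite) for experiments, feeder
  stations, colour-marked individuals and their visits, where every visit
  is automatically annotated with the solar ephemeris computed from the
  parent experiment's coordinates;
* **export/merge/backup tooling**: timestamped collision-proof backups,
  passphrase-guarded bulk deletion, conversion to an Excel workbook or a
  CSV set, and content-deduplicating merge of multiple campaign files;
* a **synthetic campaign generator** for reproducible test fixtures;
* a thin **CLI** (`antfield`) wiring all of the above.

## The model

For a civil instant with day-of-year $N$ and fractional hour $h$, the
fractional year is

$$\gamma = \frac{2\pi}{365}\left(N - 1 + \frac{h-12}{24}\right)$$

from which the equation of time (minutes) and solar declination (radians)
follow as truncated Fourier series:

$$\mathrm{EoT} = 229.18\,(0.000075 + 0.001868\cos\gamma - 0.032077\sin\gamma - 0.014615\cos 2\gamma - 0.040849\sin 2\gamma)$$

$$\delta = 0.006918 - 0.399912\cos\gamma + 0.070257\sin\gamma - 0.006758\cos 2\gamma + 0.000907\sin 2\gamma - 0.002697\cos 3\gamma + 0.00148\sin 3\gamma$$

True solar time is clock time plus the offset
$4(\lambda - 15\,\mathrm{tz}) + \mathrm{EoT}$ minutes (longitude
$\lambda$ east-positive), the hour angle is $H = \mathrm{TST}/4 - 180°$,
and the zenith and azimuth come from the spherical triangle

$$\cos\theta_z = \sin\varphi\sin\delta + \cos\varphi\cos\delta\cos H,\qquad
A = \operatorname{atan2}(\sin H,\ \cos H\sin\varphi - \tan\delta\cos\varphi) + 180°$$

with azimuth reported clockwise from north in [0°, 360°). Solar noon is
$720 - 4(\lambda - 15\,\mathrm{tz}) - \mathrm{EoT}$ minutes past local
midnight.

## Worked example

```python
from antfield import CivilInstant, GeoPosition, compute_ephemeris, parse_coordinate

position = GeoPosition(parse_coordinate("34 57"), parse_coordinate("9 58.2"), utc_offset=1.0)
eph = compute_ephemeris(CivilInstant(2014, 6, 15, 13, 30, 30), position)
```

prints (see `examples/01_solar_ephemeris.py`):

```
true solar time :  790.3394 min past midnight (13.17 solar hours)
solar noon      :  740.1606 min  (local clock 12:20)
equation of time:   -0.0406 min
declination     :  0.406469 rad
hour angle      :   17.5848 deg  (positive: afternoon)
zenith angle    :   19.2343 deg  (0 = sun overhead)
azimuth angle   :  237.3907 deg clockwise from north
```

So at 13:30:30 civil time the sun is 70 minutes past the local meridian
(hour angle +17.6°), 19.2° from the vertical, bearing 237° — west-south-west,
as expected for an early summer afternoon at 35° N. The same computation is
available from the shell:

```sh
antfield solar --lat "34 57" --lon "9 58.2" --tz 1 --date 2014-06-15 --time 13:30:30
```

The other examples walk through a miniature campaign
(`02_field_campaign.py`), backup/export/merge (`03_export_and_merge.py`)
and the synthetic generator (`04_synthetic_campaign.py`). A campaign can be
simulated from the shell with
`antfield simulate --out campaign.sqlite --seed 7` (optionally
`--spec spec.json`, a JSON object with any `CampaignSpec` fields:
`n_experiments`, `feeders_per_experiment`, `individuals_per_experiment`,
`visits_per_individual`, `day_window`, `latitude_range`, `longitude_range`,
`utc_offset`, `start_date`, `palette`, `seed`).

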