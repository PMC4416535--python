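# Methods

## The solar chain

The solar module implements the low-precision NOAA solar-position
algorithm: a truncated Fourier expansion of the equation of time and of
the solar declination in the fractional year, followed by the standard
spherical-astronomy conversion to hour angle, zenith and azimuth. The
chain runs in a fixed sequential order — day number, decimal day of year,
fractional year, equation of time, solar noon, declination, solar time
offset, true solar time, hour angle, zenith, azimuth — and
`compute_ephemeris` returns every intermediate, since field protocols use
several of them directly (solar time for activity phase, azimuth for
bearing references).

Assumptions and inherent error budget:

* The fractional year uses a 365-day period; leap days are absorbed as a
  phase error of up to ~1 day/4 years, which is part of the series'
  design accuracy (equation of time to a few seconds, declination to
  ~0.001 rad, angles to a few hundredths of a degree).
* No atmospheric refraction and no sunrise/sunset logic: the intended use
  is daytime behavioural observation, where the sun is well above the
  horizon and refraction is negligible at this precision.
* Latitude/longitude/UTC offset are taken as entered; the toolkit is
  explicitly for sites without GPS, so coordinates come from maps or known
  site surveys, and the degrees-plus-decimal-minutes parser mirrors how
  they are usually written down.

Numerical choices:

* π at full machine precision; all trigonometry in radians, with
  degree-valued fields converted at call boundaries only.
* Day arithmetic is exact integer arithmetic on a Gregorian day-number
  formula (March-based month remap); the day-of-year used by the
  fractional year is the difference of two such day numbers, so the whole
  calendar path is one primitive. Its correctness is pinned by a
  brute-force continuity test over 1990–2030 and an epoch-anchored
  comparison against the standard library's ordinal counter.
* The decimal day includes seconds (s/86400) so the sub-minute terms of
  true solar time and of the fractional year stay consistent.
* True solar time is wrapped into [0, 1440) minutes, hence the hour angle
  lies in [−180°, 180°), negative before solar noon. Solar noon is
  returned in local clock minutes, 720 − 4(λ − 15·tz) − EoT, which makes
  the noon/hour-angle consistency identity exact.
* The cosine of the zenith is clamped to [−1, 1] before the arccosine.
* Azimuth uses atan2 on the south-referenced form and is rotated to the
  north-referenced clockwise convention of the NOAA web calculator. The
  only degenerate case (observer at a pole with the sun at the celestial
  pole) returns 0° with a warning.

Validation is dual-route: the package's chain is compared point-by-point
against `scripts/noaa_reference.py`, a deliberately independent coding of
the same NOAA equations (calendar day-of-year from `datetime`, degree-
organised trigonometry, arccosine azimuth with a morning/afternoon branch).
On a fixed 1,000-point grid of dates 2000–2030, times 06:00–18:00 and
|latitude| ≤ 60°, true solar time agrees to well under 0.25 min and
azimuth to under 0.5° away from near-zenith geometry; the acceptance
script reports the corresponding mean percent agreements. The Fourier
coefficients themselves are shared between the two routes — they are the
published series — so the cross-check validates everything around them:
calendar handling, time bookkeeping, unit conversions and the angle
formulas.

"Percent agreement" is operationalised as 100·(1 − mean relative absolute
deviation); other readings (fraction of matching digits, share of points
within a tolerance) exist, and this one was chosen because it is the
strictest of the obvious candidates that is still well-defined for
continuous quantities.

## The campaign store

One campaign = one SQLite file with tables `experiment`, `feeder`,
`registration`, `visit` and a `meta` table carrying the schema version
(currently 1). Ids are `AUTOINCREMENT`, so an id is never reused after a
deletion — important when field notes refer to records by number. Foreign
keys are enforced; deleting an experiment cascades to its feeders,
registrations and visits, while deleting a feeder only nulls the optional
feeder reference on its visits (the observation itself belongs to the
individual, not to the bait station).

Timestamps are stored as ISO-8601 local civil time together with the
experiment's UTC offset; no time-zone database is involved, matching the
manual-zone-entry workflow of offline field sites.

Every visit row stores the complete solar ephemeris computed from its
timestamp and the parent experiment's coordinates at insertion time. The
annotation is *derived* data and is kept recomputable: values are stored
as binary doubles and `verify_ephemerides()` recomputes the whole chain
for every visit and demands bit-for-bit equality. Registration enforces
exactly three colour dots per individual and name uniqueness within an
experiment (the same name may recur across experiments). "Quick" visit
entry is the same operation with the feeder argument omitted; registering
an unseen individual mid-experiment is a registration followed by a visit.

## Export, merge, backup, guarded deletion

* **Backup** copies the database file byte-for-byte to
  `antfield_YYYYMMDD_HHMMSS.sqlite`; second-resolution naming makes
  successive backups collision-free, and the name parses back to its
  timestamp. The copy is staged and atomically renamed so a failing
  destination leaves no partial file.
* **Bulk deletion** requires a security key compared in constant time
  against the configured passphrase; a mismatch changes nothing. Deletion
  counts include cascade effects.
* **Conversion** writes one worksheet (or one CSV file) per table, headers
  identical to the schema, rows in id order, numeric columns numeric. The
  CSV route round-trips doubles bit-exactly; the xlsx route carries the
  OOXML number format's 16 significant digits (≤ 1 ulp), which is the
  format's own precision, so the CSV set is the archival route.
* **Merge** processes tables top-down (experiments → feeders →
  registrations → visits), renumbers ids sequentially and remaps child
  references through their parents' new ids. Two rows are duplicates when
  all non-id fields — with remapped parent ids — are equal, so merging a
  file with its own copy is a no-op and merge is idempotent. Inputs must
  share the schema version; on mismatch nothing is written. The returned
  report satisfies rows_out = rows_in − duplicates_dropped per table and
  includes the full old→new id mapping per source file.

## The synthetic generator

`generate_campaign` emulates the field protocol, not ant behaviour: per
experiment it places feeders, registers individuals with unique three-dot
colour codes (ordered triples drawn without replacement from the triple
space of an 8-colour palette; repeats within a triple are allowed, as with
real paint dots), and draws each individual's visit count from a Poisson
distribution, with arrival times i.i.d. uniform in the daily observation
window — the standard conditional construction of a homogeneous Poisson
process. A homogeneous rate is a stand-in: real foraging is strongly
temperature-driven and thus time-of-day dependent, individuals differ, and
visits cluster; none of that is modelled. Passing tests therefore
demonstrate that the *plumbing* (storage, annotation, export, merge)
handles realistic volumes and value ranges, not that the generator mimics
field statistics.

Defaults portray the motivating study system — a Tunisian salt-pan site in
early June (latitude 33.5–35° N, longitude 9–10.5° E, UTC+1), observations
08:00–18:00 local, 3 experiments on consecutive days, 2 feeders and 10
marked foragers each, mean 10 visits per forager. These are typical
single-observer session sizes for mark–resight feeder studies; tests use
smaller or larger values where the property under test requires it (e.g.
200 individuals for the Poisson goodness-of-fit).

Generation goes through the ordinary datastore API, so a generated file
satisfies every store invariant by construction, and identical spec + seed
reproduces the file byte-for-byte (single-threaded SQLite writes are
deterministic).

## Known limitations

* The solar series is the low-precision NOAA chain: no refraction, no
  sub-arcsecond ephemeris, 365-day year. For sub-0.01° work use a full
  ephemeris library.
* Azimuth relative-agreement statistics are sensitive to bearings near 0°
  (the wrap point); the acceptance comparison excludes near-zenith points,
  where the bearing itself is ill-conditioned.
* The store is single-writer; concurrent field devices should each keep
  their own file and merge afterwards — that is the intended workflow.
* The passphrase guards against accidental deletion, not against an
  adversary with file access.
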