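"""Embedded relational store for arthropod field campaigns.

A campaign is a single-file SQLite database holding four entity kinds:

* **experiment** — name, date/time, free notes and the geographic frame
  (latitude, longitude, UTC offset) of one field session;
* **feeder** — an optional baited station belonging to an experiment;
* **registration** — a colour-marked individual (three-dot paint code),
  unique by name within its experiment;
* **visit** — one observation of a registered individual, optionally at a
  feeder, automatically annotated with the full solar ephemeris computed
  from the visit timestamp and the parent experiment's coordinates.

The solar annotation is the point of the design: every visit row carries
solar time, hour angle, zenith and azimuth at the moment of observation,
recomputable bit-for-bit from (timestamp, experiment position), so the
behavioural record needs no GPS and no post-hoc almanac session.

Referential integrity is enforced by SQLite foreign keys.  Deleting an
experiment cascades to its feeders, registrations and visits; deleting a
feeder nulls the (optional) feeder reference on its visits rather than
destroying the observations.  Ids are AUTOINCREMENT and never reused.
"""

from __future__ import annotations

import re
import sqlite3
from dataclasses import dataclass, fields as _dc_fields
from datetime import datetime as _datetime
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .solar import CivilInstant, GeoPosition, SolarEphemeris, compute_ephemeris

__all__ = [
    "SCHEMA_VERSION",
    "TABLES",
    "EPHEMERIS_COLUMNS",
    "DatastoreError",
    "NotFoundError",
    "ReferentialError",
    "UniquenessError",
    "CoordinateFormatError",
    "SchemaVersionError",
    "parse_coordinate",
    "Experiment",
    "FeederStation",
    "RegisteredIndividual",
    "Visit",
    "CampaignDatabase",
]

SCHEMA_VERSION = 1
TABLES = ("experiment", "feeder", "registration", "visit")

# Column order mirrors the computation chain; stored as REAL (binary doubles)
# so the recomputation invariant can be asserted exactly.
EPHEMERIS_COLUMNS = tuple(f.name for f in _dc_fields(SolarEphemeris))


class DatastoreError(Exception):
    """Base class for campaign-database errors."""


class NotFoundError(DatastoreError):
    """Referenced id does not exist."""


class ReferentialError(DatastoreError):
    """An operation would violate a parent/child relationship."""


class UniquenessError(DatastoreError):
    """A uniqueness rule (e.g. individual name within experiment) was violated."""


class SchemaVersionError(DatastoreError):
    """The file's schema version does not match this library's."""


class CoordinateFormatError(ValueError):
    """Coordinate text matches neither the decimal nor the degrees-minutes dialect."""


_DECIMAL_RE = re.compile(r"^[+-]?\d+(?:\.\d+)?$")
_DEG_MIN_RE = re.compile(r"^([+-]?)(\d+(?:\.\d+)?)\s+(\d+(?:\.\d+)?)$")


def parse_coordinate(text: Union[str, float, int]) -> float:
    """Parse a coordinate given in decimal degrees or degrees + decimal minutes.

    Two dialects are accepted, matching how field workers read positions off
    a map or a handheld unit: ``"34.05"`` (decimal degrees) and ``"34 3.0"``
    (whole degrees, decimal minutes).  In the degrees-minutes dialect the
    sign applies to the whole value: ``"-5 15"`` → −5.25.

    Raises :class:`CoordinateFormatError` for unparseable text or minutes
    outside [0, 60).
    """
    if isinstance(text, (int, float)):
        return float(text)
    s = text.strip()
    if _DECIMAL_RE.match(s):
        return float(s)
    m = _DEG_MIN_RE.match(s)
    if m:
        sign = -1.0 if m.group(1) == "-" else 1.0
        degrees = float(m.group(2))
        minutes = float(m.group(3))
        if minutes >= 60.0:
            raise CoordinateFormatError(
                f"minutes component {minutes} must be < 60 in degrees-minutes value {text!r}"
            )
        return sign * (degrees + minutes / 60.0)
    raise CoordinateFormatError(
        f"{text!r} is neither decimal degrees ('34.05') nor degrees-minutes ('34 3.0')"
    )


@dataclass(frozen=True)
class Experiment:
    id: int
    name: str
    date: str
    time: str
    position: GeoPosition
    notes: Optional[str] = None


@dataclass(frozen=True)
class FeederStation:
    id: int
    experiment_id: int
    label: str
    notes: Optional[str] = None


@dataclass(frozen=True)
class RegisteredIndividual:
    id: int
    experiment_id: int
    name_or_number: str
    color_code: tuple


@dataclass(frozen=True)
class Visit:
    id: int
    individual_id: int
    feeder_id: Optional[int]
    timestamp: CivilInstant
    ephemeris: SolarEphemeris
    notes: Optional[str] = None


_SCHEMA = """
CREATE TABLE meta (
    schema_version INTEGER NOT NULL
);
CREATE TABLE experiment (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    name TEXT NOT NULL,
    date TEXT NOT NULL,
    time TEXT NOT NULL,
    latitude REAL NOT NULL,
    longitude REAL NOT NULL,
    utc_offset REAL NOT NULL,
    notes TEXT
);
CREATE TABLE feeder (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    experiment_id INTEGER NOT NULL REFERENCES experiment(id) ON DELETE CASCADE,
    label TEXT NOT NULL,
    notes TEXT
);
CREATE TABLE registration (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    experiment_id INTEGER NOT NULL REFERENCES experiment(id) ON DELETE CASCADE,
    name_or_number TEXT NOT NULL,
    color1 TEXT NOT NULL,
    color2 TEXT NOT NULL,
    color3 TEXT NOT NULL,
    UNIQUE (experiment_id, name_or_number)
);
CREATE TABLE visit (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    individual_id INTEGER NOT NULL REFERENCES registration(id) ON DELETE CASCADE,
    feeder_id INTEGER REFERENCES feeder(id) ON DELETE SET NULL,
    timestamp TEXT NOT NULL,
    utc_offset REAL NOT NULL,
    notes TEXT,
    {ephem_cols}
);
""".format(ephem_cols=",\n    ".join(
    f"{c} {'INTEGER' if c == 'gregorian_day_number' else 'REAL'} NOT NULL"
    for c in EPHEMERIS_COLUMNS
))

_UPDATABLE = {
    "experiment": {"name", "date", "time", "latitude", "longitude", "utc_offset", "notes"},
    "feeder": {"experiment_id", "label", "notes"},
    "registration": {"experiment_id", "name_or_number", "color1", "color2", "color3"},
    "visit": {"feeder_id", "notes"},
}


class CampaignDatabase:
    """A campaign store backed by one SQLite file (``":memory:"`` accepted).

    Usable as a context manager; commits are per-operation so a crash in the
    field loses at most the in-flight record.
    """

    def __init__(self, path: Union[str, Path]):
        self.path = str(path)
        existed = self.path == ":memory:" or Path(self.path).exists()
        self._conn = sqlite3.connect(self.path)
        self._conn.row_factory = sqlite3.Row
        self._conn.execute("PRAGMA foreign_keys = ON")
        if not existed or self._table_missing("meta"):
            with self._conn:
                self._conn.executescript(_SCHEMA)
                self._conn.execute("INSERT INTO meta (schema_version) VALUES (?)", (SCHEMA_VERSION,))
        else:
            found = self.schema_version()
            if found != SCHEMA_VERSION:
                raise SchemaVersionError(
                    f"{self.path}: expected schema version {SCHEMA_VERSION}, found {found}"
                )

    def _table_missing(self, name: str) -> bool:
        row = self._conn.execute(
            "SELECT 1 FROM sqlite_master WHERE type='table' AND name=?", (name,)
        ).fetchone()
        return row is None

    def schema_version(self) -> int:
        row = self._conn.execute("SELECT schema_version FROM meta").fetchone()
        if row is None:
            raise SchemaVersionError(f"{self.path}: no schema version recorded")
        return int(row[0])

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "CampaignDatabase":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- creation -----------------------------------------------------------

    def create_experiment(
        self,
        name: str,
        date: str,
        time: str,
        position: GeoPosition,
        notes: Optional[str] = None,
    ) -> Experiment:
        """Persist a new experiment; ``date``/``time`` are ISO strings.

        ``position`` may be built from raw field notes with
        :func:`parse_coordinate` for each axis.
        """
        if not isinstance(position, GeoPosition):
            raise TypeError("position must be a GeoPosition")
        with self._conn:
            cur = self._conn.execute(
                "INSERT INTO experiment (name, date, time, latitude, longitude, utc_offset, notes)"
                " VALUES (?, ?, ?, ?, ?, ?, ?)",
                (name, date, time, position.latitude, position.longitude, position.utc_offset, notes),
            )
        return self.get_experiment(cur.lastrowid)

    def add_feeder(self, experiment_id: int, label: str, notes: Optional[str] = None) -> FeederStation:
        self._require("experiment", experiment_id)
        with self._conn:
            cur = self._conn.execute(
                "INSERT INTO feeder (experiment_id, label, notes) VALUES (?, ?, ?)",
                (experiment_id, label, notes),
            )
        return self.get_feeder(cur.lastrowid)

    def register_individual(
        self, experiment_id: int, name_or_number: str, color_code: Sequence[str]
    ) -> RegisteredIndividual:
        """Register a colour-marked individual (exactly three paint dots)."""
        if len(color_code) != 3:
            raise ValueError(f"color_code must have exactly three entries, got {len(color_code)}")
        self._require("experiment", experiment_id)
        try:
            with self._conn:
                cur = self._conn.execute(
                    "INSERT INTO registration (experiment_id, name_or_number, color1, color2, color3)"
                    " VALUES (?, ?, ?, ?, ?)",
                    (experiment_id, name_or_number, *color_code),
                )
        except sqlite3.IntegrityError as exc:
            raise UniquenessError(
                f"individual {name_or_number!r} already registered in experiment {experiment_id}"
            ) from exc
        return self.get_individual(cur.lastrowid)

    def record_visit(
        self,
        individual_id: int,
        feeder_id: Optional[int] = None,
        timestamp: Optional[CivilInstant] = None,
        notes: Optional[str] = None,
    ) -> Visit:
        """Log one observation of a registered individual ("one click").

        The timestamp defaults to the current system clock.  The parent
        experiment's coordinates are looked up automatically and the full
        solar ephemeris for (timestamp, position) is stored with the row.
        """
        individual = self.get_individual(individual_id)
        experiment = self.get_experiment(individual.experiment_id)
        if feeder_id is not None:
            feeder = self.get_feeder(feeder_id)
            if feeder.experiment_id != individual.experiment_id:
                raise ReferentialError(
                    f"feeder {feeder_id} belongs to experiment {feeder.experiment_id},"
                    f" not {individual.experiment_id}"
                )
        if timestamp is None:
            timestamp = CivilInstant.from_datetime(_datetime.now())
        eph = compute_ephemeris(timestamp, experiment.position)
        cols = ", ".join(EPHEMERIS_COLUMNS)
        marks = ", ".join("?" for _ in EPHEMERIS_COLUMNS)
        with self._conn:
            cur = self._conn.execute(
                f"INSERT INTO visit (individual_id, feeder_id, timestamp, utc_offset, notes, {cols})"
                f" VALUES (?, ?, ?, ?, ?, {marks})",
                (
                    individual_id,
                    feeder_id,
                    timestamp.isoformat(),
                    experiment.position.utc_offset,
                    notes,
                    *(getattr(eph, c) for c in EPHEMERIS_COLUMNS),
                ),
            )
        return self.get_visit(cur.lastrowid)

    # -- retrieval ----------------------------------------------------------

    def _require(self, table: str, id_: int) -> sqlite3.Row:
        row = self._conn.execute(f"SELECT * FROM {table} WHERE id = ?", (id_,)).fetchone()
        if row is None:
            raise NotFoundError(f"no {table} with id {id_}")
        return row

    def get_experiment(self, id_: int) -> Experiment:
        r = self._require("experiment", id_)
        return Experiment(
            id=r["id"],
            name=r["name"],
            date=r["date"],
            time=r["time"],
            position=GeoPosition(r["latitude"], r["longitude"], r["utc_offset"]),
            notes=r["notes"],
        )

    def get_feeder(self, id_: int) -> FeederStation:
        r = self._require("feeder", id_)
        return FeederStation(id=r["id"], experiment_id=r["experiment_id"], label=r["label"], notes=r["notes"])

    def get_individual(self, id_: int) -> RegisteredIndividual:
        r = self._require("registration", id_)
        return RegisteredIndividual(
            id=r["id"],
            experiment_id=r["experiment_id"],
            name_or_number=r["name_or_number"],
            color_code=(r["color1"], r["color2"], r["color3"]),
        )

    def get_visit(self, id_: int) -> Visit:
        r = self._require("visit", id_)
        eph = SolarEphemeris(**{c: r[c] for c in EPHEMERIS_COLUMNS})
        return Visit(
            id=r["id"],
            individual_id=r["individual_id"],
            feeder_id=r["feeder_id"],
            timestamp=CivilInstant.from_iso(r["timestamp"]),
            ephemeris=eph,
            notes=r["notes"],
        )

    def tabulate(self, entity_kind: str) -> pd.DataFrame:
        """All rows of one entity kind as a DataFrame, ordered by id.

        An empty store yields a zero-row frame that still carries every
        column header (visits include all ephemeris columns).
        """
        if entity_kind not in TABLES:
            raise ValueError(f"unknown entity kind {entity_kind!r}; expected one of {TABLES}")
        return pd.read_sql_query(f"SELECT * FROM {entity_kind} ORDER BY id", self._conn)

    def counts(self) -> dict:
        return {t: self._conn.execute(f"SELECT COUNT(*) FROM {t}").fetchone()[0] for t in TABLES}

    # -- update / delete ----------------------------------------------------

    def update_record(self, entity_kind: str, id_: int, **fields):
        """Rewrite the named fields of one row; untouched fields are preserved."""
        if entity_kind not in TABLES:
            raise ValueError(f"unknown entity kind {entity_kind!r}")
        allowed = _UPDATABLE[entity_kind]
        bad = set(fields) - allowed
        if bad:
            raise ValueError(f"fields {sorted(bad)} not updatable on {entity_kind}; allowed: {sorted(allowed)}")
        self._require(entity_kind, id_)
        if fields:
            assignments = ", ".join(f"{k} = ?" for k in fields)
            try:
                with self._conn:
                    self._conn.execute(
                        f"UPDATE {entity_kind} SET {assignments} WHERE id = ?",
                        (*fields.values(), id_),
                    )
            except sqlite3.IntegrityError as exc:
                raise ReferentialError(str(exc)) from exc
        getter = {
            "experiment": self.get_experiment,
            "feeder": self.get_feeder,
            "registration": self.get_individual,
            "visit": self.get_visit,
        }[entity_kind]
        return getter(id_)

    def delete_record(self, entity_kind: str, id_: int) -> None:
        """Delete one row; child rows cascade (visits lose a deleted feeder's reference)."""
        if entity_kind not in TABLES:
            raise ValueError(f"unknown entity kind {entity_kind!r}")
        self._require(entity_kind, id_)
        with self._conn:
            self._conn.execute(f"DELETE FROM {entity_kind} WHERE id = ?", (id_,))

    # -- integrity ----------------------------------------------------------

    def verify_ephemerides(self) -> int:
        """Recompute every visit's ephemeris from scratch and compare bit-for-bit.

        Returns the number of visits checked; raises ``DatastoreError`` on the
        first mismatch.  This is the store's self-audit: solar annotations are
        derived data and must always be reproducible from the timestamp and
        the parent experiment's coordinates.
        """
        n = 0
        rows = self._conn.execute(
            "SELECT v.id, v.timestamp, e.latitude, e.longitude, e.utc_offset, "
            + ", ".join("v." + c for c in EPHEMERIS_COLUMNS)
            + " FROM visit v JOIN registration r ON v.individual_id = r.id"
            " JOIN experiment e ON r.experiment_id = e.id ORDER BY v.id"
        ).fetchall()
        for row in rows:
            vid, ts, lat, lon, tz = row[:5]
            stored = row[5:]
            eph = compute_ephemeris(CivilInstant.from_iso(ts), GeoPosition(lat, lon, tz))
            expected = tuple(getattr(eph, c) for c in EPHEMERIS_COLUMNS)
            if tuple(stored) != expected:
                raise DatastoreError(f"visit {vid}: stored ephemeris diverges from recomputation")
            n += 1
        return n
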