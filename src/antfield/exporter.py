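"""Campaign administration and desktop-side tooling.

Four facilities around the campaign store:

* timestamped, collision-proof **backups** of the database file;
* passphrase-guarded **bulk deletion** of records (per table or everything);
* **conversion** of a campaign file to spreadsheet form (one sheet, or one
  CSV file, per table) for analysis outside the field toolchain;
* **merging** of several exported campaign files from different series of
  experiments into one database, with id collisions resolved by renumbering
  and content-identical rows de-duplicated.

Merging is content-addressed: two rows are duplicates when every non-id
field agrees (child rows compare their parents' *remapped* ids), so merging
a file with a copy of itself is a no-op and merge is idempotent.
"""

from __future__ import annotations

import hmac
import os
import re
import shutil
import sqlite3
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .datastore import (
    SCHEMA_VERSION,
    TABLES,
    CampaignDatabase,
    DatastoreError,
    SchemaVersionError,
)

__all__ = [
    "BACKUP_PREFIX",
    "BackupName",
    "AuthorizationError",
    "backup",
    "clear_records",
    "convert_to_workbook",
    "MergeReport",
    "merge",
]

BACKUP_PREFIX = "antfield"
_BACKUP_RE = re.compile(rf"^{BACKUP_PREFIX}_(\d{{8}})_(\d{{6}})\.sqlite$")


class AuthorizationError(DatastoreError):
    """The supplied security key does not match the configured one."""


@dataclass(frozen=True)
class BackupName:
    """Backup file name: fixed prefix + date + time, parseable back to its instant.

    Second resolution makes two backups taken at different seconds collide-free,
    which is what protects already-exported data from silent replacement.
    """

    date: str  # YYYYMMDD
    time: str  # HHMMSS
    prefix: str = BACKUP_PREFIX
    extension: str = "sqlite"

    @classmethod
    def for_instant(cls, when: datetime) -> "BackupName":
        return cls(date=when.strftime("%Y%m%d"), time=when.strftime("%H%M%S"))

    @classmethod
    def parse(cls, filename: Union[str, Path]) -> "BackupName":
        name = Path(filename).name
        m = _BACKUP_RE.match(name)
        if m is None:
            raise ValueError(f"{name!r} is not a recognised backup file name")
        return cls(date=m.group(1), time=m.group(2))

    def timestamp(self) -> datetime:
        return datetime.strptime(self.date + self.time, "%Y%m%d%H%M%S")

    def __str__(self) -> str:
        return f"{self.prefix}_{self.date}_{self.time}.{self.extension}"


def backup(db_path: Union[str, Path], destination_dir: Union[str, Path], clock=None) -> Path:
    """Copy the campaign file byte-for-byte into ``destination_dir``.

    The copy is named ``antfield_YYYYMMDD_HHMMSS.sqlite`` from ``clock``
    (a ``datetime`` or a callable returning one; defaults to now).  The copy
    is staged under a temporary name and atomically renamed, so a failing
    destination never leaves a partial backup behind.
    """
    src = Path(db_path)
    if not src.exists():
        raise FileNotFoundError(f"no database at {src}")
    when = clock() if callable(clock) else (clock or datetime.now())
    dest_dir = Path(destination_dir)
    dest = dest_dir / str(BackupName.for_instant(when))
    staging = dest.with_suffix(dest.suffix + ".part")
    try:
        shutil.copyfile(src, staging)
    except OSError:
        if staging.exists():
            staging.unlink()
        raise
    os.replace(staging, dest)
    return dest


def clear_records(
    db: CampaignDatabase,
    scope: str,
    passphrase: str,
    expected_key: str,
) -> Dict[str, int]:
    """Empty one table (or all four) after checking the security key.

    Returns per-table deletion counts, including rows removed by cascade
    (a cleared experiment takes its feeders, registrations and visits with
    it).  A wrong passphrase raises :class:`AuthorizationError` and changes
    nothing; the comparison is constant-time.
    """
    if scope != "all" and scope not in TABLES:
        raise ValueError(f"scope must be one of {TABLES + ('all',)}, got {scope!r}")
    if not hmac.compare_digest(passphrase.encode(), expected_key.encode()):
        raise AuthorizationError("security key mismatch; no records deleted")
    before = db.counts()
    targets = TABLES if scope == "all" else (scope,)
    with db._conn:
        for table in targets:
            db._conn.execute(f"DELETE FROM {table}")
    after = db.counts()
    return {t: before[t] - after[t] for t in TABLES if before[t] != after[t]}


def _read_tables(db_path: Union[str, Path]) -> Dict[str, pd.DataFrame]:
    path = Path(db_path)
    if not path.exists():
        raise FileNotFoundError(f"no database at {path}")
    conn = sqlite3.connect(str(path))
    try:
        try:
            row = conn.execute("SELECT schema_version FROM meta").fetchone()
        except sqlite3.OperationalError as exc:
            raise SchemaVersionError(f"{path}: not a campaign database ({exc})") from exc
        found = int(row[0])
        if found != SCHEMA_VERSION:
            raise SchemaVersionError(
                f"{path}: expected schema version {SCHEMA_VERSION}, found {found}"
            )
        return {t: pd.read_sql_query(f"SELECT * FROM {t} ORDER BY id", conn) for t in TABLES}
    finally:
        conn.close()


def convert_to_workbook(
    db_path: Union[str, Path],
    out_path: Union[str, Path],
    format: str = "xlsx",
) -> List[Path]:
    """Convert a campaign database to spreadsheet form.

    ``format="xlsx"`` writes one worksheet per table into a single workbook;
    ``format="csv-set"`` writes one UTF-8 CSV file per table into the
    directory ``out_path`` (created if needed).  Column headers match the
    schema; rows are in id order; solar columns stay numeric.  Returns the
    written path(s).
    """
    tables = _read_tables(db_path)
    out = Path(out_path)
    if format == "xlsx":
        out.parent.mkdir(parents=True, exist_ok=True)
        with pd.ExcelWriter(out, engine="openpyxl") as writer:
            for name, frame in tables.items():
                frame.to_excel(writer, sheet_name=name, index=False)
        return [out]
    if format == "csv-set":
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, frame in tables.items():
            target = out / f"{name}.csv"
            frame.to_csv(target, index=False, encoding="utf-8")
            written.append(target)
        return written
    raise ValueError(f"format must be 'xlsx' or 'csv-set', got {format!r}")


@dataclass
class MergeReport:
    """Accounting of one merge: row flows and the id renumbering applied."""

    files_in: int
    rows_in: Dict[str, int] = field(default_factory=dict)
    duplicates_dropped: Dict[str, int] = field(default_factory=dict)
    rows_out: Dict[str, int] = field(default_factory=dict)
    # id_remap[file_index][table][old_id] -> new_id
    id_remap: List[Dict[str, Dict[int, int]]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "files_in": self.files_in,
            "rows_in": self.rows_in,
            "duplicates_dropped": self.duplicates_dropped,
            "rows_out": self.rows_out,
            "id_remap": [
                {t: {str(k): v for k, v in m.items()} for t, m in per_file.items()}
                for per_file in self.id_remap
            ],
        }


def _plain(value):
    """NaN → None, numpy scalars → Python scalars (sqlite3-bindable, NaN-safe keys)."""
    if value is None or (isinstance(value, float) and value != value):
        return None
    try:
        if pd.isna(value):
            return None
    except (TypeError, ValueError):
        pass
    if hasattr(value, "item"):
        return value.item()
    return value


def _row_key(row: dict, exclude=("id",)) -> tuple:
    return tuple((k, row[k]) for k in sorted(row) if k not in exclude)


def merge(db_paths: Sequence[Union[str, Path]], out_path: Union[str, Path]) -> MergeReport:
    """Combine several exported campaign files into one database.

    Rows are processed top-down (experiments, feeders, registrations,
    visits); ids are renumbered sequentially and child references follow
    their parents' new ids.  A row whose non-id content (with remapped
    parent references) matches an already-merged row is dropped as a
    duplicate.  All inputs must share the schema version; on a version
    mismatch no output is written.
    """
    if not db_paths:
        raise ValueError("merge needs at least one input file")
    sources = [_read_tables(p) for p in db_paths]  # validates versions before any output
    out = Path(out_path)
    if out.exists():
        out.unlink()
    merged = CampaignDatabase(out)
    report = MergeReport(files_in=len(sources))
    for t in TABLES:
        report.rows_in[t] = sum(len(src[t]) for src in sources)
        report.duplicates_dropped[t] = 0
    seen: Dict[str, Dict[tuple, int]] = {t: {} for t in TABLES}
    next_id = {t: 1 for t in TABLES}
    parent_col = {"feeder": "experiment_id", "registration": "experiment_id", "visit": "individual_id"}
    parent_table = {"feeder": "experiment", "registration": "experiment", "visit": "registration"}
    try:
        with merged._conn:
            for src_idx, src in enumerate(sources):
                remap: Dict[str, Dict[int, int]] = {t: {} for t in TABLES}
                report.id_remap.append(remap)
                for t in TABLES:
                    frame = src[t]
                    for raw in frame.to_dict("records"):
                        row = {k: _plain(v) for k, v in raw.items()}
                        old_id = int(row["id"])
                        if t in parent_col:
                            col = parent_col[t]
                            row[col] = remap[parent_table[t]][int(row[col])]
                        if t == "visit":
                            row["feeder_id"] = (
                                remap["feeder"][int(row["feeder_id"])]
                                if row["feeder_id"] is not None
                                else None
                            )
                        key = _row_key(row)
                        hit = seen[t].get(key)
                        if hit is not None:
                            remap[t][old_id] = hit
                            report.duplicates_dropped[t] += 1
                            continue
                        new_id = next_id[t]
                        next_id[t] += 1
                        row["id"] = new_id
                        cols = ", ".join(row)
                        marks = ", ".join("?" for _ in row)
                        merged._conn.execute(
                            f"INSERT INTO {t} ({cols}) VALUES ({marks})", tuple(row.values())
                        )
                        seen[t][key] = new_id
                        remap[t][old_id] = new_id
        report.rows_out = merged.counts()
    finally:
        merged.close()
    return report
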