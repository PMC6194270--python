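"""Deposit, search and retrieve spectra in an embedded single-file store.

Raw and processed spectra are archived together with searchable metadata
(sample name, instrument, operator, date, processing log) in an SQLite
database.  The numeric channels are stored as JSON arrays of full-precision
floats, so retrieval is bit-exact — the archive never round-trips through
formatted text.  :func:`schema_sql` emits a MySQL-compatible dump of the
schema for users who want to host the archive on a server instead.
"""

from __future__ import annotations

import json
import os
import re
import sqlite3
from datetime import datetime, timezone

import numpy as np

from .core import Spectrum
from .io_formats import write_gen

#: Metadata columns that are individually searchable.
SEARCH_FIELDS = ("sample_name", "instrument", "operator", "date", "processing")

_COLUMNS = (
    "id",
    "sample_name",
    "instrument",
    "operator",
    "date",
    "processing",
    "units",
    "n_averaged",
    "deposited_at",
    "meta_json",
    "data_json",
)

_SCHEMA_SQLITE = """\
CREATE TABLE IF NOT EXISTS spectra (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    sample_name TEXT DEFAULT '',
    instrument TEXT DEFAULT '',
    operator TEXT DEFAULT '',
    date TEXT DEFAULT '',
    processing TEXT DEFAULT '',
    units TEXT NOT NULL,
    n_averaged INTEGER NOT NULL,
    deposited_at TEXT NOT NULL,
    meta_json TEXT NOT NULL,
    data_json TEXT NOT NULL
);
"""

_SCHEMA_MYSQL = """\
CREATE TABLE IF NOT EXISTS spectra (
    id INTEGER PRIMARY KEY AUTO_INCREMENT,
    sample_name VARCHAR(255) DEFAULT '',
    instrument VARCHAR(255) DEFAULT '',
    operator VARCHAR(255) DEFAULT '',
    date VARCHAR(64) DEFAULT '',
    processing TEXT,
    units VARCHAR(32) NOT NULL,
    n_averaged INTEGER NOT NULL,
    deposited_at VARCHAR(64) NOT NULL,
    meta_json LONGTEXT NOT NULL,
    data_json LONGTEXT NOT NULL
);
"""


def schema_sql(dialect: str = "sqlite") -> str:
    """The CREATE TABLE statement for the archive schema."""
    if dialect == "sqlite":
        return _SCHEMA_SQLITE
    if dialect == "mysql":
        return _SCHEMA_MYSQL
    raise ValueError(f"unknown SQL dialect {dialect!r}")


class ArchiveStore:
    """Handle to a single-file spectral archive."""

    def __init__(self, path: str | os.PathLike):
        self.path = os.fspath(path)
        self._conn = sqlite3.connect(self.path)
        self._ensure_schema()

    def _ensure_schema(self) -> None:
        cur = self._conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' AND name='spectra'"
        )
        if cur.fetchone() is not None:
            cols = [r[1] for r in self._conn.execute("PRAGMA table_info(spectra)")]
            if tuple(cols) != _COLUMNS:
                raise ValueError(
                    f"{self.path}: existing 'spectra' table has an incompatible "
                    f"schema (columns {cols})"
                )
            return
        self._conn.executescript(_SCHEMA_SQLITE)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "ArchiveStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def __len__(self) -> int:
        return int(self._conn.execute("SELECT COUNT(*) FROM spectra").fetchone()[0])

    def ids(self) -> list[int]:
        return [r[0] for r in self._conn.execute("SELECT id FROM spectra ORDER BY id")]


def init_store(path: str | os.PathLike, demo: bool = False) -> ArchiveStore:
    """Open (creating if needed) an archive; optionally seed demo records.

    With ``demo=True`` an empty store is populated with three synthetic
    demonstration spectra, mirroring a template database shipped with
    example entries.  Re-initialising an existing store never loses data.
    """
    store = ArchiveStore(path)
    if demo and len(store) == 0:
        from . import synth  # local import: synth depends on core only

        helix = synth.preset_spectrum("helix", name="demo helix protein")
        sheet = synth.preset_spectrum("sheet", name="demo sheet protein")
        reps = synth.make_replicates(helix, n=3, noise_sd=0.2, seed=7)
        from .processing import average_spectra

        avg = average_spectra(reps)
        avg.meta["sample"] = "demo averaged helix"
        for s, operator in ((helix, "demo"), (sheet, "demo"), (avg, "demo")):
            deposit(
                store,
                s,
                {
                    "sample_name": s.meta.get("sample", ""),
                    "instrument": "fixtureCD",
                    "operator": operator,
                    "date": "2018-10-18",
                },
            )
    return store


def _spectrum_to_json(s: Spectrum) -> str:
    payload = {
        "wavelengths": s.wavelengths.tolist(),
        "cd": s.cd.tolist(),
        "ht": None if s.ht is None else s.ht.tolist(),
        "cd_smoothed": None if s.cd_smoothed is None else s.cd_smoothed.tolist(),
        "sd": s.sd.tolist(),
        "units": s.units,
        "n_averaged": int(s.n_averaged),
        "meta": s.meta,
    }
    return json.dumps(payload)


def _spectrum_from_json(text: str) -> Spectrum:
    payload = json.loads(text)
    return Spectrum(
        wavelengths=np.array(payload["wavelengths"]),
        cd=np.array(payload["cd"]),
        ht=None if payload["ht"] is None else np.array(payload["ht"]),
        cd_smoothed=None
        if payload["cd_smoothed"] is None
        else np.array(payload["cd_smoothed"]),
        sd=np.array(payload["sd"]),
        units=payload["units"],
        meta=dict(payload["meta"]),
        n_averaged=payload["n_averaged"],
    )


def deposit(store: ArchiveStore, s: Spectrum, metadata: dict | None = None) -> int:
    """Store a spectrum; returns its (monotonically increasing) record id."""
    metadata = dict(metadata or {})
    unknown = set(metadata) - set(SEARCH_FIELDS)
    if unknown:
        raise ValueError(f"unknown metadata fields: {sorted(unknown)}")
    row = {
        "sample_name": metadata.get("sample_name", s.meta.get("sample", "")),
        "instrument": metadata.get("instrument", s.meta.get("instrument", "")),
        "operator": metadata.get("operator", ""),
        "date": metadata.get("date", ""),
        "processing": metadata.get("processing", s.meta.get("processing", "")),
        "units": s.units,
        "n_averaged": int(s.n_averaged),
        "deposited_at": datetime.now(timezone.utc).isoformat(),
        "meta_json": json.dumps(s.meta),
        "data_json": _spectrum_to_json(s),
    }
    cur = store._conn.execute(
        "INSERT INTO spectra (sample_name, instrument, operator, date, processing,"
        " units, n_averaged, deposited_at, meta_json, data_json)"
        " VALUES (:sample_name, :instrument, :operator, :date, :processing,"
        " :units, :n_averaged, :deposited_at, :meta_json, :data_json)",
        row,
    )
    store._conn.commit()
    return int(cur.lastrowid)


def retrieve(store: ArchiveStore, record_id: int) -> Spectrum:
    """Fetch the stored spectrum, bit-exact."""
    row = store._conn.execute(
        "SELECT data_json FROM spectra WHERE id = ?", (record_id,)
    ).fetchone()
    if row is None:
        raise KeyError(f"no archive record with id {record_id}")
    return _spectrum_from_json(row[0])


def record_metadata(store: ArchiveStore, record_id: int) -> dict:
    row = store._conn.execute(
        "SELECT id, sample_name, instrument, operator, date, processing,"
        " units, n_averaged, deposited_at FROM spectra WHERE id = ?",
        (record_id,),
    ).fetchone()
    if row is None:
        raise KeyError(f"no archive record with id {record_id}")
    keys = (
        "id",
        "sample_name",
        "instrument",
        "operator",
        "date",
        "processing",
        "units",
        "n_averaged",
        "deposited_at",
    )
    return dict(zip(keys, row))


def search_text(store: ArchiveStore, needle: str) -> list[int]:
    """Ids of records where any metadata field contains ``needle``.

    Case-insensitive substring match; the empty needle matches every
    record.
    """
    needle = needle.lower()
    hits: list[int] = []
    for rid in store.ids():
        md = record_metadata(store, rid)
        fields = [str(md[f]) for f in SEARCH_FIELDS]
        if any(needle in f.lower() for f in fields):
            hits.append(rid)
    return hits


def query(store: ArchiveStore, filters: dict) -> list[int]:
    """Structured search: the conjunction of per-field predicates.

    A predicate is a plain value (equality), ``("contains", text)`` for a
    case-insensitive substring, or ``("between", low, high)`` for an
    inclusive range (useful on ``date`` / ``deposited_at``).  Queryable
    fields: the :data:`SEARCH_FIELDS` plus ``units``, ``n_averaged`` and
    ``deposited_at``.
    """
    allowed = set(SEARCH_FIELDS) | {"units", "n_averaged", "deposited_at"}
    for name in filters:
        if name not in allowed:
            raise ValueError(f"unknown query field {name!r}; known: {sorted(allowed)}")
    hits: list[int] = []
    for rid in store.ids():
        md = record_metadata(store, rid)
        ok = True
        for name, pred in filters.items():
            value = md[name]
            if isinstance(pred, tuple):
                op = pred[0]
                if op == "contains":
                    ok = str(pred[1]).lower() in str(value).lower()
                elif op == "between":
                    ok = pred[1] <= value <= pred[2]
                else:
                    raise ValueError(f"unknown predicate {op!r}")
            else:
                ok = value == pred
            if not ok:
                break
        if ok:
            hits.append(rid)
    return hits


def raw_sql(store: ArchiveStore, sql: str) -> list[tuple]:
    """Raw read-only SQL against the embedded store (SELECT only)."""
    if not sql.lstrip().lower().startswith("select"):
        raise ValueError("raw_sql accepts SELECT statements only")
    return list(store._conn.execute(sql))


def export_records(store: ArchiveStore, ids: list[int], directory: str | os.PathLike) -> list[str]:
    """Write one ``.gen`` file per record id; returns the paths written."""
    os.makedirs(directory, exist_ok=True)
    paths: list[str] = []
    for rid in ids:
        s = retrieve(store, rid)
        md = record_metadata(store, rid)
        slug = re.sub(r"[^A-Za-z0-9._-]+", "_", md["sample_name"]).strip("_") or "record"
        path = os.path.join(os.fspath(directory), f"{rid:04d}_{slug}.gen")
        write_gen(s, path)
        paths.append(path)
    return paths
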