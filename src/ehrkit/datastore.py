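"""Embedded relational store for flat-file EHR extracts.

EHR providers supply data as (optionally zipped) tab-delimited text files,
one set per table type (Patient, Practice, Clinical, ...), often split into
many part-files.  Importing them once into a single-file SQLite database
makes every downstream selection orders of magnitude faster than re-reading
text files, and lets intermediate extractions live in temporary tables
instead of memory.

Conventions:

* dates are stored as ISO-8601 **text** and compared lexicographically;
* missing values become SQL NULL;
* raw birth years are stored as ``raw + year_origin`` (CPRD extracts encode
  year of birth as an offset from 1800).
"""

from __future__ import annotations

import sqlite3
import warnings
import zipfile
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .schema import EHRSchema, get_default_schema

__all__ = [
    "Database",
    "database",
    "import_flat_files",
    "add_table_from_file",
    "head_db",
    "create_temp_table",
    "append_to_temp_table",
    "to_temp_table",
    "drop_temp_table",
    "drop_all_temp_tables",
    "export_flat_files",
]


class Database:
    """A connection to a single-file SQLite store.

    Temporary tables exist only within this connection; closing it discards
    them.
    """

    def __init__(self, path: str | Path):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "Database":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def tables(self, temp: bool = False) -> list[str]:
        master = "sqlite_temp_master" if temp else "sqlite_master"
        rows = self.conn.execute(
            f"SELECT name FROM {master} WHERE type = 'table' ORDER BY name"
        ).fetchall()
        return [r[0] for r in rows]

    def __repr__(self) -> str:
        return f"Database({self.path!r}, tables={self.tables()})"


def database(path: str | Path) -> Database:
    """Open (creating if needed) a single-file database."""
    return Database(path)


# ---------------------------------------------------------------------------
# reading flat files


def _read_flat_file(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited file, transparently unpacking single-member zips."""
    path = Path(path)
    if path.suffix.lower() == ".zip":
        with zipfile.ZipFile(path) as zf:
            members = [m for m in zf.namelist() if not m.endswith("/")]
            if len(members) != 1:
                raise ValueError(
                    f"{path}: expected a single member in zip archive, found {len(members)}"
                )
            with zf.open(members[0]) as fh:
                text = fh.read().decode("utf-8")
        return pd.read_csv(StringIO(text), sep="\t", dtype=str, keep_default_na=False,
                           na_values=[""])
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])


def _convert_dates_to_iso(
    df: pd.DataFrame, dateformat: str, schema: EHRSchema, source: str
) -> pd.DataFrame:
    """Convert date-role columns to ISO text, erroring on unparseable values.

    Conversion is idempotent: values already in ISO form pass through.
    """
    for col in schema.date_columns:
        if col not in df.columns:
            continue
        raw = df[col]
        parsed = pd.to_datetime(raw, format=dateformat, errors="coerce")
        if dateformat != "%Y-%m-%d":
            iso = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
            parsed = parsed.fillna(iso)
        bad = raw.notna() & parsed.isna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"unparseable date in {source}, row {row}, column {col!r}: {raw[bad].iloc[0]!r}"
            )
        df[col] = parsed.dt.strftime("%Y-%m-%d")
    return df


def _convert_birth_year(df: pd.DataFrame, yob_origin: int, schema: EHRSchema) -> pd.DataFrame:
    col = schema.birth_year
    if col in df.columns:
        df[col] = pd.to_numeric(df[col], errors="coerce") + yob_origin
    return df


def _coerce_numerics(df: pd.DataFrame, schema: EHRSchema) -> pd.DataFrame:
    """Store as numbers the columns that are wholly numeric text."""
    for col in df.columns:
        if col in schema.date_columns:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        if df[col].notna().equals(converted.notna()):
            if (converted.dropna() % 1 == 0).all():
                converted = converted.astype("Int64")
            df[col] = converted
    return df


def add_table_from_file(
    db: Database,
    file: str | Path,
    table_name: str,
    dateformat: str = "%Y-%m-%d",
    yob_origin: int | None = None,
    if_exists: str = "append",
    schema: EHRSchema | None = None,
) -> Database:
    """Import one flat file into ``table_name``.

    ``if_exists`` follows the pandas contract: ``"append"`` concatenates,
    ``"fail"`` errors, ``"replace"`` overwrites.
    """
    schema = schema or get_default_schema()
    df = _read_flat_file(file)
    df = _convert_dates_to_iso(df, dateformat, schema, str(file))
    if yob_origin is not None:
        df = _convert_birth_year(df, yob_origin, schema)
    df = _coerce_numerics(df, schema)
    df.to_sql(table_name, db.conn, if_exists=if_exists, index=False)
    db.conn.commit()
    return db


def import_flat_files(
    db: Database,
    data_dir: str | Path,
    filetypes: Sequence[str] = ("Clinical", "Consultation", "Patient", "Practice", "Referral"),
    dateformat: str = "%Y-%m-%d",
    yob_origin: int = 1800,
    regex: str = "ehr",
    recursive: bool = True,
    schema: EHRSchema | None = None,
) -> Database:
    """Import all flat files named ``<regex>_<Filetype>*.txt|.zip`` under ``data_dir``.

    One database table per filetype; rows from multiple part-files of the
    same filetype are concatenated verbatim (no de-duplication).  A filetype
    with no matching files raises a warning and is skipped.
    """
    schema = schema or get_default_schema()
    data_dir = Path(data_dir)
    for filetype in filetypes:
        pattern = f"{regex}_{filetype}*"
        globber = data_dir.rglob if recursive else data_dir.glob
        files = sorted(
            p for p in globber(pattern) if p.suffix.lower() in (".txt", ".zip")
        )
        if not files:
            warnings.warn(f"no files matching {pattern!r} under {data_dir}; skipping {filetype}")
            continue
        first = True
        for f in files:
            add_table_from_file(
                db,
                f,
                filetype,
                dateformat=dateformat,
                yob_origin=yob_origin,
                if_exists="replace" if first else "append",
                schema=schema,
            )
            first = False
    return db


# ---------------------------------------------------------------------------
# inspection


def head_db(
    db: Database, table: str | None = None, temp: bool = False, n: int = 6
) -> pd.DataFrame:
    """List tables, or show the first ``n`` rows of one table.

    With no ``table``, returns the catalogue (type, name, tbl_name) of
    permanent — or, with ``temp``, temporary — tables.
    """
    if table is None:
        master = "sqlite_temp_master" if temp else "sqlite_master"
        return pd.read_sql_query(
            f"SELECT type, name, tbl_name FROM {master} WHERE type='table' ORDER BY name",
            db.conn,
        )
    return pd.read_sql_query(f"SELECT * FROM {table} LIMIT {int(n)}", db.conn)


# ---------------------------------------------------------------------------
# temporary tables


def create_temp_table(db: Database, name: str, select_query: str) -> None:
    """Materialise a select as a temporary table on this connection."""
    db.conn.execute(f"CREATE TEMPORARY TABLE {name} AS {select_query}")
    db.conn.commit()


def append_to_temp_table(db: Database, name: str, select_query: str) -> None:
    db.conn.execute(f"INSERT INTO {name} {select_query}")
    db.conn.commit()


def to_temp_table(db: Database, name: str, records: pd.DataFrame) -> None:
    """Export a dataframe to a temporary table."""
    cols = ", ".join(f'"{c}"' for c in records.columns)
    db.conn.execute(f"CREATE TEMPORARY TABLE {name} ({cols})")
    placeholders = ", ".join("?" for _ in records.columns)
    rows = [
        tuple(None if pd.isna(v) else v for v in row)
        for row in records.itertuples(index=False, name=None)
    ]
    db.conn.executemany(f"INSERT INTO {name} VALUES ({placeholders})", rows)
    db.conn.commit()


def drop_temp_table(db: Database, name: str) -> bool:
    """Drop a temporary table if it exists; returns whether it did."""
    if name not in db.tables(temp=True):
        return False
    db.conn.execute(f"DROP TABLE {name}")
    db.conn.commit()
    return True


def drop_all_temp_tables(db: Database) -> int:
    """Drop every temporary table on this connection; returns the count."""
    names = db.tables(temp=True)
    for name in names:
        db.conn.execute(f"DROP TABLE {name}")
    db.conn.commit()
    return len(names)


# ---------------------------------------------------------------------------
# export


def export_flat_files(
    db: Database,
    out_dir: str | Path,
    table: str = "Consultation",
    file_type: str = "csv",
    schema: EHRSchema | None = None,
) -> list[Path]:
    """Export one database table to flat files split by practice.

    Produces ``<table>_<practid>.<ext>`` per practice; the union of exported
    rows equals the source table.  Used to stage consultation files for
    dummy-index-date matching.
    """
    schema = schema or get_default_schema()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if file_type not in ("csv", "tsv", "txt"):
        raise ValueError(f"unsupported file_type {file_type!r}")
    sep = "," if file_type == "csv" else "\t"
    df = pd.read_sql_query(f"SELECT * FROM {table}", db.conn)
    written: list[Path] = []
    for practid, group in df.groupby(schema.practice_id, sort=True):
        path = out_dir / f"{table}_{practid}.{file_type}"
        group.to_csv(path, sep=sep, index=False)
        written.append(path)
    return written
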