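"""Longitudinal extraction: run one selection over a range of year windows.

Prevalence/incidence work needs the same query run once per year with the
year's start and end dates substituted in.  :func:`select_by_year` does this
over calendar years, UK financial (QOF) years, or any custom window built
with :func:`build_date_fn`, and stacks the per-year results with a ``year``
column (plus a ``table`` column when several tables are queried).
"""

from __future__ import annotations

import datetime as dt
from concurrent.futures import ThreadPoolExecutor
from pathlib import Path
from typing import Any, Callable, Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .datastore import Database
from .query import first_events, last_events, select_events
from .schema import EHRSchema, get_default_schema

__all__ = [
    "YearWindow",
    "standard_years",
    "qof_years",
    "qof_15_months",
    "build_date_fn",
    "select_by_year",
]


class YearWindow(NamedTuple):
    """One longitudinal slice: a labelled date interval."""

    year: int
    startdate: str  # ISO date
    enddate: str  # ISO date


def _window(year: int, start: dt.date, end: dt.date) -> YearWindow:
    if start > end:
        raise ValueError(f"year window start {start} after end {end}")
    return YearWindow(year, start.isoformat(), end.isoformat())


def build_date_fn(
    start_offset: tuple[int, int, int], end_offset: tuple[int, int, int]
) -> Callable[[int], YearWindow]:
    """Build a year-window function from (year-offset, month, day) pairs.

    ``build_date_fn((0, 1, 1), (0, 12, 31))`` reproduces calendar years;
    ``build_date_fn((0, 4, 1), (1, 3, 31))`` reproduces UK financial years.
    Invalid month/day combinations raise ``ValueError`` when the function is
    applied.
    """
    sy, sm, sd = start_offset
    ey, em, ed = end_offset

    def year_fn(year: int) -> YearWindow:
        return _window(year, dt.date(year + sy, sm, sd), dt.date(year + ey, em, ed))

    return year_fn


#: Calendar years: 1 January to 31 December.
standard_years = build_date_fn((0, 1, 1), (0, 12, 31))

#: UK financial (QOF) years: 1 April to 31 March of the following year.
qof_years = build_date_fn((0, 4, 1), (1, 3, 31))

#: QOF 15-month windows: 1 January to 31 March of the following year.
qof_15_months = build_date_fn((0, 1, 1), (1, 3, 31))


def _substitute_macros(where: str | None, window: YearWindow) -> str | None:
    if where is None:
        return None
    return where.replace("STARTDATE", f"'{window.startdate}'").replace(
        "ENDDATE", f"'{window.enddate}'"
    )


def _select_one_year(
    db_or_path,
    tables: Sequence[str],
    columns: Sequence[str],
    where: str | None,
    window: YearWindow,
    selector_fn: Callable,
    env: Mapping[str, Any] | None,
    schema: EHRSchema,
    own_connection: bool,
) -> pd.DataFrame:
    db = Database(db_or_path) if own_connection else db_or_path
    try:
        parts = []
        for tab in tables:
            part = selector_fn(
                db,
                tab,
                columns=columns,
                where=_substitute_macros(where, window),
                env=env,
                schema=schema,
            )
            if len(tables) > 1:
                part = part.copy()
                part["table"] = tab
            parts.append(part)
        out = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
        out["year"] = window.year
        return out
    finally:
        if own_connection:
            db.close()


def select_by_year(
    db_or_path,
    tables: str | Sequence[str],
    columns: Sequence[str] = ("*",),
    where: str | None = None,
    year_range: Iterable[int] = (),
    year_fn: Callable[[int], YearWindow] = standard_years,
    selector_fn: Callable = select_events,
    env: Mapping[str, Any] | None = None,
    as_list: bool = False,
    cores: int = 1,
    schema: EHRSchema | None = None,
) -> pd.DataFrame | list[pd.DataFrame]:
    """Apply a database select over a range of years.

    ``STARTDATE`` and ``ENDDATE`` macros in ``where`` are replaced, per
    year, by the window's quoted ISO dates (the comparison operators around
    them are the caller's).  ``selector_fn`` is one of
    :func:`~ehrkit.query.select_events`, :func:`~ehrkit.query.first_events`,
    :func:`~ehrkit.query.last_events` or a compatible callable.

    With ``cores > 1`` a database *path* must be supplied — each worker
    opens its own connection, so open connections (and their temporary
    tables) cannot be shared.  Results are ordered by year regardless of
    completion order.
    """
    schema = schema or get_default_schema()
    if isinstance(tables, str):
        tables = [tables]
    if not callable(selector_fn):
        raise TypeError("selector_fn must be callable")
    years = list(year_range)
    own_connection = isinstance(db_or_path, (str, Path))
    if cores > 1 and not own_connection:
        raise ValueError(
            "cores > 1 requires a database path, not an open connection: "
            "connections cannot be shared across workers"
        )

    def run(year: int) -> pd.DataFrame:
        return _select_one_year(
            db_or_path, tables, columns, where, year_fn(year),
            selector_fn, env, schema, own_connection,
        )

    if cores > 1 and len(years) > 1:
        with ThreadPoolExecutor(max_workers=cores) as pool:
            results = list(pool.map(run, years))
    else:
        results = [run(y) for y in years]

    if as_list:
        return results
    if not results:
        return pd.DataFrame()
    return pd.concat(results, ignore_index=True)
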