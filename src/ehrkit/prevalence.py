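"""Person-time prevalence and incidence from patient-year tables.

:func:`prev_terms` takes a long-format table (one row per patient per year,
with registration/censoring dates and at most one first-event date) and adds
the numerator/denominator membership flags and the follow-up contribution.
:func:`prev_totals` then aggregates to rates per 100 person-years.

The membership rules, with *event* the date of interest, *tod* the transfer
out date, and the year window ``[year_start, year_end]``:

======================  =====================================================
incident numerator      event within the year AND (no tod or tod > event)
incident denominator    no event before year start AND (no tod or tod > year start)
prevalent numerator     event on or before year end AND (no tod or tod > event)
prevalent denominator   no tod or tod > year start
follow-up               min(year end, tod, death) − year start, in years
======================  =====================================================

All date comparisons are strict (``>``) where shown.  A patient with no
transfer-out date has simply not transferred out.  Two readings of the
prevalent-numerator rule circulate — "event occurs within the year" versus
"earliest event on or before the year end"; both are implemented and the
cumulative reading is the default (``prevalent_rule="on_or_before_year_end"``).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .longitudinal import YearWindow, standard_years
from .schema import EHRSchema, get_default_schema

__all__ = ["prev_terms", "prev_totals", "DAYS_PER_YEAR"]

#: Person-time divisor converting days to years.
DAYS_PER_YEAR = 365.25

_FAR_FUTURE = "9999-12-31"


def prev_terms(
    data: pd.DataFrame,
    year_fn: Callable[[int], YearWindow] = standard_years,
    event_date: str | None = None,
    prevalent_rule: str = "on_or_before_year_end",
    schema: EHRSchema | None = None,
) -> pd.DataFrame:
    """Add numerator/denominator flags and follow-up to a patient-year table.

    ``data`` must carry a ``year`` column (the window is derived from it via
    ``year_fn``), the event date column, and the schema's transfer-out and
    death columns.  Missing event/censor dates are simply absent events.
    """
    schema = schema or get_default_schema()
    event_date = event_date or schema.event_date
    tod_col = schema.date_fields["transfer_out"]
    death_col = schema.date_fields["death"]
    if "year" not in data.columns:
        raise ValueError("prev_terms requires a 'year' column giving each row's year window")
    if prevalent_rule not in ("on_or_before_year_end", "within_year"):
        raise ValueError(f"unknown prevalent_rule {prevalent_rule!r}")
    for col in (event_date, tod_col, death_col):
        if col not in data.columns:
            raise ValueError(f"prev_terms requires column {col!r}")

    out = data.copy()
    windows = {y: year_fn(int(y)) for y in out["year"].dropna().unique()}
    out["year_start"] = out["year"].map(lambda y: windows[y].startdate)
    out["year_end"] = out["year"].map(lambda y: windows[y].enddate)

    ev = out[event_date].astype("string")
    tod = out[tod_col].astype("string")
    death = out[death_col].astype("string")
    ys = out["year_start"]
    ye = out["year_end"]

    has_ev = ev.notna()
    tod_eff = tod.fillna(_FAR_FUTURE)  # missing = never transferred out
    tod_after_event = has_ev & (tod_eff > ev)
    in_year = has_ev & (ev >= ys) & (ev <= ye)

    out["incident_numerator"] = (in_year & tod_after_event).astype(bool)
    out["incident_denominator"] = (
        (~has_ev | (ev >= ys)) & (tod_eff > ys)
    ).astype(bool)
    if prevalent_rule == "within_year":
        out["prevalent_numerator"] = out["incident_numerator"]
    else:
        out["prevalent_numerator"] = (has_ev & (ev <= ye) & tod_after_event).astype(bool)
    out["prevalent_denominator"] = (tod_eff > ys).astype(bool)

    end = pd.concat(
        [ye, tod.fillna(_FAR_FUTURE), death.fillna(_FAR_FUTURE)], axis=1
    ).min(axis=1)
    days = (pd.to_datetime(end) - pd.to_datetime(ys)).dt.days.clip(lower=0)
    out["followup"] = days / DAYS_PER_YEAR
    return out


def _totals(
    terms: pd.DataFrame,
    num_flag: str,
    den_flag: str,
    rate_name: str,
    keys: list[str],
) -> pd.DataFrame:
    grouped = terms.groupby(keys, dropna=False)
    num = grouped[num_flag].sum()
    den = terms[terms[den_flag]].groupby(keys, dropna=False)["followup"].sum()
    out = pd.DataFrame({"numerator": num}).join(
        den.rename("denominator"), how="left"
    )
    out["denominator"] = out["denominator"].fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = 100.0 * out["numerator"] / out["denominator"]
    out[rate_name] = rate.where(out["denominator"] > 0)
    return out.reset_index()


def prev_totals(
    terms: pd.DataFrame,
    groups: Sequence[str] = (),
) -> dict[str, dict[str, pd.DataFrame]]:
    """Summarise :func:`prev_terms` output to rates per 100 person-years.

    Returns ``{"prevalence": {...}, "incidence": {...}}``; each inner dict
    holds ``year_counts`` (grouped by year) and, when extra ``groups`` are
    given, a further table grouped by year plus those keys.  Numerators are
    flag counts; denominators are person-years summed over denominator
    members; a zero denominator yields a missing (not infinite) rate.
    """
    required = [
        "year",
        "followup",
        "incident_numerator",
        "incident_denominator",
        "prevalent_numerator",
        "prevalent_denominator",
    ]
    missing = [c for c in required if c not in terms.columns]
    if missing:
        raise ValueError(f"prev_totals input missing columns {missing}; run prev_terms first")

    out: dict[str, dict[str, pd.DataFrame]] = {"prevalence": {}, "incidence": {}}
    keysets: list[list[str]] = [["year"]]
    if groups:
        keysets.append(["year", *groups])
    for keys in keysets:
        label = "year_counts" if keys == ["year"] else "_".join(keys[1:]) + "_counts"
        out["prevalence"][label] = _totals(
            terms, "prevalent_numerator", "prevalent_denominator", "prevalence", keys
        )
        out["incidence"][label] = _totals(
            terms, "incident_numerator", "incident_denominator", "incidence", keys
        )
    return out
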