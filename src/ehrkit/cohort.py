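"""Survival-cohort construction and time-varying covariate splitting.

:func:`build_cohort` collapses a long patient-year table (from the
prevalence workflow) into one row per patient with integer day offsets ready
for a survival model.  :func:`cut_tv` splits follow-up intervals at
covariate-change times so that every episode has constant covariate values
— the classic Lexis-style episode split, on closed integer-day intervals.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .schema import EHRSchema, get_default_schema

__all__ = ["build_cohort", "cut_tv"]


def build_cohort(
    data: pd.DataFrame,
    cohort_type: str = "prev",
    cohort_start: str = "2006-01-01",
    cohort_end: str = "2012-12-31",
    diagnosis_start: str | None = "eventdate",
    schema: EHRSchema | None = None,
) -> pd.DataFrame:
    """Collapse a patient-year prevalence table to a one-row-per-patient cohort.

    Keeps only patients in the numerator or denominator of the chosen
    ``cohort_type`` (``"prev"`` or ``"incid"``).  Per patient:

    * ``start_date`` = max(cohort start, every start-criteria date, and —
      for cases, when ``diagnosis_start`` names a column — the diagnosis
      date);
    * ``end_date`` = min(cohort end, every end-criteria date present);
    * ``start`` / ``end`` = integer day offsets from the cohort start;
    * ``case`` = 1 if the patient is ever in the numerator.

    Patients whose start date falls after their end date are dropped.
    """
    schema = schema or get_default_schema()
    if cohort_type not in ("prev", "incid"):
        raise ValueError(f"unknown cohort_type {cohort_type!r}; use 'prev' or 'incid'")
    prefix = "prevalent" if cohort_type == "prev" else "incident"
    num_flag, den_flag = f"{prefix}_numerator", f"{prefix}_denominator"
    for col in (num_flag, den_flag):
        if col not in data.columns:
            raise ValueError(f"build_cohort input missing column {col!r}; run prev_terms first")

    start_cols = schema.cohort.start_criteria
    end_cols = schema.cohort.end_criteria
    missing = [c for c in start_cols + end_cols if c not in data.columns]
    if missing:
        raise ValueError(f"build_cohort input missing cohort criteria columns {missing}")

    pid = schema.patient_id
    df = data[data[num_flag] | data[den_flag]].copy()
    if df.empty:
        return df.assign(case=pd.Series(dtype=int), start=pd.Series(dtype=int),
                         end=pd.Series(dtype=int))

    case_by_patient = df.groupby(pid)[num_flag].any()
    if diagnosis_start is not None and diagnosis_start in df.columns:
        diag_by_patient = (
            pd.to_datetime(df[diagnosis_start], errors="coerce").groupby(df[pid]).min()
        )
    else:
        diag_by_patient = None

    # one row per patient: the earliest year's row carries the covariates
    df = df.sort_values([pid, "year"], kind="stable").drop_duplicates(pid, keep="first")
    df = df.set_index(pid, drop=False)

    cs = pd.Timestamp(cohort_start)
    ce = pd.Timestamp(cohort_end)

    start_frame = pd.DataFrame(index=df.index)
    start_frame["_cohort_start"] = cs
    for c in start_cols:
        start_frame[c] = pd.to_datetime(df[c], errors="coerce")
    if diag_by_patient is not None:
        diag = pd.to_datetime(diag_by_patient, errors="coerce").reindex(df.index)
        diag[~case_by_patient.reindex(df.index).fillna(False)] = pd.NaT
        start_frame["_diagnosis"] = diag
    start_date = start_frame.max(axis=1)  # NaT ignored

    end_frame = pd.DataFrame(index=df.index)
    end_frame["_cohort_end"] = ce
    for c in end_cols:
        end_frame[c] = pd.to_datetime(df[c], errors="coerce")
    end_date = end_frame.min(axis=1)

    out = df.copy()
    out["case"] = case_by_patient.reindex(df.index).astype(int)
    out["start_date"] = start_date
    out["end_date"] = end_date
    out["start"] = (start_date - cs).dt.days
    out["end"] = (end_date - cs).dt.days
    out = out[out["start"] <= out["end"]]
    return out.reset_index(drop=True)


def cut_tv(
    data: pd.DataFrame,
    entry: str,
    exit: str,
    cut_var: str,
    id_var: str,
    tv_name: str,
    on_existing: str = "flip",
) -> pd.DataFrame:
    """Split follow-up episodes at the times in ``cut_var``.

    Intervals are closed ``[entry, exit]`` in integer days.  Per input row
    with cut time ``t``:

    * ``t`` missing or ``t > exit``: the row is unchanged (state 0 if
      ``tv_name`` is new);
    * ``t <= entry``: one row, with the state updated;
    * ``entry < t <= exit``: the row is replaced by ``[entry, t－1]``
      (pre-cut state) and ``[t, exit]`` (post-cut state).

    When ``tv_name`` is a new column the pre-cut state is 0 and the post-cut
    state 1.  When it already exists, ``on_existing="flip"`` toggles 0↔1
    (drug stop/start chains) and ``"inc"`` adds 1 (disease-stage
    progression).  All other columns — including any event indicator — are
    replicated verbatim onto both halves; survival-correct event handling on
    the final episode is the caller's responsibility.  Calls chain, one per
    cut time column.
    """
    if on_existing not in ("flip", "inc"):
        raise ValueError(f"unknown on_existing {on_existing!r}; use 'flip' or 'inc'")
    if tv_name in (entry, exit, id_var):
        raise ValueError(f"tv_name {tv_name!r} collides with entry/exit/id columns")
    for col in (entry, exit, cut_var, id_var):
        if col not in data.columns:
            raise ValueError(f"cut_tv input missing column {col!r}")
    t = pd.to_numeric(data[cut_var], errors="raise")

    df = data.copy()
    is_new = tv_name not in df.columns
    if is_new:
        df[tv_name] = 0

    def bumped(state: pd.Series) -> pd.Series:
        if is_new:
            return pd.Series(1, index=state.index)
        if on_existing == "flip":
            return 1 - state
        return state + 1

    has_t = t.notna()
    unchanged = df[~has_t | (t > df[exit])]
    at_or_before = has_t & (t <= df[entry])
    update_only = df[at_or_before].copy()
    update_only[tv_name] = bumped(update_only[tv_name])
    split_mask = has_t & (t > df[entry]) & (t <= df[exit])
    pre = df[split_mask].copy()
    post = pre.copy()
    pre[exit] = (t[split_mask] - 1).astype(pre[exit].dtype)
    post[entry] = t[split_mask].astype(post[entry].dtype)
    post[tv_name] = bumped(post[tv_name])

    out = pd.concat([unchanged, update_only, pre, post], ignore_index=True)
    out = out.sort_values([id_var, entry], kind="stable").reset_index(drop=True)
    return out
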