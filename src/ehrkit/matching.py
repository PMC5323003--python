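"""Matched-control selection for case-control and cohort designs.

Three algorithms:

* **incidence-density (risk-set) sampling** — controls for each case are
  drawn, at that case's diagnosis date, from subjects still diagnosis-free
  at that date.  The pool is *not* depleted between cases, so the same
  subject may serve as a control for several cases; this is what keeps
  risk estimates unbiased.
* **exact matching** — matched controls are removed from the pool after
  each case, so each control is used at most once and late cases may
  receive fewer than the requested number.
* **dummy-index-date matching** (:func:`match_on_index`) — controls must
  additionally come from the same practice and have a consultation within
  ``index_diff_limit`` days of the case's index date; the qualifying
  consultation date becomes the control's dummy index date.

Matching is on equality of the categorical ``match_vars`` plus an optional
``extra_conditions`` where-template in which ``.(CASE$var)`` interpolates
the current case's value.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .query import where_mask
from .schema import EHRSchema, get_default_schema

__all__ = ["get_matches", "match_on_index"]

_METHODS = ("incidence_density", "exact")


def _eligible_mask(
    pool: pd.DataFrame,
    case: pd.Series,
    match_vars: Sequence[str],
    extra_conditions: str | None,
) -> pd.Series:
    mask = pd.Series(True, index=pool.index)
    for var in match_vars:
        mask &= pool[var] == case[var]
    if extra_conditions:
        mask &= where_mask(pool, extra_conditions, env={"CASE": case})
    return mask


def _case_rngs(seed, n: int) -> list[np.random.Generator]:
    # per-case derived streams: the match table is reproducible for a fixed
    # seed no matter how cases are distributed across workers
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def get_matches(
    cases: pd.DataFrame,
    control_pool: pd.DataFrame,
    match_vars: Sequence[str],
    n_controls: int = 4,
    method: str = "incidence_density",
    diagnosis_date: str = "eventdate",
    extra_conditions: str | None = None,
    seed: int | None = None,
    schema: EHRSchema | None = None,
) -> pd.DataFrame:
    """Select up to ``n_controls`` matched controls per case.

    Returns the matched control rows with two added columns: ``case_id``
    (the case's patient id) and ``case_index`` (its positional index in
    ``cases``).  Cases are processed in input order — this matters for the
    exact method, where earlier cases deplete the pool.  Sampling within a
    case is uniform without replacement.
    """
    schema = schema or get_default_schema()
    if method not in _METHODS:
        raise ValueError(f"unknown matching method {method!r}; use one of {_METHODS}")
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1")
    pid = schema.patient_id

    pool = control_pool.copy()
    rngs = _case_rngs(seed, len(cases))
    matched: list[pd.DataFrame] = []
    for i, (_, case) in enumerate(cases.iterrows()):
        if pool.empty:
            break
        mask = _eligible_mask(pool, case, match_vars, extra_conditions)
        if method == "incidence_density":
            # diagnosis-free at the case's diagnosis date
            case_diag = case[diagnosis_date]
            if pd.notna(case_diag):
                pool_diag = pool[diagnosis_date]
                mask &= pool_diag.isna() | (pool_diag > case_diag)
        eligible = pool.index[mask]
        if len(eligible) == 0:
            continue
        k = min(n_controls, len(eligible))
        chosen_labels = eligible[np.sort(rngs[i].choice(len(eligible), size=k, replace=False))]
        picks = pool.loc[chosen_labels].copy()
        picks["case_id"] = case[pid]
        picks["case_index"] = i
        matched.append(picks)
        if method == "exact":
            pool = pool.drop(index=chosen_labels)
    if not matched:
        out = control_pool.iloc[0:0].copy()
        out["case_id"] = pd.Series(dtype=cases[pid].dtype if len(cases) else "int64")
        out["case_index"] = pd.Series(dtype="int64")
        return out
    return pd.concat(matched, ignore_index=True)


def _default_import(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix in (".txt", ".tsv") else ","
    return pd.read_csv(path, sep=sep)


def match_on_index(
    cases: pd.DataFrame,
    control_pool: pd.DataFrame,
    index_var: str,
    match_vars: Sequence[str],
    consult_path: str | Path,
    extra_conditions: str | None = None,
    index_diff_limit: int = 90,
    n_controls: int = 4,
    import_fn: Callable[[Path], pd.DataFrame] | None = None,
    file_format: str = "csv",
    consult_table: str = "Consultation",
    seed: int | None = None,
    schema: EHRSchema | None = None,
) -> pd.DataFrame:
    """Match controls within practice on a dummy index date.

    Consultation records are read from per-practice flat files
    ``<consult_table>_<practid>.<file_format>`` under ``consult_path`` (as
    written by :func:`~ehrkit.datastore.export_flat_files`), one file opened
    per practice.  A control is eligible if it shares the case's practice
    and ``match_vars``, satisfies ``extra_conditions``, and has at least one
    consultation within ``index_diff_limit`` days (inclusive) of the case's
    index date.  The qualifying consultation closest to the index date
    (ties: earliest date) becomes the control's ``dummy_index``.

    Setting ``index_diff_limit`` very large effectively drops the index-date
    constraint, reducing this to exact matching on practice + match_vars.
    """
    schema = schema or get_default_schema()
    pid, prac = schema.patient_id, schema.practice_id
    edate = schema.event_date
    consult_path = Path(consult_path)
    import_fn = import_fn or _default_import

    rngs = _case_rngs(seed, len(cases))
    matched: list[pd.DataFrame] = []
    for practid, case_group in cases.groupby(prac, sort=True):
        fpath = consult_path / f"{consult_table}_{practid}.{file_format}"
        if not fpath.exists():
            warnings.warn(f"no consultation file for practice {practid} at {fpath}; skipping")
            continue
        consults = import_fn(fpath)
        consults = consults[[pid, edate]].dropna()
        consult_dates = pd.to_datetime(consults[edate])
        practice_pool = control_pool[control_pool[prac] == practid]
        for i, (_, case) in zip(case_group.index.map(lambda ix: cases.index.get_loc(ix)),
                                case_group.iterrows()):
            if practice_pool.empty:
                continue
            mask = _eligible_mask(practice_pool, case, match_vars, extra_conditions)
            candidates = practice_pool[mask]
            if candidates.empty:
                continue
            index_date = pd.Timestamp(case[index_var])
            diffs = (consult_dates - index_date).dt.days.abs()
            near = consults[diffs <= index_diff_limit].copy()
            if near.empty:
                continue
            near["_diff"] = diffs[diffs <= index_diff_limit]
            near = near.sort_values(["_diff", edate, pid], kind="stable")
            dummy = near.drop_duplicates(subset=pid, keep="first").set_index(pid)[edate]
            candidates = candidates[candidates[pid].isin(dummy.index)]
            if candidates.empty:
                continue
            k = min(n_controls, len(candidates))
            chosen = rngs[i].choice(len(candidates), size=k, replace=False)
            picks = candidates.iloc[np.sort(chosen)].copy()
            picks["dummy_index"] = picks[pid].map(dummy)
            picks["case_id"] = case[pid]
            picks["case_index"] = i
            matched.append(picks)
    if not matched:
        out = control_pool.iloc[0:0].copy()
        for col in ("dummy_index", "case_id", "case_index"):
            out[col] = pd.Series(dtype="object")
        return out
    return pd.concat(matched, ignore_index=True)
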