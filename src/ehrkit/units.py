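"""Standardisation of glycaemic test values to IFCC mmol/mol.

HbA1c is recorded in UK primary care in a mix of units — IFCC mmol/mol,
DCCT/NGSP %, and occasionally raw fractions — and the closely analogous
fructosamine test (µmol/L) can be mapped onto the same scale for direct
comparison.  :func:`standardize_hba1c` infers the unit of each record
(from an explicit unit code when present, otherwise from the value's
magnitude), converts to mmol/mol, and removes values outside a plausible
physiological range (obvious mis-codings).

All detection bounds and conversion coefficients are configuration
(:class:`HbA1cConfig`), not hard-coded: the defaults use the NGSP↔IFCC
master equation ``IFCC = (NGSP% − 2.15) × 10.929`` and the common
fructosamine↔HbA1c% approximation ``% = 0.017 × µmol/L + 1.61``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["HbA1cConfig", "standardize_hba1c"]

_ENTITIES = ("hba1c", "fructosamine")


@dataclass
class HbA1cConfig:
    """Unit-detection bounds and conversion coefficients.

    ``percent_range`` and ``mmol_mol_range`` are half-open value windows used
    to infer the unit of an HbA1c record with no unit code;
    ``fructosamine_range`` (µmol/L) plays the same role for fructosamine.
    ``plausible_range`` (mmol/mol) is the post-conversion filter.
    """

    percent_range: tuple[float, float] = (2.5, 25.0)
    mmol_mol_range: tuple[float, float] = (25.0, 250.0)
    fructosamine_range: tuple[float, float] = (100.0, 1500.0)
    #: (offset, slope): ifcc = (percent - offset) * slope
    ngsp_to_ifcc: tuple[float, float] = (2.15, 10.929)
    #: (slope, offset): percent = slope * umol_l + offset
    fructosamine_to_percent: tuple[float, float] = (0.017, 1.61)
    plausible_range: tuple[float, float] = (10.0, 195.0)
    #: explicit unit-code → unit mappings, consulted before the heuristics
    unit_codes: dict = field(
        default_factory=lambda: {"%": "percent", "mmol/mol": "mmol_mol", "umol/L": "fructosamine"}
    )


def _percent_to_ifcc(v: pd.Series, cfg: HbA1cConfig) -> pd.Series:
    offset, slope = cfg.ngsp_to_ifcc
    return (v - offset) * slope


def standardize_hba1c(
    records: pd.DataFrame,
    config: HbA1cConfig | None = None,
    entity_col: str = "entity",
    value_col: str = "value",
    unit_col: str | None = None,
    return_removed: bool = False,
):
    """Convert HbA1c/fructosamine records to a common mmol/mol scale.

    ``records`` must already be restricted to HbA1c and fructosamine
    entities (entity values ``"hba1c"`` / ``"fructosamine"``).  Returns the
    retained records with an added ``hba1c_score`` column; with
    ``return_removed`` also the count of records dropped (negative values,
    un-inferrable units, out-of-plausible-range results).
    """
    cfg = config or HbA1cConfig()
    unknown = set(records[entity_col].dropna().unique()) - set(_ENTITIES)
    if unknown:
        raise ValueError(
            f"unknown entities {sorted(unknown)}; restrict records to {_ENTITIES}"
        )
    df = records.copy()
    v = pd.to_numeric(df[value_col], errors="coerce")
    score = pd.Series(np.nan, index=df.index)

    is_hba1c = df[entity_col] == "hba1c"
    is_fruct = df[entity_col] == "fructosamine"
    valid = v.notna() & (v > 0)

    unit = pd.Series(None, index=df.index, dtype="object")
    if unit_col is not None and unit_col in df.columns:
        unit = df[unit_col].map(cfg.unit_codes)

    # explicit unit codes first, then magnitude heuristics
    pr, mr, fr = cfg.percent_range, cfg.mmol_mol_range, cfg.fructosamine_range
    as_percent = valid & is_hba1c & (
        (unit == "percent") | (unit.isna() & (v >= pr[0]) & (v < pr[1]))
    )
    as_ifcc = valid & is_hba1c & (
        (unit == "mmol_mol") | (unit.isna() & (v >= mr[0]) & (v < mr[1]))
    )
    as_fruct = valid & is_fruct & (v >= fr[0]) & (v < fr[1])

    score[as_ifcc] = v[as_ifcc]
    score[as_percent] = _percent_to_ifcc(v[as_percent], cfg)
    slope, offset = cfg.fructosamine_to_percent
    score[as_fruct] = _percent_to_ifcc(slope * v[as_fruct] + offset, cfg)

    lo, hi = cfg.plausible_range
    keep = score.notna() & (score >= lo) & (score <= hi)
    out = df[keep].copy()
    out["hba1c_score"] = score[keep]
    if return_removed:
        return out, int((~keep).sum())
    return out
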