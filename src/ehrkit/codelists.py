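"""Clinical code list construction from keyword and code searches.

A study's conditions, exposures and outcomes are defined by lists of
clinical codes.  Draft lists are built in two stages: a
:class:`MedicalDefinition` captures the search (terms, codes, test terms,
drug terms, drug product codes), then :func:`build_definition_lists` runs it
against the medical and drug product lookup tables shipped with the EHR,
producing draft lists for clinical review.

Search semantics:

* within one group, every conjunct must appear, in any order, as a
  case-insensitive **substring** of the whitespace-normalised description
  (so ``"diabetes"`` does *not* match ``"diabetic"`` — substring, not
  stemmed; see the methods note);
* groups are OR-ed; ``exclude`` groups remove rows after inclusion;
* clinical codes match by prefix; a range ``"E114-E117z"`` matches codes
  lexically between its endpoints;
* a leading ``-`` on an entry marks the group as an exclusion;
* underscores in terms are treated as spaces.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "TermGroup",
    "MedicalDefinition",
    "parse_definition",
    "import_definitions",
    "build_definition_lists",
    "extract_keywords",
]

_KINDS = ("terms", "codes", "tests", "drugs", "drugcodes")


@dataclass
class TermGroup:
    """One search group: all conjuncts must match (logical AND)."""

    status: str  # "include" | "exclude"
    conjuncts: list[str]

    def __post_init__(self) -> None:
        if self.status not in ("include", "exclude"):
            raise ValueError(f"unknown status {self.status!r}")
        if not self.conjuncts:
            raise ValueError("a search group must have at least one conjunct")


@dataclass
class MedicalDefinition:
    """A full code-list search definition across the five search kinds."""

    terms: list[TermGroup] = field(default_factory=list)
    codes: list[TermGroup] = field(default_factory=list)
    tests: list[TermGroup] = field(default_factory=list)
    drugs: list[TermGroup] = field(default_factory=list)
    drugcodes: list[TermGroup] = field(default_factory=list)


def _parse_group(item: str | Sequence[str]) -> TermGroup:
    if isinstance(item, str):
        item = [item]
    conjuncts = [str(c) for c in item]
    status = "include"
    first = conjuncts[0].strip()
    # hyphen and unicode-dash prefixes both mark exclusions
    if first.startswith(("-", "‐", "‑", "‒", "–", "−")):
        status = "exclude"
        conjuncts[0] = first.lstrip("-‐‑‒–−").strip()
    conjuncts = [c.replace("_", " ").strip() for c in conjuncts if c.strip()]
    return TermGroup(status, conjuncts)


def parse_definition(
    terms: Iterable | None = None,
    codes: Iterable | None = None,
    tests: Iterable | None = None,
    drugs: Iterable | None = None,
    drugcodes: Iterable | None = None,
) -> MedicalDefinition:
    """Build a :class:`MedicalDefinition` from raw search lists.

    Each element of an argument list is either a single search string or a
    sequence of strings forming one AND group.  ``None`` means that kind is
    not searched.
    """
    build = lambda items: [_parse_group(it) for it in items] if items else []
    return MedicalDefinition(
        terms=build(terms),
        codes=build(codes),
        tests=build(tests),
        drugs=build(drugs),
        drugcodes=build(drugcodes),
    )


def import_definitions(csv_path: str | Path) -> MedicalDefinition:
    """Read a definition from CSV rows ``definition,status,items...``.

    Cells after the first item on a row are additional conjuncts of the
    same AND group.
    """
    groups: dict[str, list[TermGroup]] = {k: [] for k in _KINDS}
    n_rows = 0
    with open(csv_path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or not any(cell.strip() for cell in row):
                continue
            kind = row[0].strip().lower()
            if n_rows == 0 and kind == "definition":
                continue  # header
            if kind not in _KINDS:
                raise ValueError(
                    f"{csv_path}, row {lineno}: unknown definition kind {kind!r}"
                )
            status = row[1].strip().lower()
            if status not in ("include", "exclude"):
                raise ValueError(f"{csv_path}, row {lineno}: unknown status {status!r}")
            items = [c.replace("_", " ").strip() for c in row[2:] if c.strip()]
            if not items:
                raise ValueError(f"{csv_path}, row {lineno}: no search items")
            groups[kind].append(TermGroup(status, items))
            n_rows += 1
    if n_rows == 0:
        raise ValueError(f"{csv_path}: no definitions")
    return MedicalDefinition(**groups)


# ---------------------------------------------------------------------------
# searching


def _norm(text: str) -> str:
    return " ".join(str(text).lower().split())


def _desc_matches(description: str, group: TermGroup) -> bool:
    desc = _norm(description)
    return all(_norm(c) in desc for c in group.conjuncts)


def _term_hits(lookup: pd.DataFrame, groups: list[TermGroup], desc_col: str) -> pd.DataFrame:
    if lookup is None or not groups:
        return pd.DataFrame()
    includes = [g for g in groups if g.status == "include"]
    excludes = [g for g in groups if g.status == "exclude"]
    rows = []
    for _, row in lookup.iterrows():
        desc = row[desc_col]
        if pd.isna(desc):
            continue
        for g in includes:
            if _desc_matches(desc, g):
                hit = row.copy()
                hit["matched_group"] = " & ".join(g.conjuncts)
                rows.append(hit)
                break
    if not rows:
        return pd.DataFrame(columns=list(lookup.columns) + ["matched_group"])
    out = pd.DataFrame(rows)
    keep = ~out[desc_col].map(lambda d: any(_desc_matches(d, g) for g in excludes))
    return out[keep].reset_index(drop=True)


def _code_matches(code: str, pattern: str) -> bool:
    code = str(code)
    if "-" in pattern[1:]:  # range "A-B" (a leading '-' is an exclusion marker)
        lo, hi = pattern.split("-", 1)
        return lo <= code <= hi
    return code.startswith(pattern)


def _code_hits(lookup: pd.DataFrame, groups: list[TermGroup], code_col: str) -> pd.DataFrame:
    if lookup is None or not groups:
        return pd.DataFrame()
    includes = [c for g in groups if g.status == "include" for c in g.conjuncts]
    excludes = [c for g in groups if g.status == "exclude" for c in g.conjuncts]
    rows = []
    for _, row in lookup.iterrows():
        code = row[code_col]
        if pd.isna(code):
            continue
        for pattern in includes:
            if _code_matches(code, pattern):
                hit = row.copy()
                hit["matched_group"] = pattern
                rows.append(hit)
                break
    if not rows:
        return pd.DataFrame(columns=list(lookup.columns) + ["matched_group"])
    out = pd.DataFrame(rows)
    keep = ~out[code_col].map(lambda c: any(_code_matches(c, p) for p in excludes))
    return out[keep].reset_index(drop=True)


def build_definition_lists(
    definition: MedicalDefinition,
    medical_table: pd.DataFrame | None = None,
    drug_table: pd.DataFrame | None = None,
    test_table: pd.DataFrame | None = None,
    medical_desc_col: str = "desc",
    medical_code_col: str = "readcode",
    drug_name_col: str = "productname",
    drug_code_col: str = "prodcode",
    test_desc_col: str = "desc",
) -> dict[str, pd.DataFrame]:
    """Run a definition's searches against lookup tables.

    Returns draft hit lists keyed ``terms``, ``codes``, ``tests``,
    ``drugs``, ``drugcodes``; each carries a ``matched_group`` provenance
    column naming the group (or code pattern) that matched.
    """
    return {
        "terms": _term_hits(medical_table, definition.terms, medical_desc_col),
        "codes": _code_hits(medical_table, definition.codes, medical_code_col),
        "tests": _term_hits(
            test_table if test_table is not None else medical_table,
            definition.tests,
            test_desc_col,
        ),
        "drugs": _term_hits(drug_table, definition.drugs, drug_name_col),
        "drugcodes": _code_hits(drug_table, definition.drugcodes, drug_code_col),
    }


def extract_keywords(
    lookup: pd.DataFrame, keywords: Sequence[str], column: str = "desc"
) -> pd.DataFrame:
    """Rows of a lookup table whose ``column`` contains any keyword."""
    kws = [_norm(k) for k in keywords]
    mask = lookup[column].map(
        lambda d: (not pd.isna(d)) and any(k in _norm(d) for k in kws)
    )
    return lookup[mask].reset_index(drop=True)
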