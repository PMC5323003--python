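"""Registry of EHR-dialect attributes.

Every primary-care EHR extract (CPRD, THIN, QResearch, ...) uses its own
column names for the same concepts: the patient identifier, the event date,
registration and censoring dates, and so on.  :class:`EHRSchema` maps a fixed
set of *roles* onto the column names of a particular dialect so that the rest
of the toolkit can be written against roles rather than hard-coded columns.

The bundled default is the CPRD GOLD dialect (:func:`default_cprd_schema`).
Other dialects are configuration, not code: schemas round-trip through YAML.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "DATE_ROLES",
    "CohortCriteria",
    "EHRSchema",
    "default_cprd_schema",
    "get_default_schema",
    "set_default_schema",
]

#: The eight date roles every schema must map to a column name.
DATE_ROLES = (
    "event",
    "entry",
    "last_coll",
    "up_to_std",
    "first_reg",
    "current_reg",
    "transfer_out",
    "death",
)


@dataclass
class CohortCriteria:
    """Columns that bound a patient's eligible follow-up.

    ``start_criteria`` are dates a patient must be past before contributing
    person-time (e.g. registration, practice up-to-standard); ``end_criteria``
    are dates that censor follow-up (transfer out, death, last collection).
    """

    start_criteria: list[str]
    end_criteria: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.start_criteria) & set(self.end_criteria)
        if overlap:
            raise ValueError(
                f"cohort start and end criteria must be disjoint; shared: {sorted(overlap)}"
            )


@dataclass
class EHRSchema:
    """Named-attribute registry describing one EHR dialect.

    Attribute names (as used by :meth:`get_attribute` / :meth:`set_attribute`)
    follow the conventional registry spelling, e.g. ``"patient_id"`` or
    ``"EHR_name"``; see :meth:`list_attributes` for the full set.
    """

    name: str = "CPRD"
    patient_id: str = "patid"
    practice_id: str = "practid"
    event_date: str = "eventdate"
    ehr_medcode: str = "medcode"
    birth_year: str = "yob"
    raw_date_format: str = "%Y-%m-%d"
    year_origin: int = 1800
    date_fields: dict[str, str] = field(default_factory=dict)
    cohort: CohortCriteria = field(
        default_factory=lambda: CohortCriteria([], ["_end"])
    )
    tables: list[str] = field(default_factory=list)
    lookup: dict[str, str] | None = None

    # registry attribute name -> dataclass field name
    _ATTR_FIELDS = {
        "EHR_name": "name",
        "patient_id": "patient_id",
        "practice_id": "practice_id",
        "event_date": "event_date",
        "ehr_medcode": "ehr_medcode",
        "birth_year": "birth_year",
        "raw_date_format": "raw_date_format",
        "year_origin": "year_origin",
        "date_fields": "date_fields",
        "cohort": "cohort",
        "tables": "tables",
        "lookup": "lookup",
    }

    def __post_init__(self) -> None:
        if isinstance(self.cohort, dict):
            self.cohort = CohortCriteria(**self.cohort)
        for attr in ("patient_id", "practice_id", "event_date", "ehr_medcode", "birth_year"):
            if not getattr(self, attr):
                raise ValueError(f"schema attribute {attr!r} must be a non-empty column name")
        if self.date_fields:
            missing = [r for r in DATE_ROLES if r not in self.date_fields]
            if missing:
                raise ValueError(f"date_fields missing roles: {missing}")
            empty = [r for r, c in self.date_fields.items() if not c]
            if empty:
                raise ValueError(f"date_fields with empty column names: {empty}")

    # -- registry access ---------------------------------------------------

    def get_attribute(self, name: str) -> Any:
        try:
            return getattr(self, self._ATTR_FIELDS[name])
        except KeyError:
            raise KeyError(
                f"unknown EHR attribute {name!r}; valid attributes: {self.list_attributes()}"
            ) from None

    def set_attribute(self, name: str, value: Any) -> "EHRSchema":
        """Return a copy of the schema with one attribute replaced."""
        if name not in self._ATTR_FIELDS:
            raise KeyError(
                f"unknown EHR attribute {name!r}; valid attributes: {self.list_attributes()}"
            )
        out = copy.deepcopy(self)
        setattr(out, self._ATTR_FIELDS[name], value)
        return out

    def list_attributes(self) -> list[str]:
        """All registry attribute names, sorted case-insensitively."""
        return sorted(self._ATTR_FIELDS, key=str.lower)

    @property
    def date_columns(self) -> list[str]:
        """Distinct column names holding dates, in role order."""
        seen: list[str] = []
        for role in DATE_ROLES:
            col = self.date_fields.get(role)
            if col and col not in seen:
                seen.append(col)
        return seen

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["cohort"] = dataclasses.asdict(self.cohort)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "EHRSchema":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EHRSchema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_cprd_schema() -> EHRSchema:
    """The CPRD GOLD dialect.

    Birth years are stored in raw extracts as an offset from ``year_origin``
    (1800); cohort entry requires registration (``crd``) and the practice
    up-to-standard date (``uts``); follow-up is censored by transfer out
    (``tod``), death, or last data collection (``lcd``).
    """
    return EHRSchema(
        name="CPRD",
        patient_id="patid",
        practice_id="practid",
        event_date="eventdate",
        ehr_medcode="medcode",
        birth_year="yob",
        raw_date_format="%Y-%m-%d",
        year_origin=1800,
        date_fields={
            "event": "eventdate",
            "entry": "sysdate",
            "last_coll": "lcd",
            "up_to_std": "uts",
            "first_reg": "frd",
            "current_reg": "crd",
            "transfer_out": "tod",
            "death": "deathdate",
        },
        cohort=CohortCriteria(
            start_criteria=["crd", "uts"],
            end_criteria=["tod", "deathdate", "lcd"],
        ),
        tables=["Patient", "Practice", "Clinical", "Consultation", "Referral", "Therapy"],
        lookup=None,
    )


_default_schema: EHRSchema = default_cprd_schema()


def get_default_schema() -> EHRSchema:
    """The process-wide default schema (CPRD unless overridden)."""
    return _default_schema


def set_default_schema(schema: EHRSchema) -> None:
    """Replace the process-wide default schema (CLI convenience)."""
    global _default_schema
    _default_schema = schema
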