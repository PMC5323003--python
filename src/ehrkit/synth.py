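"""Synthetic CPRD-shaped EHR data.

Generates Practice, Patient, Clinical, Referral, Therapy and Consultation
tables with the layout of CPRD GOLD flat-file extracts, so the whole
import → query → prevalence → cohort → matching pipeline can be exercised
without any real (licensed) data.

Modelling choices (all exposed through :class:`SimConfig`):

* patients per practice are Poisson-distributed;
* each comorbidity is assigned independently per patient with its
  configured prevalence;
* survival after registration is exponential with hazard
  ``baseline_death_hazard × Π(hazard ratios of assigned comorbidities)``;
  transfer-out is an independent exponential;
* condition-coded event counts are Poisson in active person-time with
  event dates uniform over the active interval ``[crd, min(tod, death,
  study end)]``;
* consultation counts are Poisson at ``consultation_rate`` per person-year.

Patient ids follow the convention ``patid = serial × 1000 + practice id``
(so ``patid % 1000`` recovers the practice), matching the id patterns of
CPRD-style extracts.  A fixed seed yields byte-identical output.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .schema import EHRSchema, get_default_schema

__all__ = [
    "Comorbidity",
    "SimConfig",
    "simulate_practices",
    "simulate_patients",
    "simulate_clinical_events",
    "simulate_consultations",
    "simulate_ehr",
    "surv_sims",
    "write_flat_files",
]


@dataclass
class Comorbidity:
    """One simulated chronic condition."""

    name: str
    prevalence: float  # probability a patient has the condition
    medcodes: list[int]  # clinical code pool for its events
    hazard_ratio: float = 1.0  # multiplies the baseline death hazard
    prodcodes: list[int] = field(default_factory=list)  # therapy code pool


def _default_comorbidities() -> list[Comorbidity]:
    return [
        Comorbidity("hypertension", 0.25, [69753, 16059, 12948, 21826], 1.3, [71, 72, 73]),
        Comorbidity("chd", 0.10, [23579, 29643, 17133], 2.0, [81, 82]),
        Comorbidity("atrial_fibrilation", 0.08, [96277, 2212, 96076], 1.8, [91]),
        Comorbidity("diabetes", 0.12, [273, 277, 293, 351, 257], 1.5, [61, 62, 63]),
        Comorbidity("asthma", 0.15, [1095, 1105, 1116], 1.1, [51, 52]),
    ]


@dataclass
class SimConfig:
    """Parameters of the synthetic EHR world.

    Rates are per person-year; hazards are exponential rates per year.
    """

    n_practices: int = 10
    mean_patients_per_practice: float = 50.0
    study_start: str = "1995-01-01"
    study_end: str = "2015-01-01"
    comorbidities: list[Comorbidity] = field(default_factory=_default_comorbidities)
    consultation_rate: float = 4.0
    event_rate: float = 0.5  # condition-coded events per active person-year
    referral_prob: float = 0.2  # share of condition events also generating a referral
    therapy_rate: float = 2.0  # prescriptions per active person-year per condition
    baseline_death_hazard: float = 0.01
    transfer_out_rate: float = 0.02
    n_regions: int = 13
    birth_year_range: tuple[int, int] = (1920, 2000)
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("consultation_rate", "event_rate", "therapy_rate",
                     "baseline_death_hazard", "transfer_out_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_practices >= 1000:
            raise ValueError("practice ids must stay below 1000 for the patid encoding")


def _rng(cfg: SimConfig, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(cfg.seed if seed is None else seed)


def _date_range_days(start: str, end: str) -> int:
    return (pd.Timestamp(end) - pd.Timestamp(start)).days


def _iso(base: str, offset_days) -> list[str]:
    base_ts = pd.Timestamp(base)
    return [
        (base_ts + pd.Timedelta(days=int(d))).strftime("%Y-%m-%d")
        for d in np.atleast_1d(offset_days)
    ]


def simulate_practices(cfg: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Practice table: practid, region, uts (up-to-standard), lcd (last collection)."""
    rng = _rng(cfg, seed)
    practid = np.arange(1, cfg.n_practices + 1)
    region = rng.integers(1, cfg.n_regions + 1, size=cfg.n_practices)
    # up-to-standard a little after the study opens, collection to near its end
    uts_off = rng.integers(0, 3 * 365, size=cfg.n_practices)
    lcd_back = rng.integers(0, 365, size=cfg.n_practices)
    total = _date_range_days(cfg.study_start, cfg.study_end)
    return pd.DataFrame(
        {
            "practid": practid,
            "region": region,
            "uts": _iso(cfg.study_start, uts_off),
            "lcd": _iso(cfg.study_start, total - lcd_back),
        }
    )


def simulate_patients(
    cfg: SimConfig, practices: pd.DataFrame, seed: int | None = None
) -> pd.DataFrame:
    """Patient table plus per-comorbidity 0/1 assignment columns.

    Death and transfer-out are competing exponentials from registration;
    dates falling beyond the study end are censored to missing.
    """
    rng = _rng(cfg, seed)
    total_days = _date_range_days(cfg.study_start, cfg.study_end)
    rows = []
    for practid in practices["practid"]:
        n = rng.poisson(cfg.mean_patients_per_practice)
        for serial in range(1, n + 1):
            patid = serial * 1000 + int(practid)
            gender = int(rng.integers(0, 2))
            yob = int(rng.integers(*cfg.birth_year_range))
            crd_off = int(rng.integers(0, max(total_days - 365, 1)))
            flags = {c.name: int(rng.random() < c.prevalence) for c in cfg.comorbidities}
            hazard = cfg.baseline_death_hazard * float(
                np.prod([c.hazard_ratio for c in cfg.comorbidities if flags[c.name]])
            )
            death_days = (
                rng.exponential(1.0 / hazard) * 365.25 if hazard > 0 else np.inf
            )
            tod_days = (
                rng.exponential(1.0 / cfg.transfer_out_rate) * 365.25
                if cfg.transfer_out_rate > 0
                else np.inf
            )
            death_off = crd_off + death_days
            tod_off = crd_off + tod_days
            deathdate = (
                _iso(cfg.study_start, int(death_off))[0] if death_off <= total_days else None
            )
            tod = (
                _iso(cfg.study_start, int(tod_off))[0]
                if tod_off <= total_days and tod_off < death_off
                else None
            )
            rows.append(
                {
                    "patid": patid,
                    "practid": int(practid),
                    "gender": gender,
                    "yob": yob,
                    "frd": _iso(cfg.study_start, crd_off)[0],
                    "crd": _iso(cfg.study_start, crd_off)[0],
                    "tod": tod,
                    "deathdate": deathdate,
                    **flags,
                }
            )
    return pd.DataFrame(rows)


def _active_interval(
    patient: Mapping, cfg: SimConfig, practices_lcd: Mapping[int, str]
) -> tuple[pd.Timestamp, pd.Timestamp]:
    start = pd.Timestamp(patient["crd"])
    ends = [pd.Timestamp(cfg.study_end)]
    for key in ("tod", "deathdate"):
        if patient.get(key):
            ends.append(pd.Timestamp(patient[key]))
    lcd = practices_lcd.get(patient["practid"])
    if lcd:
        ends.append(pd.Timestamp(lcd))
    return start, min(ends)


def simulate_clinical_events(
    cfg: SimConfig,
    patients: pd.DataFrame,
    practices: pd.DataFrame | None = None,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Clinical, Referral and Therapy tables for assigned comorbidities.

    Every event date lies within its patient's active interval; medcodes are
    drawn from the assigned condition's pool.
    """
    rng = _rng(cfg, seed)
    lcd_map = (
        dict(zip(practices["practid"], practices["lcd"])) if practices is not None else {}
    )
    clinical, referral, therapy = [], [], []
    consid = 0
    for patient in patients.to_dict("records"):
        start, end = _active_interval(patient, cfg, lcd_map)
        span_days = max((end - start).days, 0)
        years = span_days / 365.25
        for condition in cfg.comorbidities:
            if not patient.get(condition.name):
                continue
            n_events = rng.poisson(cfg.event_rate * years)
            offsets = np.sort(rng.integers(0, span_days + 1, size=n_events))
            for off in offsets:
                consid += 1
                date = (start + pd.Timedelta(days=int(off))).strftime("%Y-%m-%d")
                row = {
                    "patid": patient["patid"],
                    "eventdate": date,
                    "constype": int(rng.integers(0, 2)),
                    "consid": consid,
                    "medcode": int(rng.choice(condition.medcodes)),
                    "comorbidity": condition.name,
                    "practid": patient["practid"],
                }
                clinical.append(row)
                if rng.random() < cfg.referral_prob:
                    referral.append(dict(row))
            n_rx = rng.poisson(cfg.therapy_rate * years) if condition.prodcodes else 0
            for off in np.sort(rng.integers(0, span_days + 1, size=n_rx)):
                therapy.append(
                    {
                        "patid": patient["patid"],
                        "eventdate": (start + pd.Timedelta(days=int(off))).strftime("%Y-%m-%d"),
                        "prodcode": int(rng.choice(condition.prodcodes)),
                        "comorbidity": condition.name,
                        "practid": patient["practid"],
                    }
                )
    cols = ["patid", "eventdate", "constype", "consid", "medcode", "comorbidity", "practid"]
    tcols = ["patid", "eventdate", "prodcode", "comorbidity", "practid"]
    return {
        "Clinical": pd.DataFrame(clinical, columns=cols),
        "Referral": pd.DataFrame(referral, columns=cols),
        "Therapy": pd.DataFrame(therapy, columns=tcols),
    }


def simulate_consultations(
    cfg: SimConfig,
    patients: pd.DataFrame,
    practices: pd.DataFrame | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Consultation table: per-patient counts ~ rate × active person-years."""
    rng = _rng(cfg, seed)
    lcd_map = (
        dict(zip(practices["practid"], practices["lcd"])) if practices is not None else {}
    )
    rows = []
    consid = 0
    for patient in patients.to_dict("records"):
        start, end = _active_interval(patient, cfg, lcd_map)
        span_days = max((end - start).days, 0)
        n = rng.poisson(cfg.consultation_rate * span_days / 365.25)
        for off in np.sort(rng.integers(0, span_days + 1, size=n)):
            consid += 1
            rows.append(
                {
                    "patid": patient["patid"],
                    "eventdate": (start + pd.Timedelta(days=int(off))).strftime("%Y-%m-%d"),
                    "constype": int(rng.integers(0, 2)),
                    "consid": consid,
                    "practid": patient["practid"],
                }
            )
    return pd.DataFrame(rows, columns=["patid", "eventdate", "constype", "consid", "practid"])


def simulate_ehr(cfg: SimConfig | None = None, seed: int | None = None) -> dict[str, pd.DataFrame]:
    """All six tables from one seed, with derived sub-seeds per table."""
    cfg = cfg or SimConfig()
    base = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    s_prac, s_pat, s_ev, s_cons = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4))
    practices = simulate_practices(cfg, seed=s_prac)
    patients = simulate_patients(cfg, practices, seed=s_pat)
    events = simulate_clinical_events(cfg, patients, practices, seed=s_ev)
    consultations = simulate_consultations(cfg, patients, practices, seed=s_cons)
    patient_cols = ["patid", "practid", "gender", "yob", "frd", "crd", "tod", "deathdate"]
    return {
        "Practice": practices,
        "Patient": patients[patient_cols + [c.name for c in cfg.comorbidities]],
        "Consultation": consultations,
        **events,
    }


def surv_sims(
    n: int,
    hazard: float,
    censor_rate: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Exponential survival times with independent exponential censoring.

    Returns columns ``time`` (observed time) and ``event`` (1 = event
    observed, 0 = censored).  With ``censor_rate`` 0 every event is
    observed and the mean observed time estimates ``1/hazard``.
    """
    if hazard <= 0:
        raise ValueError("hazard must be > 0")
    rng = np.random.default_rng(seed)
    t = rng.exponential(1.0 / hazard, size=n)
    if censor_rate > 0:
        c = rng.exponential(1.0 / censor_rate, size=n)
    else:
        c = np.full(n, np.inf)
    return pd.DataFrame({"time": np.minimum(t, c), "event": (t <= c).astype(int)})


def write_flat_files(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    prefix: str = "ehr",
    raw_birth_year: bool = True,
    schema: EHRSchema | None = None,
) -> list[Path]:
    """Write tables as ``<prefix>_<Filetype>.txt`` tab-delimited flat files.

    With ``raw_birth_year`` the patient birth-year column is written as an
    offset from the schema's ``year_origin`` (as raw CPRD extracts are), so
    imports exercise the year-origin conversion.
    """
    schema = schema or get_default_schema()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        df = df.copy()
        yob = schema.birth_year
        if raw_birth_year and yob in df.columns:
            df[yob] = df[yob] - schema.year_origin
        path = out_dir / f"{prefix}_{name}.txt"
        df.to_csv(path, sep="\t", index=False, na_rep="")
        written.append(path)
    return written
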