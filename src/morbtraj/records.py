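"""Normalisation of raw ICD-10 coded diagnosis events into ordered block sequences.

The analysis unit is the per-patient, date-ordered, deduplicated sequence of
ICD-10 *blocks*: codes are mapped to blocks, non-disease chapters (letters
O–Z: obstetric, perinatal, congenital, symptom, injury and healthcare-contact
codes) are removed, only the earliest instance of each block is kept, and
same-date ties are broken by a seeded deterministic shuffle.  Blocks below a
prevalence threshold within each sex are then filtered out.

Re-hospitalisation outcomes are built from the *unfiltered* admission-date
stream (all coded events, no O–Z or prevalence filtering), which
:func:`normalize_records` retains on the cohort as ``admissions``.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Iterator

import numpy as np
import pandas as pd

from .catalog import UNMAPPED, BlockCatalog

__all__ = [
    "DiagnosisEvent",
    "PatientRecord",
    "Cohort",
    "normalize_records",
    "prevalence_filter",
    "age_at_diagnosis",
    "HALF_YEAR_DAYS",
    "DAYS_PER_YEAR",
]

logger = logging.getLogger(__name__)

#: Midpoint of a year in days, accounting for leap years.
HALF_YEAR_DAYS = 182.625
DAYS_PER_YEAR = 365.25

_EVENT_COLS = ["patient_id", "sex", "icd10_code", "diagnosis_date"]
_SEXES = ("female", "male")

# Chapters starting with these letters code procedures, symptoms, injuries and
# healthcare interactions rather than disease conditions.
_EXCLUDED_LETTERS = set("OPQRSTUVWXYZ")


@dataclass(frozen=True)
class DiagnosisEvent:
    """One first-in-record block diagnosis of one patient."""

    block_id: str
    diagnosis_date: date
    position: int
    days_since_first: float


@dataclass(frozen=True)
class PatientRecord:
    """A sex-labelled ordered diagnosis sequence plus follow-up metadata."""

    patient_id: str
    sex: str
    events: tuple[DiagnosisEvent, ...]
    age_at_assessment: float | None = None
    assessment_date: date | None = None
    death_date: date | None = None
    followup_end: date | None = None

    @property
    def n_diagnoses(self) -> int:
        return len(self.events)

    @property
    def is_multimorbid(self) -> bool:
        return len(self.events) >= 2


@dataclass
class Cohort:
    """Normalised diagnosis events plus per-patient metadata.

    Attributes
    ----------
    events:
        Long table with columns ``patient_id, sex, block_id, chapter_id,
        diagnosis_date, position, days_since_first``, sorted within patient.
    meta:
        One row per patient: ``patient_id, sex, age_at_assessment,
        assessment_date, death_date, followup_end``.
    admissions:
        Unfiltered per-patient admission dates (``patient_id,
        admission_date``) used for re-hospitalisation outcomes.
    tie_seed:
        Seed of the deterministic same-date tie-break, recorded for
        reproducibility.
    """

    events: pd.DataFrame
    meta: pd.DataFrame
    admissions: pd.DataFrame | None = None
    tie_seed: int = 0

    def patients(self, sex: str | None = None) -> pd.Index:
        meta = self.meta if sex is None else self.meta[self.meta["sex"] == sex]
        return pd.Index(meta["patient_id"])

    def subset(self, patient_ids) -> "Cohort":
        ids = set(patient_ids)
        return replace(
            self,
            events=self.events[self.events["patient_id"].isin(ids)].reset_index(drop=True),
            meta=self.meta[self.meta["patient_id"].isin(ids)].reset_index(drop=True),
            admissions=None
            if self.admissions is None
            else self.admissions[self.admissions["patient_id"].isin(ids)].reset_index(drop=True),
        )

    def by_sex(self, sex: str) -> "Cohort":
        if sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {sex!r}")
        return self.subset(self.meta.loc[self.meta["sex"] == sex, "patient_id"])

    def multimorbid(self) -> "Cohort":
        counts = self.events.groupby("patient_id")["block_id"].nunique()
        return self.subset(counts.index[counts >= 2])

    def iter_patients(self) -> Iterator[PatientRecord]:
        meta = self.meta.set_index("patient_id")
        for pid, grp in self.events.groupby("patient_id", sort=True):
            row = meta.loc[pid]
            events = tuple(
                DiagnosisEvent(
                    block_id=e.block_id,
                    diagnosis_date=e.diagnosis_date.date()
                    if hasattr(e.diagnosis_date, "date")
                    else e.diagnosis_date,
                    position=int(e.position),
                    days_since_first=float(e.days_since_first),
                )
                for e in grp.itertuples(index=False)
            )
            yield PatientRecord(
                patient_id=pid,
                sex=row["sex"],
                events=events,
                age_at_assessment=row.get("age_at_assessment"),
                assessment_date=_as_date(row.get("assessment_date")),
                death_date=_as_date(row.get("death_date")),
                followup_end=_as_date(row.get("followup_end")),
            )


def _as_date(value):
    if value is None or (isinstance(value, float) and np.isnan(value)) or pd.isna(value):
        return None
    return value.date() if hasattr(value, "date") else value


def _tie_key(tie_seed: int, patient_id, block_id: str) -> int:
    """Deterministic pseudo-random key, stable across runs and row order."""
    return zlib.crc32(f"{tie_seed}|{patient_id}|{block_id}".encode())


def _finalize_order(events: pd.DataFrame, tie_seed: int) -> pd.DataFrame:
    """Sort events within patient, breaking same-date ties by seeded key, then
    assign 1-based positions and days since each patient's first diagnosis."""
    ev = events.copy()
    ev["_tie"] = [
        _tie_key(tie_seed, p, b) for p, b in zip(ev["patient_id"], ev["block_id"])
    ]
    ev = ev.sort_values(
        ["patient_id", "diagnosis_date", "_tie", "block_id"], kind="stable"
    ).drop(columns="_tie")
    ev["position"] = ev.groupby("patient_id").cumcount() + 1
    first = ev.groupby("patient_id")["diagnosis_date"].transform("min")
    ev["days_since_first"] = (ev["diagnosis_date"] - first).dt.days.astype(float)
    return ev.reset_index(drop=True)


def normalize_records(
    raw: pd.DataFrame,
    catalog: BlockCatalog,
    tie_seed: int = 0,
    meta: pd.DataFrame | None = None,
    filter_oz: bool = True,
    dedupe: bool = True,
) -> Cohort:
    """Normalise a raw coded event table into an analysis-ready :class:`Cohort`.

    Parameters
    ----------
    raw:
        Columns ``patient_id, sex, icd10_code, diagnosis_date``.  Codes may be
        3- or 4-character ICD-10 codes (4-character codes map via their
        3-character prefix) or already-mapped block ids.
    catalog:
        Block catalog used for the mapping; unmapped codes are dropped with a
        logged count.
    tie_seed:
        Seed for the deterministic same-date tie-break (diagnoses recorded on
        the same date carry no usable order, so ties are shuffled
        reproducibly).
    meta:
        Optional per-patient table with ``age_at_assessment, assessment_date,
        death_date, followup_end``; merged into the cohort and validated
        (no diagnosis may postdate death).
    filter_oz:
        Drop blocks in chapters O–Z (non-disease codes).  Disable for
        outcome-stream construction, which uses unfiltered admissions.
    dedupe:
        Keep only the earliest instance of each block per patient.
    """
    missing = [c for c in _EVENT_COLS if c not in raw.columns]
    if missing:
        raise ValueError(f"raw events missing columns: {missing}")
    bad_sex = set(raw["sex"].unique()) - set(_SEXES)
    if bad_sex:
        raise ValueError(f"unrecognised sex values: {sorted(bad_sex)}")

    ev = raw[_EVENT_COLS].copy()
    ev["diagnosis_date"] = pd.to_datetime(ev["diagnosis_date"])

    mapping = {c: catalog.lookup(c) for c in ev["icd10_code"].unique()}
    ev["block_id"] = ev["icd10_code"].map(lambda c: mapping[c][0])
    ev["chapter_id"] = ev["icd10_code"].map(lambda c: mapping[c][1])

    # unfiltered admission stream, kept before any dropping
    admissions = (
        ev[["patient_id", "diagnosis_date"]]
        .drop_duplicates()
        .rename(columns={"diagnosis_date": "admission_date"})
        .sort_values(["patient_id", "admission_date"], kind="stable")
        .reset_index(drop=True)
    )

    n_unmapped = int((ev["block_id"] == UNMAPPED).sum())
    if n_unmapped:
        logger.info("dropping %d events with codes outside the catalog", n_unmapped)
        ev = ev[ev["block_id"] != UNMAPPED]

    if filter_oz:
        excluded = ev["block_id"].str[0].isin(_EXCLUDED_LETTERS)
        if excluded.any():
            logger.info("dropping %d events in excluded chapters O-Z", int(excluded.sum()))
            ev = ev[~excluded]

    n_before = len(ev)
    ev = ev.drop_duplicates(subset=["patient_id", "block_id", "diagnosis_date"])
    if len(ev) < n_before:
        logger.info("collapsed %d duplicate (patient, block, date) rows", n_before - len(ev))

    if dedupe:
        ev = (
            ev.sort_values(["patient_id", "block_id", "diagnosis_date"], kind="stable")
            .groupby(["patient_id", "block_id"], as_index=False)
            .first()
        )

    ev = ev[["patient_id", "sex", "block_id", "chapter_id", "diagnosis_date"]]
    ev = _finalize_order(ev, tie_seed)

    if meta is not None:
        meta = meta.copy()
        for col in ("assessment_date", "death_date", "followup_end"):
            if col in meta.columns:
                meta[col] = pd.to_datetime(meta[col])
        if "death_date" in meta.columns:
            death = meta.set_index("patient_id")["death_date"]
            ev_death = ev["patient_id"].map(death)
            after = ev["diagnosis_date"] > ev_death
            if bool(after.fillna(False).any()):
                bad = ev.loc[after.fillna(False), "patient_id"].unique()
                raise ValueError(
                    f"diagnosis events after death_date for patients: {list(bad[:5])}"
                )
    else:
        meta = (
            ev.groupby("patient_id", as_index=False)
            .agg(sex=("sex", "first"))
            .assign(
                age_at_assessment=np.nan,
                assessment_date=pd.NaT,
                death_date=pd.NaT,
                followup_end=pd.NaT,
            )
        )

    return Cohort(events=ev, meta=meta.reset_index(drop=True), admissions=admissions, tie_seed=tie_seed)


def prevalence_filter(
    cohort: Cohort, threshold: float = 0.01
) -> tuple[Cohort, dict[str, set[str]]]:
    """Drop blocks carried by at most *threshold* of patients within each sex.

    Retention is strict (``carrier proportion > threshold``).  Positions and
    days-since-first are recomputed on the surviving events, so a patient's
    clock restarts at their first *retained* diagnosis.

    Returns the filtered cohort and the retained block set per sex.
    """
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    if cohort.meta.empty:
        raise ValueError("empty cohort")

    retained: dict[str, set[str]] = {}
    keep_masks = []
    for sex in _SEXES:
        n_sex = int((cohort.meta["sex"] == sex).sum())
        ev_sex = cohort.events[cohort.events["sex"] == sex]
        if n_sex == 0:
            retained[sex] = set()
            continue
        carriers = ev_sex.groupby("block_id")["patient_id"].nunique()
        kept = set(carriers.index[carriers / n_sex > threshold])
        retained[sex] = kept
        keep_masks.append((cohort.events["sex"] == sex) & cohort.events["block_id"].isin(kept))

    keep = np.logical_or.reduce(keep_masks) if keep_masks else np.zeros(len(cohort.events), bool)
    ev = cohort.events[keep][
        ["patient_id", "sex", "block_id", "chapter_id", "diagnosis_date"]
    ]
    ev = _finalize_order(ev, cohort.tie_seed)
    filtered = replace(cohort, events=ev)
    return filtered, retained


def age_at_diagnosis(age_at_assessment, assessment_date, diagnosis_date):
    """Age in years at diagnosis, from the integer recorded age at assessment.

    Recorded age is a floor in whole years, so half a year (182.625 days,
    the leap-aware midpoint) is added before offsetting by the signed
    day-difference between diagnosis and assessment.  Accepts scalars or
    aligned vectors.
    """
    delta = pd.to_datetime(diagnosis_date) - pd.to_datetime(assessment_date)
    if isinstance(delta, pd.Series):
        days = delta.dt.days
    elif isinstance(delta, pd.TimedeltaIndex):
        days = delta.days.to_numpy()
    else:
        days = delta.days
    return age_at_assessment + (days + HALF_YEAR_DAYS) / DAYS_PER_YEAR
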