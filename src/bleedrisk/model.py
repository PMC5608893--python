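"""Domain model for anticoagulation cohorts and delimited-text I/O.

A cohort is stored as two CSV files: a *baseline* table with one row per
patient (demographics, comorbidity flags, labs, follow-up, outcome) and a
long-format *INR* table (patient_id, day, inr).  Dates are integer day
offsets from each patient's entry (day 0); one year is 365.25 days
everywhere in this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

BLEED_SITES = ("intracranial", "gastrointestinal", "other_critical", "other")
SEXES = ("male", "female")

#: fixed column order of the baseline CSV
BASELINE_COLUMNS = [
    "patient_id", "sex", "age",
    "hypertension", "uncontrolled_hypertension", "diabetes", "heart_failure",
    "prior_stroke_tia", "hepatic_impairment", "renal_impairment",
    "severe_renal_disease", "egfr_lt60", "hemoglobin", "anemia",
    "coronary_artery_disease", "smoking", "alcohol_excess",
    "antiplatelet_or_nsaid", "malignancy", "prior_major_bleed",
    "rebleed_history", "platelet_defect", "genetic_cyp2c9", "fall_risk",
    "followup_years", "bled",
    "bleed_day", "bleed_site", "bleed_fatal", "hb_drop", "units_transfused",
]

#: fixed column order of the INR CSV
INR_COLUMNS = ["patient_id", "day", "inr"]

_FLAG_FIELDS = [
    "hypertension", "uncontrolled_hypertension", "diabetes", "heart_failure",
    "prior_stroke_tia", "hepatic_impairment", "renal_impairment",
    "severe_renal_disease", "egfr_lt60",
    "coronary_artery_disease", "smoking", "alcohol_excess",
    "antiplatelet_or_nsaid", "malignancy", "prior_major_bleed",
    "rebleed_history", "platelet_defect", "genetic_cyp2c9", "fall_risk",
]


class CohortError(ValueError):
    """Base class for cohort validation failures."""


class SchemaError(CohortError):
    """A required column is missing or the header does not match."""


class RowError(CohortError):
    """A row failed parsing or an invariant; carries row context."""

    def __init__(self, message: str, row: Optional[int] = None,
                 patient_id: Optional[str] = None):
        ctx = []
        if row is not None:
            ctx.append(f"row {row}")
        if patient_id is not None:
            ctx.append(f"patient {patient_id!r}")
        prefix = " / ".join(ctx)
        super().__init__(f"{prefix}: {message}" if prefix else message)
        self.row = row
        self.patient_id = patient_id


class ReferentialError(CohortError):
    """Cross-table reference broken (unknown or duplicate patient id)."""


class AnemiaUnresolvableError(CohortError):
    """Neither an explicit anemia flag nor a hemoglobin value is available."""


def derive_anemia(sex: str, hemoglobin: float) -> bool:
    """Anemia flag from hemoglobin (g/dL): <13.0 for men, <12.0 for women.

    Strict inequalities; a hemoglobin exactly at the cut-off is not anemic.
    """
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}")
    if hemoglobin is None or hemoglobin <= 0:
        raise ValueError("hemoglobin must be a positive value")
    return hemoglobin < (13.0 if sex == "male" else 12.0)


@dataclass(frozen=True)
class BleedEvent:
    day: int
    site: str = "other"
    fatal: bool = False
    hb_drop: float = 0.0
    units_transfused: int = 0

    def __post_init__(self):
        if self.day < 0:
            raise CohortError(f"bleed day must be >= 0, got {self.day}")
        if self.site not in BLEED_SITES:
            raise CohortError(f"unknown bleed site {self.site!r}")
        if self.hb_drop < 0:
            raise CohortError("hb_drop must be >= 0")
        if self.units_transfused < 0:
            raise CohortError("units_transfused must be >= 0")


@dataclass
class PatientRecord:
    patient_id: str
    sex: str
    age: int
    hypertension: bool = False
    uncontrolled_hypertension: bool = False
    diabetes: bool = False
    heart_failure: bool = False
    prior_stroke_tia: bool = False
    hepatic_impairment: bool = False
    renal_impairment: bool = False
    severe_renal_disease: bool = False
    egfr_lt60: bool = False
    hemoglobin: Optional[float] = None
    anemia: Optional[bool] = None
    coronary_artery_disease: bool = False
    smoking: bool = False
    alcohol_excess: bool = False
    antiplatelet_or_nsaid: bool = False
    malignancy: bool = False
    prior_major_bleed: bool = False
    rebleed_history: bool = False
    platelet_defect: bool = False
    genetic_cyp2c9: bool = False
    fall_risk: bool = False
    followup_years: float = 1.0
    bled: bool = False
    bleed_event: Optional[BleedEvent] = None

    def validate(self) -> None:
        if self.sex not in SEXES:
            raise RowError(f"sex must be one of {SEXES}, got {self.sex!r}",
                           patient_id=self.patient_id)
        if self.age < 18:
            raise RowError(f"age must be >= 18, got {self.age}",
                           patient_id=self.patient_id)
        if self.followup_years <= 0:
            raise RowError("followup_years must be > 0",
                           patient_id=self.patient_id)
        if self.severe_renal_disease and not self.renal_impairment:
            raise RowError("severe_renal_disease requires renal_impairment",
                           patient_id=self.patient_id)
        if self.rebleed_history and not self.prior_major_bleed:
            raise RowError("rebleed_history requires prior_major_bleed",
                           patient_id=self.patient_id)
        if self.hemoglobin is not None and self.hemoglobin <= 0:
            raise RowError("hemoglobin must be positive",
                           patient_id=self.patient_id)
        if self.bled != (self.bleed_event is not None):
            raise RowError("bled flag and bleed_event presence must agree",
                           patient_id=self.patient_id)
        if self.bleed_event is not None:
            if self.bleed_event.day > self.followup_years * DAYS_PER_YEAR:
                raise RowError(
                    f"bleed day {self.bleed_event.day} exceeds follow-up "
                    f"({self.followup_years:.3f} y)",
                    patient_id=self.patient_id)

    def resolve_anemia(self) -> bool:
        """Resolve the anemia flag, preferring an explicit adjudicated flag.

        If both an explicit flag and a hemoglobin value are present and
        disagree, the explicit flag wins and a warning is logged.
        """
        derived = (derive_anemia(self.sex, self.hemoglobin)
                   if self.hemoglobin is not None else None)
        if self.anemia is not None:
            if derived is not None and derived != self.anemia:
                logger.warning(
                    "patient %s: explicit anemia flag %s disagrees with "
                    "hemoglobin %.2f g/dL; keeping explicit flag",
                    self.patient_id, self.anemia, self.hemoglobin)
            return self.anemia
        if derived is None:
            raise AnemiaUnresolvableError(
                f"patient {self.patient_id!r}: anemia flag missing and no "
                "hemoglobin available")
        return derived


@dataclass(frozen=True)
class INRObservation:
    patient_id: str
    day: int
    inr: float

    def __post_init__(self):
        if self.day < 0:
            raise RowError(f"day must be >= 0, got {self.day}",
                           patient_id=self.patient_id)
        if not (0.5 < self.inr < 20):
            raise RowError(f"inr must be in (0.5, 20), got {self.inr}",
                           patient_id=self.patient_id)


@dataclass
class Cohort:
    patients: list[PatientRecord] = field(default_factory=list)
    inr_series: dict[str, list[INRObservation]] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for p in self.patients:
            if p.patient_id in seen:
                raise ReferentialError(
                    f"duplicate patient_id {p.patient_id!r}")
            seen.add(p.patient_id)
            p.validate()
        for pid, obs in self.inr_series.items():
            if pid not in seen:
                raise ReferentialError(
                    f"INR series for unknown patient {pid!r}")
            last = -1
            for o in obs:
                if o.patient_id != pid:
                    raise ReferentialError(
                        f"INR observation for {o.patient_id!r} filed under "
                        f"{pid!r}")
                if o.day <= last:
                    raise RowError(
                        f"INR days must be strictly increasing "
                        f"(day {o.day} after day {last})", patient_id=pid)
                last = o.day

    def __len__(self) -> int:
        return len(self.patients)

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


# ---------------------------------------------------------------------------
# CSV serialization

def _parse_flag(value: str, column: str, row: int) -> bool:
    if value in ("0", "1"):
        return value == "1"
    raise RowError(f"column {column!r} must be 0 or 1, got {value!r}",
                   row=row)


def _cell(df_value) -> str:
    return "" if pd.isna(df_value) else str(df_value).strip()


def read_cohort(baseline_path, inr_path) -> Cohort:
    """Read baseline + INR CSVs into a validated :class:`Cohort`.

    Raises :class:`SchemaError` for missing columns, :class:`RowError` with
    the 1-based data row number for unparseable values, and
    :class:`ReferentialError` for broken cross references.
    """
    base = pd.read_csv(baseline_path, dtype=str, keep_default_na=False)
    missing = [c for c in BASELINE_COLUMNS if c not in base.columns]
    if missing:
        raise SchemaError(f"baseline file missing columns: {missing}")
    inr = pd.read_csv(inr_path, dtype=str, keep_default_na=False)
    missing = [c for c in INR_COLUMNS if c not in inr.columns]
    if missing:
        raise SchemaError(f"INR file missing columns: {missing}")

    patients: list[PatientRecord] = []
    ids: set[str] = set()
    for i, row in enumerate(base.itertuples(index=False), start=1):
        rec = row._asdict()
        pid = _cell(rec["patient_id"])
        if not pid:
            raise RowError("empty patient_id", row=i)
        if pid in ids:
            raise ReferentialError(
                f"duplicate patient_id {pid!r} at baseline row {i}")
        ids.add(pid)
        try:
            flags = {f: _parse_flag(_cell(rec[f]), f, i) for f in _FLAG_FIELDS}
            hb = _cell(rec["hemoglobin"])
            an = _cell(rec["anemia"])
            bled = _parse_flag(_cell(rec["bled"]), "bled", i)
            event = None
            if bled:
                event = BleedEvent(
                    day=int(_cell(rec["bleed_day"])),
                    site=_cell(rec["bleed_site"]) or "other",
                    fatal=_parse_flag(_cell(rec["bleed_fatal"]) or "0",
                                      "bleed_fatal", i),
                    hb_drop=float(_cell(rec["hb_drop"]) or 0.0),
                    units_transfused=int(_cell(rec["units_transfused"]) or 0),
                )
            patient = PatientRecord(
                patient_id=pid,
                sex=_cell(rec["sex"]),
                age=int(_cell(rec["age"])),
                hemoglobin=float(hb) if hb else None,
                anemia=_parse_flag(an, "anemia", i) if an else None,
                followup_years=float(_cell(rec["followup_years"])),
                bled=bled,
                bleed_event=event,
                **flags,
            )
            patient.validate()
        except RowError as exc:
            if exc.row is None:
                raise RowError(str(exc), row=i) from exc
            raise
        except (ValueError, CohortError) as exc:
            raise RowError(f"unparseable baseline row: {exc}", row=i,
                           patient_id=pid) from exc
        patients.append(patient)

    series: dict[str, list[INRObservation]] = {}
    for i, row in enumerate(inr.itertuples(index=False), start=1):
        rec = row._asdict()
        pid = _cell(rec["patient_id"])
        if pid not in ids:
            raise ReferentialError(
                f"INR row {i} references unknown patient {pid!r}")
        try:
            obs = INRObservation(patient_id=pid, day=int(_cell(rec["day"])),
                                 inr=float(_cell(rec["inr"])))
        except (ValueError, CohortError) as exc:
            raise RowError(f"unparseable INR row: {exc}", row=i,
                           patient_id=pid) from exc
        series.setdefault(pid, []).append(obs)

    return Cohort(patients=patients, inr_series=series)


def write_cohort(cohort: Cohort, baseline_path, inr_path) -> None:
    """Write a cohort to the two-CSV format with fixed column order.

    Optional values (hemoglobin, anemia, bleed fields for non-bleeders) are
    written as empty cells and round-trip to missing.
    """
    def flag(v) -> str:
        return "1" if v else "0"

    rows = []
    for p in cohort.patients:
        row = {
            "patient_id": p.patient_id, "sex": p.sex, "age": p.age,
            "hemoglobin": "" if p.hemoglobin is None else repr(p.hemoglobin),
            "anemia": "" if p.anemia is None else flag(p.anemia),
            "followup_years": repr(p.followup_years),
            "bled": flag(p.bled),
            "bleed_day": "", "bleed_site": "", "bleed_fatal": "",
            "hb_drop": "", "units_transfused": "",
        }
        for f in _FLAG_FIELDS:
            row[f] = flag(getattr(p, f))
        if p.bleed_event is not None:
            ev = p.bleed_event
            row.update(bleed_day=ev.day, bleed_site=ev.site,
                       bleed_fatal=flag(ev.fatal), hb_drop=repr(ev.hb_drop),
                       units_transfused=ev.units_transfused)
        rows.append(row)
    pd.DataFrame(rows, columns=BASELINE_COLUMNS).to_csv(
        baseline_path, index=False)

    inr_rows = [
        {"patient_id": o.patient_id, "day": o.day, "inr": repr(o.inr)}
        for p in cohort.patients
        for o in cohort.inr_series.get(p.patient_id, [])
    ]
    pd.DataFrame(inr_rows, columns=INR_COLUMNS).to_csv(inr_path, index=False)
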