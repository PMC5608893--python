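"""Additive clinical bleeding-risk scores and ISTH major-bleed classification.

Implements HAS-BLED, ATRIA, ORBIT, HEMORR2HAGES (plus CHA2DS2-VASc for
descriptive output), the "+ labile INR" modified variants that add one point
when TTR < 65%, and the binary risk-category mapping used in the analysis
tables.  Every awarded point is recorded in a per-criterion breakdown so
that scores are fully auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .model import BleedEvent, PatientRecord

LOW = "low"
HIGH = "high_or_medium_high"

#: minimum points for the high / medium-high category, per base score
CATEGORY_THRESHOLDS: Mapping[str, int] = {
    "HASBLED": 3,
    "ATRIA": 4,
    "ORBIT": 3,
    "HEMORR2HAGES": 2,
}

MAX_POINTS: Mapping[str, int] = {
    "HASBLED": 9,
    "ATRIA": 10,
    "ORBIT": 7,
    "HEMORR2HAGES": 12,
    "CHA2DS2VASC": 9,
}

SCORE_NAMES = ("HASBLED", "ATRIA", "ORBIT", "HEMORR2HAGES")
MODIFIED_SCORE_NAMES = ("ATRIA_TTR", "ORBIT_TTR", "HEMORR2HAGES_TTR")


class MissingCriterionError(ValueError):
    """A score criterion could not be evaluated for a patient."""


@dataclass(frozen=True)
class ScoreResult:
    score_name: str
    points: int
    category: str
    component_breakdown: Mapping[str, int]

    def __post_init__(self):
        if self.points != sum(self.component_breakdown.values()):
            raise ValueError("points must equal the sum of the breakdown")


def _categorize(base_name: str, points: int) -> str:
    return HIGH if points >= CATEGORY_THRESHOLDS[base_name] else LOW


def _result(name: str, base_name: str, breakdown: dict[str, int]) -> ScoreResult:
    points = sum(breakdown.values())
    return ScoreResult(score_name=name, points=points,
                       category=_categorize(base_name, points),
                       component_breakdown=breakdown)


def compute_hasbled(patient: PatientRecord, labile_inr: bool) -> ScoreResult:
    """HAS-BLED: nine one-point criteria; high risk at >= 3 points.

    ``labile_inr`` is computed upstream from the Rosendaal TTR (TTR < 65%
    by default) and passed in, since the score itself does not own the INR
    history.  The elderly criterion is age > 65.
    """
    if labile_inr is None:
        raise MissingCriterionError("labile_inr flag is required for HAS-BLED")
    breakdown = {
        "uncontrolled_hypertension": int(patient.uncontrolled_hypertension),
        "abnormal_renal_function": int(patient.renal_impairment),
        "abnormal_liver_function": int(patient.hepatic_impairment),
        "stroke": int(patient.prior_stroke_tia),
        "bleeding_history": int(patient.prior_major_bleed),
        "labile_inr": int(labile_inr),
        "elderly_gt65": int(patient.age > 65),
        "antiplatelet_or_nsaid": int(patient.antiplatelet_or_nsaid),
        "alcohol_excess": int(patient.alcohol_excess),
    }
    return _result("HASBLED", "HASBLED", breakdown)


def compute_atria(patient: PatientRecord) -> ScoreResult:
    """ATRIA: anemia 3, severe renal disease 3, age >= 75 -> 2, prior
    bleeding 1, hypertension 1; medium/high risk at >= 4 points."""
    breakdown = {
        "anemia": 3 * int(patient.resolve_anemia()),
        "severe_renal_disease": 3 * int(patient.severe_renal_disease),
        "age_ge75": 2 * int(patient.age >= 75),
        "prior_bleeding": int(patient.prior_major_bleed),
        "hypertension": int(patient.hypertension),
    }
    return _result("ATRIA", "ATRIA", breakdown)


def compute_orbit(patient: PatientRecord) -> ScoreResult:
    """ORBIT: age >= 75 -> 1, anemia 2, bleeding history 2, eGFR < 60 -> 1,
    antiplatelet treatment 1; medium/high risk at >= 3 points."""
    breakdown = {
        "age_ge75": int(patient.age >= 75),
        "anemia": 2 * int(patient.resolve_anemia()),
        "bleeding_history": 2 * int(patient.prior_major_bleed),
        "egfr_lt60": int(patient.egfr_lt60),
        "antiplatelet": int(patient.antiplatelet_or_nsaid),
    }
    return _result("ORBIT", "ORBIT", breakdown)


def compute_hemorr2hages(patient: PatientRecord) -> ScoreResult:
    """HEMORR2HAGES: one point per criterion, two for rebleeding history;
    medium/high risk at >= 2 points."""
    breakdown = {
        "hepatic_or_renal_disease": int(patient.hepatic_impairment
                                        or patient.renal_impairment),
        "ethanol_abuse": int(patient.alcohol_excess),
        "malignancy": int(patient.malignancy),
        "age_gt75": int(patient.age > 75),
        "reduced_platelets": int(patient.platelet_defect),
        "rebleeding": 2 * int(patient.rebleed_history),
        "uncontrolled_hypertension": int(patient.uncontrolled_hypertension),
        "anemia": int(patient.resolve_anemia()),
        "genetic_cyp2c9": int(patient.genetic_cyp2c9),
        "fall_risk": int(patient.fall_risk),
        "stroke": int(patient.prior_stroke_tia),
    }
    return _result("HEMORR2HAGES", "HEMORR2HAGES", breakdown)


_BASE_SCORERS = {
    "HASBLED": compute_hasbled,
    "ATRIA": compute_atria,
    "ORBIT": compute_orbit,
    "HEMORR2HAGES": compute_hemorr2hages,
}


def compute_modified_score(base: str, patient: PatientRecord,
                           labile_inr: bool) -> ScoreResult:
    """TTR-modified variant: base score plus one point when labile INR
    (TTR < 65%); the category threshold is unchanged from the base score."""
    if base not in ("ATRIA", "ORBIT", "HEMORR2HAGES"):
        raise ValueError(f"no TTR-modified variant of {base!r}")
    base_result = _BASE_SCORERS[base](patient)
    breakdown = dict(base_result.component_breakdown)
    breakdown["labile_inr"] = int(labile_inr)
    return _result(f"{base}_TTR", base, breakdown)


def compute_cha2ds2vasc(patient: PatientRecord) -> ScoreResult:
    """CHA2DS2-VASc stroke-risk score (descriptive output only).

    Vascular disease maps to coronary artery disease, the only vascular
    covariate carried in the baseline table.
    """
    breakdown = {
        "heart_failure": int(patient.heart_failure),
        "hypertension": int(patient.hypertension),
        "age_ge75": 2 * int(patient.age >= 75),
        "diabetes": int(patient.diabetes),
        "stroke_tia": 2 * int(patient.prior_stroke_tia),
        "vascular_disease": int(patient.coronary_artery_disease),
        "age_65_74": int(65 <= patient.age <= 74),
        "female": int(patient.sex == "female"),
    }
    points = sum(breakdown.values())
    return ScoreResult(score_name="CHA2DS2VASC", points=points,
                       category=LOW if points < 2 else HIGH,
                       component_breakdown=breakdown)


def compute_score(name: str, patient: PatientRecord,
                  labile_inr: bool | None = None) -> ScoreResult:
    """Dispatch on score name (original, ``*_TTR`` modified, or
    CHA2DS2VASC)."""
    if name == "HASBLED":
        return compute_hasbled(patient, labile_inr)
    if name in _BASE_SCORERS:
        return _BASE_SCORERS[name](patient)
    if name == "CHA2DS2VASC":
        return compute_cha2ds2vasc(patient)
    if name.endswith("_TTR"):
        return compute_modified_score(name[:-4], patient, labile_inr)
    raise ValueError(f"unknown score {name!r}")


def classify_isth_major(event: BleedEvent) -> bool:
    """ISTH 2005 major bleeding: fatal, critical-site, hemoglobin fall of
    2 g/dL or more, or transfusion of two or more units."""
    return (event.fatal
            or event.site in ("intracranial", "other_critical")
            or event.hb_drop >= 2.0
            or event.units_transfused >= 2)
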