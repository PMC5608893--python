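"""Synthetic cohort generator.

Generates cohorts with the statistical structure the analysis pipeline
assumes: realistic covariate prevalences, per-patient INR trajectories over
the first six months whose between-patient spread is auto-tuned so that a
target fraction of patients has TTR < 65%, and exponential time-to-major-
bleed with a log-linear hazard in the covariates and the realized labile
flag.  A fixed seed yields a bitwise-identical cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .model import (BleedEvent, Cohort, INRObservation, PatientRecord,
                    DAYS_PER_YEAR)
from .ttr import segment_fractions

N_STUDY = 1361

#: marginal covariate prevalences (counts over N=1361)
DEFAULT_PREVALENCES: Mapping[str, float] = {
    "female": 698 / N_STUDY,
    "hypertension": 1116 / N_STUDY,
    "diabetes": 363 / N_STUDY,
    "heart_failure": 429 / N_STUDY,
    "prior_stroke_tia": 257 / N_STUDY,
    "hepatic_impairment": 18 / N_STUDY,
    "renal_impairment": 144 / N_STUDY,
    "anemia": 254 / N_STUDY,
    "coronary_artery_disease": 255 / N_STUDY,
    "smoking": 210 / N_STUDY,
    "alcohol_excess": 50 / N_STUDY,
    "antiplatelet_or_nsaid": 243 / N_STUDY,
    "malignancy": 105 / N_STUDY,
    # registry-style flags without a published margin (see docs)
    "prior_major_bleed": 0.10,
    "platelet_defect": 0.02,
    "genetic_cyp2c9": 0.05,
    "fall_risk": 0.15,
    # conditional prevalences for nested flags
    "uncontrolled_hypertension_given_hypertension": 0.30,
    "severe_renal_given_renal": 0.30,
    "rebleed_given_prior_bleed": 0.25,
    "egfr_lt60_extra": 0.15,
}

DEFAULT_LOG_HAZARD_EFFECTS: Mapping[str, float] = {
    "labile_inr": math.log(1.5),
    "prior_major_bleed": math.log(1.5),
    "anemia": math.log(1.4),
    "renal_impairment": math.log(1.3),
    "antiplatelet_or_nsaid": math.log(1.3),
    "alcohol_excess": math.log(1.3),
    "uncontrolled_hypertension": math.log(1.25),
    "prior_stroke_tia": math.log(1.2),
}

#: site mix among major bleeds (intracranial 78/250, GI 97/250)
DEFAULT_SITE_PROBS: Mapping[str, float] = {
    "intracranial": 78 / 250,
    "gastrointestinal": 97 / 250,
    "other_critical": 0.06,
    "other": 1 - 78 / 250 - 97 / 250 - 0.06,
}


class TuningError(RuntimeError):
    """The target labile fraction could not be reached by tuning."""


@dataclass
class SyntheticCohortConfig:
    n_patients: int = N_STUDY
    seed: int = 0
    covariate_prevalences: dict = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    age_median: float = 76.0
    age_sd: float = 7.4          # matches IQR 71-81 under normality
    inr_visit_interval_days: float = 28.0
    inr_visit_interval_sd: float = 5.0
    inr_target_mean: float = 2.5
    inr_sd_between: Optional[float] = None   # None -> auto-tuned
    inr_sd_within: float = 0.35
    target_labile_fraction: float = 0.242
    labile_tolerance: float = 0.02
    labile_threshold_pct: float = 65.0
    ttr_window_days: float = 183.0
    range_low: float = 2.0
    range_high: float = 3.0
    baseline_hazard: Optional[float] = None  # None -> calibrated to target
    target_event_rate_per_year: float = 0.0282
    log_hazard_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_LOG_HAZARD_EFFECTS))
    followup_median_years: float = 6.5
    followup_log_sd: float = 0.45            # lognormal; IQR approx 4.3-7.9
    site_probs: dict = field(default_factory=lambda: dict(DEFAULT_SITE_PROBS))
    fatal_prob: float = 52 / 250
    copula_rho: float = 0.2                  # age<->renal, age<->anemia

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for k, v in self.covariate_prevalences.items():
            if not 0 <= v <= 1:
                raise ValueError(f"prevalence {k!r} outside [0,1]")
        if not 0 <= self.target_labile_fraction <= 1:
            raise ValueError("target_labile_fraction outside [0,1]")
        if self.baseline_hazard is not None and self.baseline_hazard < 0:
            raise ValueError("baseline_hazard must be >= 0")
        if abs(sum(self.site_probs.values()) - 1) > 1e-9:
            raise ValueError("site_probs must sum to 1")


def _visit_days(rng: np.random.Generator, cfg: SyntheticCohortConfig,
                n: int) -> list[np.ndarray]:
    """Per-patient INR visit days: day 0, then roughly 4-weekly gaps."""
    max_visits = int(cfg.ttr_window_days / 7) + 2
    gaps = np.clip(np.rint(rng.normal(cfg.inr_visit_interval_days,
                                      cfg.inr_visit_interval_sd,
                                      size=(n, max_visits))),
                   7, 56).astype(int)
    days = np.concatenate([np.zeros((n, 1), dtype=int),
                           np.cumsum(gaps, axis=1)], axis=1)
    return [row[row <= cfg.ttr_window_days] for row in days]


def _cohort_ttr_pct(days: list[np.ndarray], inr: list[np.ndarray],
                    cfg: SyntheticCohortConfig) -> np.ndarray:
    """Vectorized Rosendaal TTR for a whole cohort (visits already inside
    the window and gap-capped by construction)."""
    seg_pid, t0, t1, i0, i1 = [], [], [], [], []
    for p, (d, v) in enumerate(zip(days, inr)):
        if d.size < 2:
            continue
        seg_pid.append(np.full(d.size - 1, p))
        t0.append(d[:-1])
        t1.append(d[1:])
        i0.append(v[:-1])
        i1.append(v[1:])
    seg_pid = np.concatenate(seg_pid)
    dur = (np.concatenate(t1) - np.concatenate(t0)).astype(float)
    _, in_f, _ = segment_fractions(np.concatenate(i0), np.concatenate(i1),
                                   cfg.range_low, cfg.range_high)
    n = len(days)
    in_time = np.zeros(n)
    tot_time = np.zeros(n)
    np.add.at(in_time, seg_pid, in_f * dur)
    np.add.at(tot_time, seg_pid, dur)
    with np.errstate(invalid="ignore"):
        return np.where(tot_time > 0, 100.0 * in_time / tot_time, np.nan)


def _tune_sd_between(days, zb, zw, cfg) -> tuple[float, np.ndarray]:
    """Bisection on the between-patient INR SD so the realized labile
    fraction hits the target within tolerance.  Reuses fixed noise draws,
    so tuning consumes no extra randomness."""

    def realize(sd_b: float) -> list[np.ndarray]:
        return [np.clip(cfg.inr_target_mean + sd_b * zb[i]
                        + cfg.inr_sd_within * zw[i][:d.size], 0.6, 9.0)
                for i, d in enumerate(days)]

    def labile_frac(sd_b: float) -> float:
        ttr = _cohort_ttr_pct(days, realize(sd_b), cfg)
        return float(np.mean(ttr < cfg.labile_threshold_pct))

    # the realized fraction is granular in 1/n, so small cohorts cannot hit
    # a tight tolerance; widen it accordingly
    tolerance = max(cfg.labile_tolerance, 1.0 / len(days))
    lo, hi = 1e-3, 2.0
    if labile_frac(hi) < cfg.target_labile_fraction - tolerance:
        raise TuningError("target labile fraction unattainable: too high")
    best_sd, best_gap = hi, abs(labile_frac(hi) - cfg.target_labile_fraction)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f = labile_frac(mid)
        gap = abs(f - cfg.target_labile_fraction)
        if gap < best_gap:
            best_sd, best_gap = mid, gap
        if f < cfg.target_labile_fraction:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    if best_gap > tolerance:
        raise TuningError(
            f"labile fraction off target by {best_gap:.3f} after tuning")
    return best_sd, np.asarray(realize(best_sd), dtype=object)


def _calibrate_baseline_hazard(rel: np.ndarray, censor: np.ndarray,
                               target_rate: float) -> float:
    """Baseline hazard such that the *expected* events-per-person-year
    (events shorten exposure) equals the target.  Deterministic bisection
    on the closed-form exponential expectations."""
    if target_rate == 0:
        return 0.0

    def expected_rate(h0: float) -> float:
        lam = h0 * rel
        p_event = 1.0 - np.exp(-lam * censor)
        person_time = p_event / lam  # E[min(T, C)] for exponential T
        return float(p_event.sum() / person_time.sum())

    lo, hi = 1e-8, 10.0
    for _ in range(80):
        mid = math.sqrt(lo * hi)
        if expected_rate(mid) < target_rate:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def generate_cohort(config: SyntheticCohortConfig) -> Cohort:
    """Generate a validated synthetic :class:`Cohort` from ``config``."""
    config.validate()
    cfg = config
    n = cfg.n_patients
    rng = np.random.default_rng(cfg.seed)
    prev = cfg.covariate_prevalences

    # --- correlated latents: age, renal impairment, anemia (hemoglobin)
    e = rng.standard_normal((n, 3))
    rho = cfg.copula_rho
    z_age = e[:, 0]
    z_renal = rho * e[:, 0] + math.sqrt(1 - rho ** 2) * e[:, 1]
    z_anem = rho * e[:, 0] + math.sqrt(1 - rho ** 2) * e[:, 2]

    age = np.clip(np.rint(cfg.age_median + cfg.age_sd * z_age),
                  18, 102).astype(int)
    from scipy.stats import norm
    renal = norm.cdf(z_renal) < prev["renal_impairment"]

    female = rng.random(n) < prev["female"]
    # sex-specific hemoglobin tuned so derived anemia matches its margin
    hb = np.where(female, 13.15 - 1.30 * z_anem, 14.30 - 1.45 * z_anem)
    hb = np.clip(np.round(hb, 1), 5.0, 20.0)

    draw = {k: rng.random(n) < prev[k] for k in
            ("hypertension", "diabetes", "heart_failure", "prior_stroke_tia",
             "hepatic_impairment", "coronary_artery_disease", "smoking",
             "alcohol_excess", "antiplatelet_or_nsaid", "malignancy",
             "prior_major_bleed", "platelet_defect", "genetic_cyp2c9",
             "fall_risk")}
    uncontrolled = draw["hypertension"] & (
        rng.random(n) < prev["uncontrolled_hypertension_given_hypertension"])
    severe_renal = renal & (rng.random(n) < prev["severe_renal_given_renal"])
    rebleed = draw["prior_major_bleed"] & (
        rng.random(n) < prev["rebleed_given_prior_bleed"])
    egfr_lt60 = renal | (rng.random(n) < prev["egfr_lt60_extra"])

    # --- INR trajectories and labile flags
    days = _visit_days(rng, cfg, n)
    zb = rng.standard_normal(n)
    zw = [rng.standard_normal(d.size) for d in days]
    if cfg.inr_sd_between is None:
        sd_b, inr_values = _tune_sd_between(days, zb, zw, cfg)
    else:
        sd_b = cfg.inr_sd_between
        inr_values = np.asarray(
            [np.clip(cfg.inr_target_mean + sd_b * zb[i]
                     + cfg.inr_sd_within * zw[i], 0.6, 9.0)
             for i in range(n)], dtype=object)
    ttr_pct = _cohort_ttr_pct(days, list(inr_values), cfg)
    labile = ttr_pct < cfg.labile_threshold_pct

    # --- hazard and outcomes
    anemia = np.where(female, hb < 12.0, hb < 13.0)
    covariates = {
        "labile_inr": labile, "prior_major_bleed": draw["prior_major_bleed"],
        "anemia": anemia, "renal_impairment": renal,
        "severe_renal_disease": severe_renal,
        "antiplatelet_or_nsaid": draw["antiplatelet_or_nsaid"],
        "alcohol_excess": draw["alcohol_excess"],
        "uncontrolled_hypertension": uncontrolled,
        "prior_stroke_tia": draw["prior_stroke_tia"],
        "hypertension": draw["hypertension"],
        "diabetes": draw["diabetes"],
        "heart_failure": draw["heart_failure"],
        "hepatic_impairment": draw["hepatic_impairment"],
        "egfr_lt60": egfr_lt60, "malignancy": draw["malignancy"],
        "age_per_decade": (age - cfg.age_median) / 10.0,
    }
    xbeta = np.zeros(n)
    for name, beta in cfg.log_hazard_effects.items():
        if name not in covariates:
            raise ValueError(f"unknown hazard covariate {name!r}")
        xbeta += beta * np.asarray(covariates[name], dtype=float)
    rel = np.exp(xbeta)

    censor = rng.lognormal(math.log(cfg.followup_median_years),
                           cfg.followup_log_sd, size=n)
    censor = np.maximum(censor, 0.6)  # everyone completes the TTR window
    if cfg.baseline_hazard is not None:
        h0 = cfg.baseline_hazard
    else:
        h0 = _calibrate_baseline_hazard(rel, censor,
                                        cfg.target_event_rate_per_year)
    lam = h0 * rel
    with np.errstate(divide="ignore"):
        t_event = np.where(lam > 0, rng.exponential(1.0, size=n) / np.maximum(lam, 1e-300),
                           np.inf)
    bled = t_event <= censor
    followup = np.where(bled, t_event, censor)

    fatal = rng.random(n) < cfg.fatal_prob
    sites = list(cfg.site_probs)
    site_idx = rng.choice(len(sites), size=n,
                          p=[cfg.site_probs[s] for s in sites])
    hb_drop = np.round(2.0 + np.abs(rng.normal(0.0, 1.2, size=n)), 1)
    units = rng.poisson(2.0, size=n)

    width = max(4, len(str(n)))
    patients = []
    inr_series: dict[str, list[INRObservation]] = {}
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        event = None
        if bled[i]:
            event = BleedEvent(
                day=int(math.floor(t_event[i] * DAYS_PER_YEAR)),
                site=sites[site_idx[i]], fatal=bool(fatal[i]),
                hb_drop=float(hb_drop[i]), units_transfused=int(units[i]))
        patients.append(PatientRecord(
            patient_id=pid, sex="female" if female[i] else "male",
            age=int(age[i]),
            hypertension=bool(draw["hypertension"][i]),
            uncontrolled_hypertension=bool(uncontrolled[i]),
            diabetes=bool(draw["diabetes"][i]),
            heart_failure=bool(draw["heart_failure"][i]),
            prior_stroke_tia=bool(draw["prior_stroke_tia"][i]),
            hepatic_impairment=bool(draw["hepatic_impairment"][i]),
            renal_impairment=bool(renal[i]),
            severe_renal_disease=bool(severe_renal[i]),
            egfr_lt60=bool(egfr_lt60[i]),
            hemoglobin=float(hb[i]), anemia=None,
            coronary_artery_disease=bool(draw["coronary_artery_disease"][i]),
            smoking=bool(draw["smoking"][i]),
            alcohol_excess=bool(draw["alcohol_excess"][i]),
            antiplatelet_or_nsaid=bool(draw["antiplatelet_or_nsaid"][i]),
            malignancy=bool(draw["malignancy"][i]),
            prior_major_bleed=bool(draw["prior_major_bleed"][i]),
            rebleed_history=bool(rebleed[i]),
            platelet_defect=bool(draw["platelet_defect"][i]),
            genetic_cyp2c9=bool(draw["genetic_cyp2c9"][i]),
            fall_risk=bool(draw["fall_risk"][i]),
            followup_years=float(followup[i]),
            bled=bool(bled[i]), bleed_event=event))
        inr_series[pid] = [INRObservation(patient_id=pid, day=int(d),
                                          inr=float(v))
                           for d, v in zip(days[i], inr_values[i])]
    return Cohort(patients=patients, inr_series=inr_series)


# ---------------------------------------------------------------------------
# Deterministic worked fixtures used throughout the unit tests


def _simple_patient(pid: str, **kwargs) -> PatientRecord:
    defaults = dict(patient_id=pid, sex="male", age=60, hemoglobin=14.0,
                    followup_years=5.0)
    defaults.update(kwargs)
    return PatientRecord(**defaults)


def _flat_inr(pid: str) -> list[INRObservation]:
    return [INRObservation(patient_id=pid, day=0, inr=2.5),
            INRObservation(patient_id=pid, day=30, inr=2.5)]


def generate_worked_fixtures() -> dict[str, Cohort]:
    """Tiny hand-auditable cohorts with closed-form TTR, Kaplan-Meier and
    concordance values."""
    fixtures: dict[str, Cohort] = {}

    # io3: 3 patients with INR series of lengths 3, 2 and 1
    patients = [_simple_patient(f"A{i}") for i in (1, 2, 3)]
    series = {
        "A1": [INRObservation("A1", 0, 2.2), INRObservation("A1", 28, 2.6),
               INRObservation("A1", 60, 3.1)],
        "A2": [INRObservation("A2", 0, 1.8), INRObservation("A2", 40, 2.4)],
        "A3": [INRObservation("A3", 10, 2.9)],
    }
    fixtures["io3"] = Cohort(patients=patients, inr_series=series)

    # ttr_cross: linear segment 2.0 -> 3.5 over 3 days crosses the upper
    # bound at day 2, so TTR = 2/3
    p = _simple_patient("T1")
    fixtures["ttr_cross"] = Cohort(
        patients=[p],
        inr_series={"T1": [INRObservation("T1", 0, 2.0),
                           INRObservation("T1", 3, 3.5)]})

    # km6: event times 1, 2, 3 years with censoring at 2, 4, 5;
    # product-limit S = 5/6, 2/3, 4/9
    times = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
    events = [True, True, False, True, False, False]
    patients = []
    for i, (t, ev) in enumerate(zip(times, events)):
        event = (BleedEvent(day=int(t * DAYS_PER_YEAR) - 1, site="other",
                            hb_drop=2.5) if ev else None)
        patients.append(_simple_patient(f"K{i + 1}", followup_years=t,
                                        bled=ev, bleed_event=event))
    fixtures["km6"] = Cohort(
        patients=patients,
        inr_series={p.patient_id: _flat_inr(p.patient_id) for p in patients})

    # sep8: the four bleeders carry HAS-BLED points, the four non-bleeders
    # none -> c-index 1.0 on HAS-BLED points
    patients = []
    for i in range(4):
        event = BleedEvent(day=100 + i, site="gastrointestinal", hb_drop=3.0)
        patients.append(_simple_patient(
            f"S{i + 1}", prior_major_bleed=True, antiplatelet_or_nsaid=True,
            bled=True, bleed_event=event))
    for i in range(4, 8):
        patients.append(_simple_patient(f"S{i + 1}"))
    fixtures["sep8"] = Cohort(
        patients=patients,
        inr_series={p.patient_id: _flat_inr(p.patient_id) for p in patients})

    return fixtures
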