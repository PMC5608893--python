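"""End-to-end analysis pipeline.

Stages: cohort (simulate or ingest) -> TTR/labile flags -> scores ->
rate/contingency tables -> survival -> discrimination/reclassification/
calibration -> decision curves.  Every stage is a pure function of
(inputs, config, seed); outputs are written as TSV/JSON at full precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import contingency, decision_curve, discrimination, scores, survival, ttr
from .model import Cohort, read_cohort, write_cohort
from .synthetic import SyntheticCohortConfig, generate_cohort

logger = logging.getLogger(__name__)

DEFAULT_PAIRINGS = [
    ("ATRIA", "ATRIA_TTR"),
    ("ORBIT", "ORBIT_TTR"),
    ("HEMORR2HAGES", "HEMORR2HAGES_TTR"),
    ("ATRIA", "HASBLED"),
    ("ORBIT", "HASBLED"),
    ("HEMORR2HAGES", "HASBLED"),
]

ALL_SCORES = list(scores.SCORE_NAMES) + list(scores.MODIFIED_SCORE_NAMES)


@dataclass
class RunConfig:
    baseline_path: Optional[str] = None
    inr_path: Optional[str] = None
    simulate: Optional[SyntheticCohortConfig] = None
    ttr_threshold_pct: float = 65.0
    score_names: list[str] = field(default_factory=lambda: list(ALL_SCORES))
    pairings: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_PAIRINGS))
    out_dir: str = "bleedrisk_out"
    seed: int = 0

    def validate(self) -> None:
        has_files = self.baseline_path is not None and self.inr_path is not None
        if has_files == (self.simulate is not None):
            raise ValueError("provide either input paths or a simulation "
                             "config, not both")
        for a, b in self.pairings:
            if a not in self.score_names or b not in self.score_names:
                raise ValueError(f"pairing ({a}, {b}) references a score "
                                 "not in score_names")


@dataclass
class EvaluationReport:
    n_patients: int
    rates: dict
    score_frame: pd.DataFrame
    ttr_frame: pd.DataFrame
    table2: pd.DataFrame
    or_table: pd.DataFrame
    km_curves: dict[str, pd.DataFrame]
    logrank: pd.DataFrame
    cox: pd.DataFrame
    c_indexes: dict[str, float]
    comparisons: pd.DataFrame
    calibration: pd.DataFrame
    dca: pd.DataFrame


def stage_seed(seed: int, stage: str) -> int:
    """Stage-derived substream seed: adding a stage never perturbs the
    randomness consumed by earlier stages."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "little")


def _score_frame(cohort: Cohort, labile: dict[str, bool],
                 score_names: list[str]) -> pd.DataFrame:
    rows = []
    for p in cohort.patients:
        row = {"patient_id": p.patient_id, "bled": p.bled,
               "followup_years": p.followup_years,
               "labile_inr": labile[p.patient_id]}
        for name in score_names + ["CHA2DS2VASC"]:
            res = scores.compute_score(name, p,
                                       labile_inr=labile[p.patient_id])
            row[f"{name}_points"] = res.points
            row[f"{name}_category"] = res.category
            row[f"{name}_breakdown"] = "|".join(
                f"{k}={v}" for k, v in res.component_breakdown.items() if v)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> EvaluationReport:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: cohort
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate,
                                  seed=stage_seed(config.seed, "simulate"))
        logger.info("simulating cohort (n=%d)", sim.n_patients)
        cohort = generate_cohort(sim)
        write_cohort(cohort, out / "baseline.csv", out / "inr.csv")
    else:
        cohort = read_cohort(config.baseline_path, config.inr_path)
    n = len(cohort)

    # --- stage: TTR
    ttr_frame = ttr.cohort_ttr_frame(
        cohort, labile_threshold_pct=config.ttr_threshold_pct)
    labile = dict(zip(ttr_frame["patient_id"], ttr_frame["labile"]))

    # --- stage: scores
    frame = _score_frame(cohort, labile, config.score_names)
    outcome = frame["bled"].to_numpy(dtype=bool)

    # --- stage: rates
    def site_filter(site):
        return lambda p: p.bled and p.bleed_event.site == site

    rates = {}
    for label, filt in [
            ("major_bleed", lambda p: p.bled),
            ("intracranial", site_filter("intracranial")),
            ("gastrointestinal", site_filter("gastrointestinal")),
            ("fatal", lambda p: p.bled and p.bleed_event.fatal)]:
        count, crude, annual = contingency.crude_and_annualized_rates(
            cohort, filt)
        rates[label] = {"count": count, "crude_pct": crude,
                        "pct_per_year": annual}
    rates["labile_fraction"] = float(np.mean(list(labile.values())))

    # --- stage: contingency tables
    t2_rows, or_rows = [], []
    for name in config.score_names:
        results = [scores.compute_score(name, p, labile_inr=labile[p.patient_id])
                   for p in cohort.patients]
        dist = contingency.score_distribution_table(cohort, results, outcome)
        dist.insert(0, "score", name)
        t2_rows.append(dist)
        table = contingency.category_two_by_two(results, outcome)
        orr = contingency.odds_ratio(table)
        or_rows.append({"score": name, "a": table.a, "b": table.b,
                        "c": table.c, "d": table.d, "or": orr.or_value,
                        "ci_low": orr.ci_low, "ci_high": orr.ci_high,
                        "p": orr.p_value})
    table2 = pd.concat(t2_rows, ignore_index=True)
    or_table = pd.DataFrame(or_rows)

    # --- stage: survival
    time = frame["followup_years"].to_numpy(dtype=float)
    km_curves, lr_rows, cox_rows = {}, [], []
    for name in config.score_names:
        cat = frame[f"{name}_category"].to_numpy()
        pts = frame[f"{name}_points"].to_numpy(dtype=float)
        groups = []
        for level in (scores.LOW, scores.HIGH):
            mask = cat == level
            if mask.any():
                groups.append((time[mask], outcome[mask]))
                km = survival.kaplan_meier(time[mask], outcome[mask])
                km_curves[f"{name}_{level}"] = pd.DataFrame(
                    {"time": km.times, "at_risk": km.at_risk,
                     "n_events": km.n_events, "survival": km.survival})
        if len(groups) == 2:
            stat, p = survival.log_rank_test(groups)
            lr_rows.append({"score": name, "statistic": stat, "p": p})
        for kind, x in (("continuous", pts),
                        ("categorical", (cat == scores.HIGH).astype(float))):
            if np.ptp(x) == 0:
                continue
            fit = survival.cox_univariate(time, outcome, x)
            cox_rows.append({"score": name, "kind": kind, "hr": fit.hr,
                             "ci_low": fit.ci_low, "ci_high": fit.ci_high,
                             "p": fit.p_value, "converged": fit.converged})
    logrank = pd.DataFrame(lr_rows)
    cox = pd.DataFrame(cox_rows)

    # --- stage: discrimination / reclassification / calibration
    points = {name: frame[f"{name}_points"].to_numpy(dtype=float)
              for name in config.score_names}
    probs = {name: discrimination.score_to_probability(points[name], outcome)
             for name in config.score_names}
    c_indexes = {name: discrimination.c_index(points[name], outcome)
                 for name in config.score_names}
    comp_rows = []
    for old, new in config.pairings:
        roc = discrimination.delong_compare(points[new], points[old], outcome)
        nri_res = discrimination.nri(probs[old], probs[new], outcome)
        idi_res = discrimination.idi(probs[old], probs[new], outcome)
        comp_rows.append({
            "reference": old, "model": new,
            "c_index_model": roc.c_index_a, "c_index_reference": roc.c_index_b,
            "z": roc.z_statistic, "p_delong": roc.p_value,
            "nri": nri_res.nri, "nri_events": nri_res.nri_events,
            "nri_nonevents": nri_res.nri_nonevents, "p_nri": nri_res.p_nri,
            "idi": idi_res.idi, "p_idi": idi_res.p_idi})
    comparisons = pd.DataFrame(comp_rows)

    cal_rows = []
    for name in scores.MODIFIED_SCORE_NAMES:
        if name not in probs:
            continue
        cal = discrimination.hosmer_lemeshow(probs[name], outcome)
        cal_rows.append({"score": name, "hl_statistic": cal.hl_statistic,
                         "df": cal.df, "p": cal.p_value})
    calibration = pd.DataFrame(cal_rows)

    # --- stage: decision curves
    dca = decision_curve.decision_curves(probs, outcome)

    report = EvaluationReport(
        n_patients=n, rates=rates, score_frame=frame, ttr_frame=ttr_frame,
        table2=table2, or_table=or_table, km_curves=km_curves,
        logrank=logrank, cox=cox, c_indexes=c_indexes,
        comparisons=comparisons, calibration=calibration, dca=dca)
    _write_report(report, out)
    return report


def _write_report(report: EvaluationReport, out: Path) -> None:
    report.score_frame.to_csv(out / "scores.tsv", sep="\t", index=False)
    report.ttr_frame.to_csv(out / "ttr.tsv", sep="\t", index=False)
    report.table2.to_csv(out / "table2.tsv", sep="\t", index=False)
    report.or_table.to_csv(out / "odds_ratios.tsv", sep="\t", index=False)
    report.logrank.to_csv(out / "logrank.tsv", sep="\t", index=False)
    report.cox.to_csv(out / "cox.tsv", sep="\t", index=False)
    report.comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False)
    report.calibration.to_csv(out / "calibration.tsv", sep="\t", index=False)
    report.dca.to_csv(out / "dca.tsv", sep="\t", index=False)
    for name, km in report.km_curves.items():
        km.to_csv(out / f"km_{name}.tsv", sep="\t", index=False)
    summary = {"n_patients": report.n_patients, "rates": report.rates,
               "c_indexes": report.c_indexes}
    (out / "report.json").write_text(json.dumps(summary, indent=2,
                                                sort_keys=True))
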