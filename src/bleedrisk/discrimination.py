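"""Discrimination, reclassification and calibration statistics.

Covers the c-index (Mann-Whitney concordance), the DeLong paired comparison
of correlated AUCs, logistic calibration of integer scores to event
probabilities, Pencina's NRI and IDI, and the Hosmer-Lemeshow test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RocComparison:
    c_index_a: float
    c_index_b: float
    z_statistic: float
    p_value: float


@dataclass(frozen=True)
class ReclassificationResult:
    nri: float
    nri_events: float
    nri_nonevents: float
    idi: float
    p_nri: float
    p_idi: float


@dataclass(frozen=True)
class CalibrationResult:
    hl_statistic: float
    df: int
    p_value: float
    bin_table: pd.DataFrame


def _check_outcome(scores, outcome):
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    if scores.shape != outcome.shape:
        raise ValueError("scores and outcome must align")
    if outcome.all() or not outcome.any():
        raise ValueError("both outcome classes must be present")
    return scores, outcome


def c_index(scores, outcome) -> float:
    """P(score_event > score_nonevent) + 0.5 P(equal) over all pairs.

    Computed via the rank-sum identity rather than explicit pair
    enumeration.
    """
    scores, outcome = _check_outcome(scores, outcome)
    n1 = int(outcome.sum())
    n0 = scores.size - n1
    ranks = stats.rankdata(scores)
    u = ranks[outcome].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def _delong_components(scores: np.ndarray, outcome: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the DeLong structural components V10 (events) and V01
    (non-events)."""
    pos = scores[outcome]
    neg = scores[~outcome]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return float(auc), v10, v01


def delong_compare(scores_a, scores_b, outcome) -> RocComparison:
    """DeLong test for the difference of two correlated AUCs on paired
    data (two-sided z test)."""
    scores_a, outcome = _check_outcome(scores_a, outcome)
    scores_b, outcome_b = _check_outcome(scores_b, outcome)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have equal length")
    auc_a, v10_a, v01_a = _delong_components(scores_a, outcome)
    auc_b, v10_b, v01_b = _delong_components(scores_b, outcome)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
           + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n)
    if var <= 0:
        # degenerate covariance: identical AUCs are a null result, different
        # AUCs with zero estimated variance an unbounded signal
        if auc_a == auc_b:
            return RocComparison(c_index_a=auc_a, c_index_b=auc_b,
                                 z_statistic=0.0, p_value=1.0)
        z = np.inf if auc_a > auc_b else -np.inf
        return RocComparison(c_index_a=auc_a, c_index_b=auc_b,
                             z_statistic=float(z), p_value=0.0)
    z = (auc_a - auc_b) / np.sqrt(var)
    return RocComparison(c_index_a=auc_a, c_index_b=auc_b,
                         z_statistic=float(z),
                         p_value=float(2 * stats.norm.sf(abs(z))))


def delong_variance(scores_a, scores_b, outcome) -> float:
    """Variance of the paired AUC difference (exposed for oracle checks)."""
    scores_a, outcome = _check_outcome(scores_a, outcome)
    scores_b, _ = _check_outcome(scores_b, outcome)
    _, v10_a, v01_a = _delong_components(scores_a, outcome)
    _, v10_b, v01_b = _delong_components(scores_b, outcome)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    return float((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / v10_a.size
                 + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / v01_a.size)


def score_to_probability(scores, outcome) -> np.ndarray:
    """Event probabilities from a univariate logistic regression of the
    outcome on score points (maximum likelihood).

    The analysis maps integer scores to probabilities this way before any
    probability-scale statistic (IDI, Hosmer-Lemeshow, decision curves);
    rank statistics (c-index, DeLong) operate on raw points and bypass it.
    """
    scores, outcome = _check_outcome(scores, outcome)
    if np.ptp(scores) == 0:  # intercept-only model
        return np.full(scores.size, outcome.mean())
    design = sm.add_constant(scores)
    try:
        fit = sm.Logit(outcome.astype(float), design).fit(disp=0)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise ValueError(f"logistic calibration failed: {exc}") from exc
    if not np.all(np.isfinite(fit.params)):
        raise ValueError("logistic calibration diverged (separation?)")
    return np.asarray(fit.predict(design), dtype=float)


def nri(prob_old, prob_new, outcome, mode: str = "continuous",
        category_threshold: float | None = None) -> ReclassificationResult:
    """Net reclassification improvement (Pencina).

    ``continuous`` mode counts any probability increase as up-classification;
    ``two_category`` mode counts crossings of ``category_threshold``.
    """
    prob_old, outcome = _check_outcome(prob_old, outcome)
    prob_new, _ = _check_outcome(prob_new, outcome)
    if mode == "continuous":
        up = prob_new > prob_old
        down = prob_new < prob_old
    elif mode == "two_category":
        if category_threshold is None:
            raise ValueError("two_category mode requires a threshold")
        old_high = prob_old >= category_threshold
        new_high = prob_new >= category_threshold
        up = new_high & ~old_high
        down = ~new_high & old_high
    else:
        raise ValueError(f"unknown NRI mode {mode!r}")

    n_e = int(outcome.sum())
    n_ne = int((~outcome).sum())
    p_up_e = up[outcome].mean()
    p_down_e = down[outcome].mean()
    p_up_ne = up[~outcome].mean()
    p_down_ne = down[~outcome].mean()
    nri_events = float(p_up_e - p_down_e)
    nri_nonevents = float(p_down_ne - p_up_ne)
    total = nri_events + nri_nonevents
    var = ((p_up_e + p_down_e - nri_events ** 2) / n_e
           + (p_up_ne + p_down_ne - nri_nonevents ** 2) / n_ne)
    if var <= 0:
        p = 1.0 if total == 0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(total) / np.sqrt(var)))
    return ReclassificationResult(nri=total, nri_events=nri_events,
                                  nri_nonevents=nri_nonevents, idi=np.nan,
                                  p_nri=p, p_idi=np.nan)


def idi(prob_old, prob_new, outcome) -> ReclassificationResult:
    """Integrated discrimination improvement: the change in discrimination
    slope, with Pencina's paired-difference asymptotic test."""
    prob_old, outcome = _check_outcome(prob_old, outcome)
    prob_new, _ = _check_outcome(prob_new, outcome)
    d = prob_new - prob_old
    d_e = d[outcome]
    d_ne = d[~outcome]
    value = float(d_e.mean() - d_ne.mean())
    se = np.sqrt(d_e.var(ddof=1) / d_e.size + d_ne.var(ddof=1) / d_ne.size)
    if se == 0:
        p = 1.0 if value == 0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(value) / se))
    return ReclassificationResult(nri=np.nan, nri_events=np.nan,
                                  nri_nonevents=np.nan, idi=value,
                                  p_nri=np.nan, p_idi=p)


def _hl_bins(prob: np.ndarray, bins: int) -> np.ndarray:
    """Equal-count bin assignment by ranked probability, keeping tied
    probabilities in the same bin so the grouping is deterministic."""
    order = np.argsort(prob, kind="stable")
    n = prob.size
    raw = np.minimum((np.arange(n) * bins) // n, bins - 1)
    bin_of = np.empty(n, dtype=int)
    bin_of[order] = raw
    # ties spanning a bin edge: pull the whole tied block into the lower bin
    sorted_prob = prob[order]
    for i in range(1, n):
        if sorted_prob[i] == sorted_prob[i - 1]:
            bin_of[order[i]] = bin_of[order[i - 1]]
    return bin_of


def hosmer_lemeshow(prob, outcome, bins: int = 10) -> CalibrationResult:
    """Hosmer-Lemeshow chi-squared over probability-ranked bins,
    df = bins - 2.  Bins with zero expected events are merged into their
    lower neighbour (with a warning)."""
    prob, outcome = _check_outcome(prob, outcome)
    assignment = _hl_bins(prob, bins)
    rows = []
    for g in sorted(set(assignment)):
        mask = assignment == g
        n_g = int(mask.sum())
        if n_g == 0:
            continue
        rows.append({"n": n_g, "observed": int(outcome[mask].sum()),
                     "expected": float(prob[mask].sum()),
                     "mean_prob": float(prob[mask].mean())})
    merged = []
    for row in rows:
        if merged and (row["expected"] == 0 or row["expected"] == row["n"]):
            logger.warning("merging degenerate Hosmer-Lemeshow bin")
            prev = merged[-1]
            for k in ("n", "observed", "expected"):
                prev[k] += row[k]
            prev["mean_prob"] = prev["expected"] / prev["n"]
        else:
            merged.append(dict(row))
    table = pd.DataFrame(merged)
    n_g = table["n"].to_numpy(dtype=float)
    o = table["observed"].to_numpy(dtype=float)
    e = table["expected"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (o - e) ** 2 / (e * (1 - e / n_g))
    stat = float(np.nansum(terms))
    df = len(table) - 2
    p = float(stats.chi2.sf(stat, df=df)) if df > 0 else np.nan
    return CalibrationResult(hl_statistic=stat, df=df, p_value=p,
                             bin_table=table)
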