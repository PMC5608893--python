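"""2x2 association statistics and event-rate summaries.

Odds ratios use the cross-product estimate with a Woolf (log-OR normal)
confidence interval and a Pearson chi-squared p-value without continuity
correction; a Haldane-Anscombe 0.5 correction is applied (with a warning)
only when a cell is zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import Cohort, PatientRecord
from .scores import ScoreResult, LOW, HIGH

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TwoByTwo:
    """Counts: a = exposed with event, b = exposed without,
    c = unexposed with event, d = unexposed without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be >= 0")
        if self.total == 0:
            raise ValueError("table must have at least one count")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins_ok(self) -> bool:
        return (self.a + self.b > 0 and self.c + self.d > 0
                and self.a + self.c > 0 and self.b + self.d > 0)


@dataclass(frozen=True)
class ORResult:
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float


def odds_ratio(t: TwoByTwo, alpha: float = 0.05) -> ORResult:
    """Cross-product odds ratio with Woolf CI and chi-squared p-value."""
    if not t.margins_ok():
        raise ValueError("odds ratio undefined: a zero margin")
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0:
        logger.warning("zero cell in 2x2 table; applying Haldane-Anscombe "
                       "0.5 correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_value = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    ci_low = float(np.exp(np.log(or_value) - z * se))
    ci_high = float(np.exp(np.log(or_value) + z * se))
    _, p = chi_squared_proportions(t)
    return ORResult(or_value=float(or_value), ci_low=ci_low, ci_high=ci_high,
                    p_value=p)


def chi_squared_proportions(t: TwoByTwo) -> tuple[float, float]:
    """Pearson chi-squared test on the 2x2 table, df=1, no continuity
    correction."""
    if not t.margins_ok():
        raise ValueError("chi-squared undefined: a zero margin")
    table = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def crude_pct(count: int, n: int) -> float:
    if n <= 0:
        raise ValueError("empty denominator")
    return 100.0 * count / n


def crude_and_annualized_rates(cohort: Cohort,
                               event_filter: Callable[[PatientRecord], bool],
                               ) -> tuple[int, float, float]:
    """(count, crude %, %/year) of patients matching ``event_filter``.

    The annualized rate uses summed person-years of follow-up as the
    denominator.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    count = sum(bool(event_filter(p)) for p in cohort.patients)
    person_years = sum(p.followup_years for p in cohort.patients)
    return count, crude_pct(count, len(cohort)), 100.0 * count / person_years


def score_distribution_table(cohort: Cohort,
                             score_results: Sequence[ScoreResult],
                             event_flags: Sequence[bool],
                             cap: int = 5) -> pd.DataFrame:
    """Distribution of events across score values (capped at ``>=cap``) and
    risk categories, with percentages of the total event count."""
    if not (len(cohort) == len(score_results) == len(event_flags)):
        raise ValueError("cohort, scores and event flags must align")
    events = [r for r, e in zip(score_results, event_flags) if e]
    n_events = len(events)
    rows = []
    for v in range(cap):
        k = sum(r.points == v for r in events)
        rows.append({"row": str(v), "n_events": k,
                     "pct_of_events": crude_pct(k, n_events) if n_events else 0.0})
    k = sum(r.points >= cap for r in events)
    rows.append({"row": f">={cap}", "n_events": k,
                 "pct_of_events": crude_pct(k, n_events) if n_events else 0.0})
    for label, cat in (("low_risk", LOW), ("high_or_medium_high_risk", HIGH)):
        k = sum(r.category == cat for r in events)
        rows.append({"row": label, "n_events": k,
                     "pct_of_events": crude_pct(k, n_events) if n_events else 0.0})
    return pd.DataFrame(rows)


def category_two_by_two(score_results: Sequence[ScoreResult],
                        event_flags: Sequence[bool]) -> TwoByTwo:
    """2x2 table of risk category (high/medium-high = exposed) vs event."""
    a = sum(r.category == HIGH and e for r, e in zip(score_results, event_flags))
    b = sum(r.category == HIGH and not e
            for r, e in zip(score_results, event_flags))
    c = sum(r.category == LOW and e for r, e in zip(score_results, event_flags))
    d = sum(r.category == LOW and not e
            for r, e in zip(score_results, event_flags))
    return TwoByTwo(a=a, b=b, c=c, d=d)
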