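"""Time in therapeutic range by Rosendaal linear interpolation.

Between consecutive INR measurements the INR is assumed to change linearly
by day; each inter-visit day is split into time below / in / above the
therapeutic range from the crossing times of the range bounds on the linear
segment.  Boundary INRs (exactly at a range bound) count as in range.
Inter-visit gaps longer than ``max_gap_days`` contribute no time, to either
numerator or denominator.  Time after the last observation in the window is
not extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import INRObservation

DEFAULT_WINDOW_DAYS = 183
DEFAULT_MAX_GAP_DAYS = 56
DEFAULT_LABILE_THRESHOLD_PCT = 65.0


class TTRUndefinedError(ValueError):
    """Fewer than two usable observations in the window."""


@dataclass(frozen=True)
class TTRResult:
    ttr_pct: float
    below_pct: float
    above_pct: float
    pinrr_pct: float
    n_observations: int
    covered_days: float
    labile: bool


def segment_fractions(i0: np.ndarray, i1: np.ndarray,
                      range_low: float, range_high: float
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fractions of a linear INR segment spent below / in / above range.

    Along a linear segment the INR value is uniformly distributed between
    its endpoints, so fractions reduce to clipped interval overlaps.
    Vectorized over arrays of endpoint pairs.
    """
    i0 = np.asarray(i0, dtype=float)
    i1 = np.asarray(i1, dtype=float)
    lo = np.minimum(i0, i1)
    hi = np.maximum(i0, i1)
    span = hi - lo
    constant = span == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        below = np.where(constant, (lo < range_low).astype(float),
                         np.clip((range_low - lo) / np.where(constant, 1, span),
                                 0.0, 1.0))
        above = np.where(constant, (lo > range_high).astype(float),
                         np.clip((hi - range_high) / np.where(constant, 1, span),
                                 0.0, 1.0))
    in_range = np.clip(1.0 - below - above, 0.0, 1.0)
    return below, in_range, above


def rosendaal_ttr(series: Sequence[INRObservation] | Sequence[tuple[float, float]],
                  range_low: float = 2.0, range_high: float = 3.0,
                  window_days: float = DEFAULT_WINDOW_DAYS,
                  max_gap_days: Optional[float] = DEFAULT_MAX_GAP_DAYS,
                  labile_threshold_pct: float = DEFAULT_LABILE_THRESHOLD_PCT,
                  ) -> TTRResult:
    """Rosendaal TTR over ``[0, window_days]`` for one patient's INR series.

    ``series`` is an ordered sequence of :class:`INRObservation` (or plain
    ``(day, inr)`` pairs).  ``max_gap_days=None`` disables the gap cap.
    Raises :class:`TTRUndefinedError` if fewer than two observations fall
    inside the window, and ``ValueError`` on non-increasing days.
    """
    if len(series) == 0:
        raise TTRUndefinedError("empty INR series")
    first = series[0]
    if isinstance(first, INRObservation):
        days = np.array([o.day for o in series], dtype=float)
        inrs = np.array([o.inr for o in series], dtype=float)
    else:
        arr = np.asarray(series, dtype=float).reshape(len(series), 2)
        days, inrs = arr[:, 0], arr[:, 1]
    if np.any(np.diff(days) <= 0):
        raise ValueError("INR observation days must be strictly increasing")

    in_window = (days >= 0) & (days <= window_days)
    n_obs = int(np.count_nonzero(in_window))
    if n_obs < 2:
        raise TTRUndefinedError(
            f"need >= 2 observations within [0, {window_days}] days, "
            f"got {n_obs}")
    pinrr = 100.0 * np.count_nonzero(
        in_window & (inrs >= range_low) & (inrs <= range_high)) / n_obs

    t0, t1 = days[:-1], days[1:]
    v0, v1 = inrs[:-1], inrs[1:]
    keep = (t1 > 0) & (t0 < window_days)
    if max_gap_days is not None:
        keep &= (t1 - t0) <= max_gap_days
    t0, t1, v0, v1 = t0[keep], t1[keep], v0[keep], v1[keep]

    # clip segments to the window by interpolating endpoint INRs
    slope = (v1 - v0) / (t1 - t0)
    c0 = np.maximum(t0, 0.0)
    c1 = np.minimum(t1, float(window_days))
    w0 = v0 + slope * (c0 - t0)
    w1 = v0 + slope * (c1 - t0)
    dur = c1 - c0

    below_f, in_f, above_f = segment_fractions(w0, w1, range_low, range_high)
    covered = float(np.sum(dur))
    if covered <= 0:
        raise TTRUndefinedError("no covered time within the window")
    below = float(np.sum(below_f * dur)) / covered * 100.0
    in_range = float(np.sum(in_f * dur)) / covered * 100.0
    above = float(np.sum(above_f * dur)) / covered * 100.0

    return TTRResult(ttr_pct=in_range, below_pct=below, above_pct=above,
                     pinrr_pct=pinrr, n_observations=n_obs,
                     covered_days=covered,
                     labile=in_range < labile_threshold_pct)


def labile_flag(ttr: TTRResult,
                threshold_pct: float = DEFAULT_LABILE_THRESHOLD_PCT) -> bool:
    """Labile-INR flag: TTR strictly below the threshold (default 65%).

    A TTR of exactly 65.0% is *not* labile.
    """
    return ttr.ttr_pct < threshold_pct


def cohort_ttr_frame(cohort, policy: str = "raise", **kwargs):
    """Per-patient TTR table for a cohort.

    ``policy`` controls undefined TTRs (too few observations): ``"raise"``
    propagates the error, ``"nan"`` emits a row of NaNs with ``labile``
    missing.
    """
    import pandas as pd

    rows = []
    for p in cohort.patients:
        series = cohort.inr_series.get(p.patient_id, [])
        try:
            r = rosendaal_ttr(series, **kwargs)
            rows.append({"patient_id": p.patient_id, "ttr_pct": r.ttr_pct,
                         "below_pct": r.below_pct, "above_pct": r.above_pct,
                         "pinrr_pct": r.pinrr_pct,
                         "n_observations": r.n_observations,
                         "covered_days": r.covered_days,
                         "labile": r.labile})
        except TTRUndefinedError:
            if policy == "raise":
                raise
            rows.append({"patient_id": p.patient_id, "ttr_pct": np.nan,
                         "below_pct": np.nan, "above_pct": np.nan,
                         "pinrr_pct": np.nan, "n_observations": len(series),
                         "covered_days": 0.0, "labile": np.nan})
    return pd.DataFrame(rows)
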