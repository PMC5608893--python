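"""Independent brute-force oracles shared between unit and acceptance
tests.  These deliberately avoid the package's own algorithms."""

import itertools

import numpy as np


def grid_ttr(series, range_low=2.0, range_high=3.0, window_days=183,
             max_gap_days=56, step=0.01):
    """Fine-grid interpolation oracle: evaluate the interpolated INR at
    midpoints of `step`-day cells and count in/below/above fractions."""
    in_t = below_t = above_t = total_t = 0.0
    for (t0, i0), (t1, i1) in zip(series[:-1], series[1:]):
        if max_gap_days is not None and t1 - t0 > max_gap_days:
            continue
        a, b = max(t0, 0.0), min(t1, float(window_days))
        if b <= a:
            continue
        ts = np.arange(a, b, step) + step / 2
        ts = ts[ts < b]
        vals = i0 + (i1 - i0) * (ts - t0) / (t1 - t0)
        below_t += step * np.count_nonzero(vals < range_low)
        above_t += step * np.count_nonzero(vals > range_high)
        in_t += step * np.count_nonzero((vals >= range_low)
                                        & (vals <= range_high))
        total_t += b - a
    return (100 * in_t / total_t, 100 * below_t / total_t,
            100 * above_t / total_t)


def pair_enumeration_cindex(scores, outcome):
    """Concordance by explicit enumeration of all event/non-event pairs."""
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    pos = scores[outcome]
    neg = scores[~outcome]
    total = 0.0
    for a, b in itertools.product(pos, neg):
        total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (pos.size * neg.size)


def random_inr_series(rng, n_min=2, n_max=10, max_day=180):
    n = int(rng.integers(n_min, n_max + 1))
    days = np.sort(rng.choice(np.arange(0, max_day), size=n, replace=False))
    vals = np.round(rng.uniform(0.8, 5.0, size=n), 2)
    return list(zip(days.tolist(), vals.tolist()))
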