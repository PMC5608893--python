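"""Decision-curve analysis: net benefit across threshold probabilities.

A subject is classified positive when the predicted probability is greater
than or equal to the threshold (ties positive, for bit-exact
reproducibility).  Net benefit = TP/N - (FP/N) * t/(1-t); treat-all and
treat-none reference strategies are emitted alongside the models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_GRID = np.round(np.arange(0.01, 0.505, 0.01), 10)


@dataclass(frozen=True)
class NetBenefitCurve:
    model_name: str
    thresholds: np.ndarray
    net_benefit: np.ndarray


def net_benefit(prob, outcome, threshold: float) -> float:
    """Net benefit of 'treat when prob >= threshold' at one threshold."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    prob = np.asarray(prob, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    if prob.shape != outcome.shape:
        raise ValueError("prob and outcome must align")
    n = prob.size
    if n == 0:
        raise ValueError("empty input")
    positive = prob >= threshold
    tp = int((positive & outcome).sum())
    fp = int((positive & ~outcome).sum())
    return tp / n - (fp / n) * threshold / (1 - threshold)


def treat_all_net_benefit(prevalence: float, threshold: float) -> float:
    """Closed form for the treat-all reference curve."""
    return prevalence - (1 - prevalence) * threshold / (1 - threshold)


def decision_curves(models: Mapping[str, Sequence[float]], outcome,
                    grid: Sequence[float] = DEFAULT_GRID) -> pd.DataFrame:
    """Tidy (model, threshold, net_benefit) table for each named model plus
    ``treat_all`` and ``treat_none`` references."""
    if not models:
        raise ValueError("empty model set")
    outcome = np.asarray(outcome, dtype=bool)
    grid = np.asarray(grid, dtype=float)
    prevalence = outcome.mean()
    rows = []
    for name, prob in models.items():
        prob = np.asarray(prob, dtype=float)
        for t in grid:
            rows.append({"model": name, "threshold": float(t),
                         "net_benefit": net_benefit(prob, outcome, t)})
    for t in grid:
        rows.append({"model": "treat_all", "threshold": float(t),
                     "net_benefit": treat_all_net_benefit(prevalence, t)})
        rows.append({"model": "treat_none", "threshold": float(t),
                     "net_benefit": 0.0})
    return pd.DataFrame(rows)
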