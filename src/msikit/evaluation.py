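"""Classifier evaluation: confusion counts, metrics, Wilson intervals, sweeps.

Per-pair instability scores are compared against a gold-standard label
(MSI-H positive vs MSS negative).  A pair is called positive when its score
strictly exceeds the threshold.  Sensitivity and specificity carry 95%
Wilson score intervals with continuity correction; error rate is
incorrect/total and accuracy its complement.  A threshold sweep evaluates a
grid of cutoffs and reports the accuracy-maximizing one (ties resolved to
the smallest threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ranking import LABEL_NEGATIVE, LABEL_POSITIVE, _check_labels
from .scoring import DEFAULT_THRESHOLD


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("at least one call is required")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Point metrics in [0, 1]; None where the denominator is zero."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float
    error_rate: float
    sensitivity_ci: tuple[float, float] | None = None
    specificity_ci: tuple[float, float] | None = None


def confusion(
    scores: "pd.Series | dict[str, float]",
    labels: "pd.Series | dict[str, str]",
    threshold: float = DEFAULT_THRESHOLD,
) -> ConfusionCounts:
    """Tally calls (score > threshold => positive) against gold labels."""
    scores = pd.Series(scores, dtype=float)
    labels = pd.Series(labels)
    _check_labels(labels)
    missing = scores.index.difference(labels.index)
    if len(missing):
        raise KeyError(f"unlabeled pairs: {sorted(missing)}")
    labels = labels.reindex(scores.index)
    called_pos = scores > threshold
    is_pos = labels == LABEL_POSITIVE
    return ConfusionCounts(
        tp=int((called_pos & is_pos).sum()),
        fp=int((called_pos & ~is_pos).sum()),
        tn=int((~called_pos & ~is_pos).sum()),
        fn=int((~called_pos & is_pos).sum()),
    )


def metrics(counts: ConfusionCounts, confidence: float = 0.95) -> MetricSet:
    """Sensitivity, specificity (with Wilson CIs), accuracy and error rate."""
    sens = spec = None
    sens_ci = spec_ci = None
    if counts.tp + counts.fn > 0:
        sens = counts.tp / (counts.tp + counts.fn)
        sens_ci = wilson_ci(counts.tp, counts.tp + counts.fn, confidence)
    if counts.tn + counts.fp > 0:
        spec = counts.tn / (counts.tn + counts.fp)
        spec_ci = wilson_ci(counts.tn, counts.tn + counts.fp, confidence)
    error = (counts.fp + counts.fn) / counts.total
    return MetricSet(
        sensitivity=sens,
        specificity=spec,
        accuracy=1.0 - error,
        error_rate=error,
        sensitivity_ci=sens_ci,
        specificity_ci=spec_ci,
    )


def wilson_ci(
    successes: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval with continuity correction, clipped to [0, 1].

    Closed-form lower/upper bounds (Newcombe's formulation); the lower bound
    is 0 when no successes are observed and the upper bound 1 when all are.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    z = float(norm.ppf(1.0 - (1.0 - confidence) / 2.0))
    p = successes / n
    denom = 2.0 * (n + z * z)
    if successes == 0:
        lower = 0.0
    else:
        lower = (
            2.0 * n * p + z * z - 1.0
            - z * math.sqrt(z * z - 2.0 - 1.0 / n + 4.0 * p * (n * (1.0 - p) + 1.0))
        ) / denom
    if successes == n:
        upper = 1.0
    else:
        upper = (
            2.0 * n * p + z * z + 1.0
            + z * math.sqrt(z * z + 2.0 - 1.0 / n + 4.0 * p * (n * (1.0 - p) - 1.0))
        ) / denom
    return max(0.0, lower), min(1.0, upper)


def threshold_grid(lo: float = 0.001, hi: float = 0.6, count: int = 600) -> np.ndarray:
    """Evenly spaced candidate thresholds, endpoints included."""
    return np.linspace(lo, hi, count)


def threshold_sweep(
    scores: "pd.Series | dict[str, float]",
    labels: "pd.Series | dict[str, str]",
    grid: "np.ndarray | list[float] | None" = None,
) -> tuple[pd.DataFrame, float]:
    """Metrics at every grid threshold; returns (table, best threshold).

    Best is the accuracy-maximizing threshold, smallest first on ties.
    """
    grid = threshold_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid must be non-empty")
    rows = []
    for t in grid:
        m = metrics(confusion(scores, labels, threshold=float(t)))
        rows.append(
            {
                "threshold": float(t),
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "accuracy": m.accuracy,
                "error_rate": m.error_rate,
            }
        )
    table = pd.DataFrame(rows)
    best_idx = int(table["accuracy"].to_numpy().argmax())  # argmax takes first tie
    return table, float(table.loc[best_idx, "threshold"])


def format_percent(x: float | None) -> str:
    """One-decimal percentage, e.g. 0.9737 -> '97.4%'; '.' when undefined."""
    return "." if x is None else f"{100.0 * x:.1f}%"
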