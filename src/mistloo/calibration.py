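"""ROC calibration of the leave-one-out percent-increase threshold.

The driver-variant threshold is chosen by evaluating sensitivity and
specificity against a labeled set of known pathogenic variants (in the
source study, protein-truncating and splicing variants of a well
characterized susceptibility gene) across a grid of candidate thresholds,
and picking the threshold maximizing Youden's J.  Proportions carry exact
(Clopper-Pearson) binomial confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateLabelError(ValueError):
    """Both a positive and a negative class are required."""


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for k successes in n trials.

    Obtained by inverting the binomial tails via beta quantiles; the
    boundary cases are lower = 0 at k = 0 and upper = 1 at k = n (where
    the lower bound is (alpha/2)^(1/n)).
    """
    if n < 1:
        raise ValueError("need n >= 1 trials")
    if not (0 <= k <= n):
        raise ValueError("successes must lie in [0, n]")
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lo, hi


@dataclass(frozen=True)
class RocPoint:
    """Confusion counts and rates at one percent-increase threshold."""

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def confusion_at_threshold(pct_increases: np.ndarray, labels: np.ndarray,
                           threshold: float, conf: float = 0.95) -> RocPoint:
    """Confusion statistics for the rule ``flag = pct_increase >= threshold``.

    ``labels`` is boolean (True = known pathogenic).  Raises
    :class:`DegenerateLabelError` unless both classes are present.
    """
    inc = np.asarray(pct_increases, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if inc.shape != lab.shape:
        raise ValueError("increase and label vectors differ in length")
    if lab.all() or not lab.any():
        raise DegenerateLabelError("need both pathogenic and benign labels")
    flag = inc >= threshold
    tp = int((flag & lab).sum())
    fp = int((flag & ~lab).sum())
    fn = int((~flag & lab).sum())
    tn = int((~flag & ~lab).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return RocPoint(
        threshold=float(threshold), tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec,
        sens_ci=clopper_pearson(tp, tp + fn, conf),
        spec_ci=clopper_pearson(tn, tn + fp, conf),
    )


def default_grid() -> np.ndarray:
    """Threshold grid from 5% to 105% in 5-point steps."""
    return np.round(np.arange(0.05, 1.051, 0.05), 2)


def roc_select_threshold(pct_increases: np.ndarray, labels: np.ndarray,
                         grid: np.ndarray | None = None
                         ) -> tuple[float, list[RocPoint]]:
    """Pick the grid threshold maximizing Youden's J (ties -> stricter).

    Returns (chosen threshold, the full ROC point list).  If even the best
    threshold has J <= 0 the labels are likely inverted or uninformative
    and a warning is emitted.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    points = [confusion_at_threshold(pct_increases, labels, t) for t in grid]
    best_j = max(p.youden_j for p in points)
    chosen = max(p.threshold for p in points if p.youden_j == best_j)
    if best_j <= 0:
        warnings.warn(
            "best Youden J is non-positive; labels may be inverted",
            stacklevel=2,
        )
    return chosen, points


def roc_table(points: list[RocPoint]) -> pd.DataFrame:
    """ROC points as a tidy table for reporting."""
    return pd.DataFrame(
        {
            "threshold": [p.threshold for p in points],
            "tp": [p.tp for p in points],
            "fp": [p.fp for p in points],
            "tn": [p.tn for p in points],
            "fn": [p.fn for p in points],
            "sensitivity": [p.sensitivity for p in points],
            "specificity": [p.specificity for p in points],
            "sens_lo": [p.sens_ci[0] for p in points],
            "sens_hi": [p.sens_ci[1] for p in points],
            "spec_lo": [p.spec_ci[0] for p in points],
            "spec_hi": [p.spec_ci[1] for p in points],
            "youden_j": [p.youden_j for p in points],
        }
    )
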