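"""Agreement and performance statistics for the pipeline's two tasks.

Classification of segment quality is summarized by confusion-matrix
metrics (accuracy, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP));
BP estimation by Pearson correlation, mean absolute difference, Bland-
Altman limits of agreement (bias +/- 1.96 SD of the errors), and the
cumulative error distribution at 5/10/15 mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "AgreementStats",
    "classification_metrics",
    "pearson",
    "mad",
    "bland_altman",
    "error_distribution",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        t = np.asarray(y_true).astype(bool)
        p = np.asarray(y_pred).astype(bool)
        if t.shape != p.shape:
            raise ValueError("label arrays must match in length")
        return cls(
            tp=int(np.sum(t & p)),
            tn=int(np.sum(~t & ~p)),
            fp=int(np.sum(~t & p)),
            fn=int(np.sum(t & ~p)),
        )


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman summary: bias, error SD, limits, % outside the limits."""

    bias: float
    sd_error: float
    loa_lower: float
    loa_upper: float
    pct_outside: float

    def __post_init__(self) -> None:
        if not self.loa_lower <= self.bias <= self.loa_upper:
            raise ValueError("limits of agreement must bracket the bias")


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity TP/(TP+FN), specificity TN/(TN+FP).

    A zero denominator reports NaN for that metric rather than raising.
    """
    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return {
        "accuracy": _ratio(c.tp + c.tn, c.total),
        "sensitivity": _ratio(c.tp, c.tp + c.fn),
        "specificity": _ratio(c.tn, c.tn + c.fp),
    }


def pearson(x, y) -> float:
    """Pearson correlation rho(X, Y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equal length")
    if len(x) < 2:
        raise ValueError("need at least two points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


def mad(errors, variant: str = "mean_abs") -> float:
    """Mean absolute difference of a sequence of errors (mmHg).

    ``mean_abs`` is the primary definition; ``rms`` exposes the
    sqrt(S^2 + Dbar^2) combination of error SD and mean error as an
    alternative magnitude measure.
    """
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("empty error sequence")
    if variant == "mean_abs":
        return float(np.mean(np.abs(e)))
    if variant == "rms":
        return float(np.sqrt(np.std(e) ** 2 + np.mean(e) ** 2))
    raise ValueError(f"unknown MAD variant {variant!r}")


def bland_altman(reference, estimate) -> AgreementStats:
    """Limits-of-agreement analysis of estimate - reference errors.

    bias = mean error; limits = bias +/- 1.96 * SD(error) (population SD);
    ``pct_outside`` is the percentage of pairs beyond either limit.
    """
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    if ref.shape != est.shape:
        raise ValueError("paired sequences must match in length")
    if len(ref) < 2:
        raise ValueError("need at least two pairs")
    err = est - ref
    bias = float(np.mean(err))
    sd = float(np.std(err))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    outside = float(np.mean((err < lo) | (err > hi)) * 100.0)
    return AgreementStats(bias=bias, sd_error=sd, loa_lower=lo, loa_upper=hi,
                          pct_outside=outside)


def error_distribution(errors, bins_mmHg=(5.0, 10.0, 15.0)) -> dict[float, float]:
    """Cumulative % of |error| no more than each bound (inclusive)."""
    e = np.abs(np.asarray(errors, dtype=float))
    if e.size == 0:
        raise ValueError("empty error sequence")
    return {float(b): float(np.mean(e <= b) * 100.0) for b in bins_mmHg}
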