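"""Normalization, classification metrics, and model-comparison statistics.

Metrics come straight from aggregate confusion counts:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

For multiclass problems the counts are micro one-vs-rest totals: each
class in turn is treated as positive, and its TP/TN/FP/FN are summed
over classes before the formulas apply.

Model comparison uses the paired t-test (sample standard deviation,
n - 1 degrees of freedom, two-sided p from the exact t distribution),
Cohen's d with the pooled standard deviation, and the t-based confidence
interval for a mean.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """y_i = (x_i - min) / (max - min), preserving shape.

    A constant input maps to all zeros (degenerate-denominator
    convention).  Idempotent on already-normalized non-constant input.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty array")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# confusion counts and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray, num_classes: int | None = None
    ) -> "ConfusionCounts":
        """Micro one-vs-rest totals: sum per-class TP/TN/FP/FN over all
        classes, each class in turn taken as positive."""
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must have the same length")
        if num_classes is None:
            num_classes = int(max(y_true.max(), y_pred.max())) + 1
        tp = tn = fp = fn = 0
        for k in range(num_classes):
            pos_true, pos_pred = y_true == k, y_pred == k
            tp += int(np.sum(pos_true & pos_pred))
            tn += int(np.sum(~pos_true & ~pos_pred))
            fp += int(np.sum(~pos_true & pos_pred))
            fn += int(np.sum(pos_true & ~pos_pred))
        return cls(tp, tn, fp, fn)


@dataclass
class MetricReport:
    """Accuracy/precision/recall/F1 in [0, 1]; a metric whose denominator
    is zero is ``None`` and listed in ``undefined`` rather than being
    silently reported as 0."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    undefined: list = field(default_factory=list)

    def as_percentages(self, decimals: int = 2) -> dict:
        out = {}
        for name in ("accuracy", "precision", "recall", "f1"):
            value = getattr(self, name)
            out[name] = None if value is None else round_half_away(
                100.0 * value, decimals
            )
        return out

    def to_json(self) -> str:
        d = {name: getattr(self, name)
             for name in ("accuracy", "precision", "recall", "f1")}
        d["undefined"] = self.undefined
        return json.dumps(d)


def round_half_away(value: float, decimals: int = 2) -> float:
    """Round half away from zero (matching how printed percentages are
    conventionally rounded, unlike banker's rounding)."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)


def classification_metrics(c: ConfusionCounts) -> MetricReport:
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    undefined = []

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    accuracy = ratio(c.tp + c.tn, c.total, "accuracy")
    precision = ratio(c.tp, c.tp + c.fp, "precision")
    recall = ratio(c.tp, c.tp + c.fn, "recall")
    if precision is None or recall is None or precision + recall == 0.0:
        undefined.append("f1")
        f1 = None
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricReport(accuracy, precision, recall, f1, undefined)


# ---------------------------------------------------------------------------
# comparison statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def paired_t_test(a: np.ndarray, b: np.ndarray) -> TTestResult:
    """Two-sided paired t-test on matched samples.

    t = mean(a - b) / (sd(a - b) / sqrt(n)) with the sample standard
    deviation (n - 1 denominator); df = n - 1; p from the exact t CDF.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D vectors of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise ValueError("differences have zero variance; t is undefined")
    t = float(np.mean(d)) / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=t, df=df, p=p)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference with the pooled sample SD:

    d = (mean(a) - mean(b)) / sqrt(((n_a-1) s_a^2 + (n_b-1) s_b^2)
                                   / (n_a + n_b - 2))
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    na, nb = a.size, b.size
    pooled_var = (
        (na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)
    ) / (na + nb - 2)
    pooled_sd = math.sqrt(float(pooled_var))
    if pooled_sd == 0.0:
        raise ValueError("pooled standard deviation is zero; d is undefined")
    return float(np.mean(a) - np.mean(b)) / pooled_sd


def mean_confidence_interval(
    x: np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """t-based CI for the mean: mean +/- t_{(1+level)/2, n-1} * sd/sqrt(n)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values for a confidence interval")
    if not 0.0 <= level < 1.0:
        raise ValueError("level must lie in [0, 1)")
    n = x.size
    mean = float(np.mean(x))
    half = float(
        stats.t.ppf((1.0 + level) / 2.0, n - 1) * np.std(x, ddof=1) / math.sqrt(n)
    )
    return mean - half, mean + half


def comparison_report(a: np.ndarray, b: np.ndarray, level: float = 0.95) -> dict:
    """t-test, effect size and per-sample CIs for two accuracy columns."""
    test = paired_t_test(a, b)
    ci_a = mean_confidence_interval(a, level)
    ci_b = mean_confidence_interval(b, level)
    return {
        "t_statistic": test.t,
        "df": test.df,
        "p_value": test.p,
        "cohens_d": cohens_d(a, b),
        "ci_a": list(ci_a),
        "ci_b": list(ci_b),
        "level": level,
    }
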