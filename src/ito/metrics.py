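"""Accuracy, Matthews correlation, the efficiency index rho, and filtering arithmetic.

The efficiency index of a binary predictor is

    rho = MCC * accuracy

a statistical conjunction of reliability (MCC, robust to class imbalance)
and raw accuracy: a model only scores high when it is strong on both,
which is what makes rho usable for ranking candidate models where accuracy
alone rewards overfitting to the majority class.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class MetricError(ValueError):
    pass


def confusion_counts(predicted, actual) -> tuple:
    """(TP, TN, FP, FN) with 1 as the positive class."""
    p = np.asarray(predicted)
    a = np.asarray(actual)
    if p.shape != a.shape or p.ndim != 1 or len(p) == 0:
        raise MetricError("vectors must be 1-d, equal length and nonempty")
    if not (np.isin(p, (0, 1)).all() and np.isin(a, (0, 1)).all()):
        raise MetricError("vectors must be binary 0/1")
    tp = int(np.sum((p == 1) & (a == 1)))
    tn = int(np.sum((p == 0) & (a == 0)))
    fp = int(np.sum((p == 1) & (a == 0)))
    fn = int(np.sum((p == 0) & (a == 1)))
    return tp, tn, fp, fn


def mcc(counts) -> float:
    """Matthews correlation coefficient from (TP, TN, FP, FN).

    Any zero factor in the denominator yields 0 (the usual convention for
    degenerate confusion tables).
    """
    tp, tn, fp, fn = (float(c) for c in counts)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def efficiency_index(mcc_value: float, accuracy_value: float) -> float:
    """rho = MCC * accuracy (no clamping)."""
    return mcc_value * accuracy_value


@dataclass(frozen=True)
class EvaluationResult:
    """Accuracy, MCC and rho of one predictor under one evaluation protocol."""

    accuracy: float
    mcc: float
    rho: float
    n_evaluated: int
    confusion: tuple

    @classmethod
    def from_predictions(cls, predicted, actual) -> "EvaluationResult":
        counts = confusion_counts(predicted, actual)
        tp, tn, fp, fn = counts
        n = tp + tn + fp + fn
        acc = (tp + tn) / n
        m = mcc(counts)
        return cls(accuracy=acc, mcc=m, rho=efficiency_index(m, acc), n_evaluated=n, confusion=counts)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "rho": self.rho,
            "n_evaluated": self.n_evaluated,
            "confusion": list(self.confusion),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationResult":
        return cls(
            accuracy=d["accuracy"],
            mcc=d["mcc"],
            rho=d["rho"],
            n_evaluated=d["n_evaluated"],
            confusion=tuple(d["confusion"]),
        )


#: reporting offset so the strict test rho > epsilon holds for the pass set
_EPSILON_OFFSET = 2.0 ** -40


def epsilon_for_fraction(rhos, fraction: float) -> tuple:
    """Threshold admitting at least the top ``fraction`` of ``rhos``.

    ``k = ceil(fraction * n)`` members pass; members tied with the k-th
    value also pass ("at least"). Returns ``(epsilon, pass_indices)`` where
    ``epsilon`` is just below the smallest passing rho, so the strict
    filter ``rho > epsilon`` reproduces the pass set.
    """
    rhos = list(rhos)
    if not rhos:
        raise MetricError("empty rho list")
    if not 0 < fraction <= 1:
        raise MetricError("fraction must be in (0, 1]")
    k = math.ceil(fraction * len(rhos))
    boundary = sorted(rhos, reverse=True)[k - 1]
    pass_idx = [i for i, r in enumerate(rhos) if r >= boundary]
    epsilon = boundary - _EPSILON_OFFSET
    return epsilon, pass_idx


def improvement_percentage(final: float, baseline: float):
    """Relative gain of ``final`` over ``baseline``: 100*(final-baseline)/final.

    Undefined (returns None) when ``final`` is 0.
    """
    if final == 0:
        return None
    return 100.0 * (final - baseline) / final
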