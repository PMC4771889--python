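"""Confusion-matrix scoring of an inferred signed network against a gold standard.

Every ordered gene pair (i, j), *including* self-pairs, is classified by
whether a regulation is predicted and whether one exists in the gold
standard, so the four counts always sum to N^2.  Edge existence is scored
unsigned (regulation vs no regulation); sign fidelity among true positives
is reported separately.

Metrics:

    Sn  = TP / (TP + FN)                    (sensitivity / recall)
    Sp  = TN / (TN + FP)                    (specificity)
    Acc = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) /
          sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))   (0 when the denominator is 0)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .benchmark import SignedNetwork

__all__ = ["ConfusionMetrics", "metrics_from_counts", "confusion", "sign_agreement"]


@dataclass
class ConfusionMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def rounded(self, ndigits: int = 3) -> dict:
        """Summary dict with metrics rounded for reporting."""
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "Sn": round(self.sensitivity, ndigits),
            "Sp": round(self.specificity, ndigits),
            "Accuracy": round(self.accuracy, ndigits),
            "MCC": round(self.mcc, ndigits),
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> ConfusionMetrics:
    """Compute Sn, Sp, accuracy and MCC from raw confusion counts."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    sn = _safe_div(tp, tp + fn)
    sp = _safe_div(tn, tn + fp)
    acc = _safe_div(tp + tn, tp + tn + fp + fn)
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, denom)
    return ConfusionMetrics(int(tp), int(tn), int(fp), int(fn), sn, sp, acc, mcc)


def confusion(predicted: SignedNetwork, gold: SignedNetwork) -> ConfusionMetrics:
    """Score predicted vs gold regulations over all N^2 ordered gene pairs."""
    if predicted.n_genes != gold.n_genes:
        raise ValueError(
            f"network sizes differ: {predicted.n_genes} vs {gold.n_genes}"
        )
    p = predicted.signs != 0
    g = gold.signs != 0
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    return metrics_from_counts(tp, tn, fp, fn)


def sign_agreement(predicted: SignedNetwork, gold: SignedNetwork) -> tuple[int, int]:
    """Among true-positive pairs, count matching vs flipped regulation signs.

    A fitted weight perturbed from the true one is harmless unless its sign
    (the regulation type) flips.
    """
    if predicted.n_genes != gold.n_genes:
        raise ValueError("network sizes differ")
    ps, gs = predicted.signs, gold.signs
    tp_mask = (ps != 0) & (gs != 0)
    n_correct = int(np.sum(tp_mask & (ps == gs)))
    n_flipped = int(np.sum(tp_mask & (ps != gs)))
    return n_correct, n_flipped
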