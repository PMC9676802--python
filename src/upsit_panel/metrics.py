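"""Diagnostic test metrics from 2×2 confusion matrices.

Covers the full published metric suite — sensitivity, specificity, positive
and negative likelihood ratios, positive and negative predictive values,
accuracy — each proportion with its binomial standard error
SE = sqrt(p(1−p)/n), plus the inverse problem: recovering the unique integer
confusion matrix consistent with sensitivity/specificity printed at two
decimals, given the class sizes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FN/FP/TN with PD as the positive class (tp = PD called PD)."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.n_pd < 1 or self.n_hs < 1:
            raise ValueError("both classes must contain at least one subject")

    @property
    def n_pd(self) -> int:
        return self.tp + self.fn

    @property
    def n_hs(self) -> int:
        return self.fp + self.tn

    @property
    def n(self) -> int:
        return self.n_pd + self.n_hs


def proportion_se(p: float, n: int) -> float:
    """Binomial standard error sqrt(p(1−p)/n)."""
    if n < 1:
        raise ValueError("denominator must be ≥ 1")
    if not 0 <= p <= 1:
        raise ValueError(f"proportion {p} outside [0, 1]")
    return math.sqrt(p * (1 - p) / n)


@dataclass(frozen=True)
class DiagnosticReport:
    """The full metric suite of a confusion matrix.

    Proportions carry binomial SEs.  ``lr_pos_infinite`` flags a perfect
    specificity (fp = 0); in that case ``lr_pos`` holds the one-sided
    continuity-corrected value sens/(0.5/n_hs) and the flag must be consulted.
    ``ppv``/``npv`` are None when their denominator is empty (no positive /
    no negative calls).
    """

    cm: ConfusionMatrix
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    accuracy: float
    sensitivity_se: float
    specificity_se: float
    ppv_se: float | None
    npv_se: float | None
    accuracy_se: float
    lr_pos: float
    lr_neg: float
    lr_pos_infinite: bool

    def to_dict(self) -> dict:
        return {
            "confusion": {"tp": self.cm.tp, "fn": self.cm.fn, "fp": self.cm.fp, "tn": self.cm.tn},
            "sensitivity": self.sensitivity, "sensitivity_se": self.sensitivity_se,
            "specificity": self.specificity, "specificity_se": self.specificity_se,
            "ppv": self.ppv, "ppv_se": self.ppv_se,
            "npv": self.npv, "npv_se": self.npv_se,
            "accuracy": self.accuracy, "accuracy_se": self.accuracy_se,
            "lr_pos": self.lr_pos, "lr_pos_infinite": self.lr_pos_infinite,
            "lr_neg": self.lr_neg,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def metrics_from_confusion(cm: ConfusionMatrix) -> DiagnosticReport:
    """Compute the full diagnostic suite from raw counts."""
    sens = cm.tp / cm.n_pd
    spec = cm.tn / cm.n_hs
    n_pos_calls = cm.tp + cm.fp
    n_neg_calls = cm.tn + cm.fn
    ppv = cm.tp / n_pos_calls if n_pos_calls else None
    npv = cm.tn / n_neg_calls if n_neg_calls else None
    acc = (cm.tp + cm.tn) / cm.n
    lr_pos_inf = cm.fp == 0
    if lr_pos_inf:
        # one-sided continuity correction: false-positive rate 0.5/n_hs
        lr_pos = sens / (0.5 / cm.n_hs)
    else:
        lr_pos = sens / (1 - spec)
    lr_neg = (1 - sens) / spec if spec > 0 else math.inf
    return DiagnosticReport(
        cm=cm,
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv, accuracy=acc,
        sensitivity_se=proportion_se(sens, cm.n_pd),
        specificity_se=proportion_se(spec, cm.n_hs),
        ppv_se=proportion_se(ppv, n_pos_calls) if ppv is not None else None,
        npv_se=proportion_se(npv, n_neg_calls) if npv is not None else None,
        accuracy_se=proportion_se(acc, cm.n),
        lr_pos=lr_pos, lr_neg=lr_neg, lr_pos_infinite=lr_pos_inf,
    )


def mann_whitney_auc(scores, y) -> float:
    """AUROC of continuous scores via the rank (Mann–Whitney) statistic.

    Ties receive mid-ranks.  ``y`` is the 0/1 class vector (PD = 1); higher
    scores are assumed to indicate PD.
    """
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for AUROC")
    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


class ReconstructionError(ValueError):
    """No or multiple integer matrices match the rounded metrics."""


def _rounds_to(exact: float, printed: float) -> bool:
    # interval membership [printed − 0.005, printed + 0.005): robust to the
    # rounding convention used when the table was typeset
    return printed - 0.005 <= exact < printed + 0.005


def reconstruct_confusion(
    sens_2dp: float, spec_2dp: float, n_pd: int, n_hs: int
) -> ConfusionMatrix:
    """Invert 2-dp rounded sensitivity/specificity to the integer matrix.

    Exhaustively searches tp ∈ 0..n_pd, tn ∈ 0..n_hs for counts whose exact
    proportions fall in the half-open rounding interval of each printed value.
    Raises ReconstructionError when no or multiple solutions exist (listing
    them all in the multiple case).
    """
    if n_pd < 1 or n_hs < 1:
        raise ValueError("class sizes must be positive")
    tps = [tp for tp in range(n_pd + 1) if _rounds_to(tp / n_pd, sens_2dp)]
    tns = [tn for tn in range(n_hs + 1) if _rounds_to(tn / n_hs, spec_2dp)]
    solutions = [(tp, tn) for tp in tps for tn in tns]
    if not solutions:
        raise ReconstructionError(
            f"no integer matrix has sens≈{sens_2dp}, spec≈{spec_2dp} at n={n_pd}/{n_hs}"
        )
    if len(solutions) > 1:
        raise ReconstructionError(f"multiple solutions: {solutions}")
    tp, tn = solutions[0]
    return ConfusionMatrix(tp=tp, fn=n_pd - tp, fp=n_hs - tn, tn=tn)
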