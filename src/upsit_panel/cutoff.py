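"""Panel sum score, integer-threshold ROC, and the Youden-optimal cut-off.

The screening rule is "panel sum score ≤ t ⇒ PD" (hyposmia lowers odor
identification scores).  Thresholds are integers only — scores are counts —
and the Youden index J(t) = sensitivity(t) + specificity(t) − 1 picks the
cut-off, ties broken toward the lowest t (favors specificity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortMatrix
from .metrics import mann_whitney_auc


@dataclass(frozen=True)
class SumScoreRoc:
    """Per-integer-threshold operating points of the "score ≤ t ⇒ PD" rule."""

    thresholds: np.ndarray     # t = -1 .. max score
    sensitivity: np.ndarray    # P(score ≤ t | PD)
    specificity: np.ndarray    # P(score > t | HS)
    youden: np.ndarray         # sens + spec − 1
    auc: float                 # trapezoid over (FPR, TPR)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "youden_j": self.youden,
        })

    def to_csv(self, path) -> None:
        self.table().to_csv(path, index=False)


def sum_score(cohort: CohortMatrix, panel=None) -> np.ndarray:
    """Per-subject count of correct responses among panel items (None = all)."""
    if panel is None:
        idx = list(range(cohort.n_items))
    else:
        idx = [int(i) for i in (panel.items if hasattr(panel, "items") else panel)]
        if any(i < 0 or i >= cohort.n_items for i in idx):
            raise ValueError("panel contains item indices outside the cohort")
    return cohort.responses[:, idx].sum(axis=1)


def roc_over_cutoffs(scores: np.ndarray, y: np.ndarray) -> SumScoreRoc:
    """ROC of the low-score-positive rule across every integer threshold.

    For t in −1..max(scores): sens = fraction of PD with score ≤ t,
    spec = fraction of HS with score > t.  t = −1 (call nobody PD) anchors
    the curve at (0, 0) in (FPR, TPR) space; AUC is the trapezoid over it.
    """
    scores = np.asarray(scores, dtype=int)
    y = np.asarray(y, dtype=int)
    n_pd = int(y.sum())
    n_hs = int(len(y) - n_pd)
    if n_pd == 0 or n_hs == 0:
        raise ValueError("both classes required")
    ts = np.arange(-1, int(scores.max()) + 1)
    sens = np.array([(scores[y == 1] <= t).mean() for t in ts])
    spec = np.array([(scores[y == 0] > t).mean() for t in ts])
    fpr = 1 - spec
    auc = float(np.trapezoid(sens, fpr))
    return SumScoreRoc(thresholds=ts, sensitivity=sens, specificity=spec,
                       youden=sens + spec - 1, auc=auc)


def youden_cutoff(roc: SumScoreRoc) -> tuple[int, float]:
    """Threshold maximizing J; ties go to the lowest t."""
    if roc.thresholds.size == 0:
        raise ValueError("empty ROC")
    i = int(np.argmax(roc.youden))  # argmax takes the first (lowest t) on ties
    return int(roc.thresholds[i]), float(roc.youden[i])


def cutoff_summary(cohort: CohortMatrix, panel=None) -> dict:
    """Convenience bundle: scores → ROC → chosen cut-off, as plain dict."""
    scores = sum_score(cohort, panel)
    roc = roc_over_cutoffs(scores, cohort.y)
    t, j = youden_cutoff(roc)
    i = int(np.where(roc.thresholds == t)[0][0])
    return {
        "cutoff": t,
        "rule": f"score <= {t} => PD",
        "youden_j": j,
        "sensitivity": float(roc.sensitivity[i]),
        "specificity": float(roc.specificity[i]),
        "auc": roc.auc,
        "auc_mann_whitney": mann_whitney_auc(-scores, cohort.y),
    }


def write_cutoff_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
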