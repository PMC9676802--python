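"""Univariate per-item discrimination statistics and rankings.

For each item, the 2×2 correct/incorrect by class table yields three
statistics:

* two-sided Fisher exact p-value (point-probability rule);
* diagnostic odds ratio, DOR = (incorrect_PD · correct_HS) /
  (correct_PD · incorrect_HS), with the Haldane–Anscombe +0.5 correction on
  all four cells whenever any cell is zero;
* single-item AUC of the binary rule "incorrect response ⇒ PD",
  AUC = (TPR + TNR)/2.

The incorrect response is the test-positive state for PD throughout, so
larger DOR/AUC (and smaller p) always mean a more discriminative item.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .cohort import CohortMatrix, ContingencyTable, contingency_for_item
from .ranking import ASCENDING, MethodRanking, order_from_scores

UNIVARIATE_METHODS = ("fisher", "dor", "auc")


def fisher_exact_p(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value for one item's 2×2 table.

    Sums hypergeometric probabilities (margins fixed) of all tables whose
    point probability is ≤ that of the observed table.  Degenerate tables
    with a zero margin (e.g. every subject correct) return 1.0 by convention.
    """
    if table.n_pd < 1 or table.n_hs < 1:
        raise ValueError("both class sizes must be ≥ 1")
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0  # degenerate: a zero margin carries no information
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def diagnostic_odds_ratio(table: ContingencyTable) -> float:
    """DOR with Haldane–Anscombe +0.5 correction when any cell is zero."""
    a, b = float(table.incorrect_pd), float(table.correct_pd)
    c, d = float(table.incorrect_hs), float(table.correct_hs)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def item_auc(table: ContingencyTable) -> float:
    """AUC of the single binary predictor "incorrect ⇒ PD": (TPR + TNR)/2."""
    if table.n_pd < 1 or table.n_hs < 1:
        raise ValueError("both class sizes must be ≥ 1")
    tpr = table.incorrect_pd / table.n_pd
    tnr = table.correct_hs / table.n_hs
    return (tpr + tnr) / 2


_STAT_FUNCS = {"fisher": fisher_exact_p, "dor": diagnostic_odds_ratio, "auc": item_auc}


def rank_items(cohort: CohortMatrix, method: str) -> MethodRanking:
    """Rank all items by one univariate statistic.

    fisher sorts ascending p; dor/auc sort descending.  Ties break toward the
    lower item index.  A note is recorded whenever the DOR of an item needed
    the zero-cell correction.
    """
    if method not in UNIVARIATE_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {UNIVARIATE_METHODS}")
    func = _STAT_FUNCS[method]
    tables = [contingency_for_item(cohort, j) for j in range(cohort.n_items)]
    scores = np.array([func(t) for t in tables])
    notes = []
    if method == "dor":
        corrected = [j + 1 for j, t in enumerate(tables) if min(t.as_array().ravel()) == 0]
        if corrected:
            notes.append(f"Haldane-Anscombe +0.5 correction applied to items {corrected}")
    ascending = ASCENDING[method]
    return MethodRanking(
        method=method,
        scores=scores,
        order=order_from_scores(scores, ascending),
        direction="ascending p-value" if ascending else f"descending {method}",
        notes=tuple(notes),
    )
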