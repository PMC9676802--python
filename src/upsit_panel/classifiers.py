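"""Panel classifiers: PLS-DA and a CART decision tree, with pooled-fold CV.

PLS-DA fits a PLS1 regression (NIPALS) of the 0/1 class indicator (PD = 1) on
the selected item columns and thresholds the continuous prediction at 0.5.
The tree is greedy binary recursive partitioning on 0/1 responses with Gini
impurity; tie-breaks are pinned so fits are fully deterministic: equal
impurity gains go to the lowest item number, and a tied leaf labels PD
(screening favors sensitivity).

Cross-validation is stratified k-fold (seeded, shuffled); every subject is
predicted exactly once out-of-fold and all metrics derive from the single
pooled confusion matrix — never from per-fold averages.  AUROC comes from the
pooled out-of-fold scores via the mid-rank Mann–Whitney statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

from .cohort import CohortMatrix
from .metrics import ConfusionMatrix, DiagnosticReport, mann_whitney_auc, metrics_from_confusion

DEFAULT_N_COMPONENTS = 2
DEFAULT_N_FOLDS = 10
DEFAULT_MAX_DEPTH = 10
DEFAULT_MIN_LEAF = 2
PLSDA_THRESHOLD = 0.5


def _select_items(cohort: CohortMatrix, items) -> tuple[np.ndarray, tuple[int, ...]]:
    if items is None:
        idx = tuple(range(cohort.n_items))
    else:
        idx = tuple(int(i) for i in (items.items if hasattr(items, "items") else items))
        if any(i < 0 or i >= cohort.n_items for i in idx):
            raise ValueError("panel contains item indices outside the cohort")
    return cohort.responses[:, list(idx)].astype(float), idx


# ---------------------------------------------------------------------------
# PLS-DA


@dataclass(frozen=True)
class PlsdaModel:
    """Fitted PLS1 discriminant model on an item subset.

    Stores everything needed to reproduce predictions by explicit matrix
    arithmetic: column means, per-component x-weights/loadings and the
    regression coefficients of the final linear predictor.
    """

    items: tuple[int, ...]
    x_mean: np.ndarray
    y_mean: float
    x_weights: np.ndarray    # (p, n_comp), unit-norm columns
    x_loadings: np.ndarray   # (p, n_comp)
    coef: np.ndarray         # (p,), final linear predictor on centered X
    n_components: int
    threshold: float = PLSDA_THRESHOLD


def fit_plsda(
    cohort: CohortMatrix, items=None, n_components: int = DEFAULT_N_COMPONENTS
) -> PlsdaModel:
    """Fit PLS-DA on the given item subset (None = all items).

    Each component's x-weight is proportional to Xᵀy on the deflated,
    centered data (normalized); X is deflated per component.  Raises when
    n_components exceeds the rank of the centered item matrix.
    """
    X, idx = _select_items(cohort, items)
    y = cohort.y.astype(float)
    if n_components < 1:
        raise ValueError("n_components must be ≥ 1")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds the centered data rank {rank}"
        )
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    return PlsdaModel(
        items=idx,
        x_mean=pls._x_mean.copy(),
        y_mean=float(pls._y_mean[0]),
        x_weights=pls.x_weights_.copy(),
        x_loadings=pls.x_loadings_.copy(),
        coef=pls.coef_.ravel().copy(),
        n_components=n_components,
    )


def plsda_scores(model: PlsdaModel, cohort: CohortMatrix) -> np.ndarray:
    """Continuous linear predictor on the 0/1 response scale."""
    missing = [i for i in model.items if i >= cohort.n_items]
    if missing:
        raise ValueError(f"cohort lacks item indices {missing}")
    X = cohort.responses[:, list(model.items)].astype(float)
    return (X - model.x_mean) @ model.coef + model.y_mean


def predict_plsda(model: PlsdaModel, cohort: CohortMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject continuous score and 0/1 label (PD iff score ≥ threshold)."""
    scores = plsda_scores(model, cohort)
    return scores, (scores >= model.threshold).astype(int)


# ---------------------------------------------------------------------------
# Decision tree


@dataclass(frozen=True)
class TreeNode:
    """One node; internal nodes split on item == 1 (right = correct)."""

    n_pd: int
    n_hs: int
    item: int | None = None           # None for leaves
    left: "TreeNode | None" = None    # incorrect response (0)
    right: "TreeNode | None" = None   # correct response (1)

    @property
    def is_leaf(self) -> bool:
        return self.item is None

    @property
    def pd_fraction(self) -> float:
        return self.n_pd / (self.n_pd + self.n_hs)

    @property
    def label(self) -> int:
        # exact tie labels PD: a screening rule prefers sensitivity
        return int(self.n_pd >= self.n_hs)


@dataclass(frozen=True)
class TreeModel:
    items: tuple[int, ...]
    root: TreeNode
    max_depth: int
    min_leaf: int
    criterion: str = "gini"

    def depth(self) -> int:
        def _d(node):
            if node.is_leaf:
                return 0
            return 1 + max(_d(node.left), _d(node.right))
        return _d(self.root)


def _gini(n_pd: int, n_hs: int) -> float:
    n = n_pd + n_hs
    if n == 0:
        return 0.0
    p = n_pd / n
    return 2 * p * (1 - p)


def fit_tree(
    cohort: CohortMatrix,
    items=None,
    max_depth: int = DEFAULT_MAX_DEPTH,
    min_leaf: int = DEFAULT_MIN_LEAF,
) -> TreeModel:
    """Greedy Gini CART on 0/1 items.

    Splits maximize impurity decrease; growth stops at node purity, the depth
    cap, or when a split would create a leaf below min_leaf.  Items already
    used on the path are not reused (a 0/1 item admits only one split).
    """
    if max_depth < 1 or min_leaf < 1:
        raise ValueError("max_depth and min_leaf must be ≥ 1")
    X, idx = _select_items(cohort, items)
    X = X.astype(int)
    y = cohort.y
    if X.shape[0] == 0:
        raise ValueError("empty cohort")

    def build(rows: np.ndarray, used: frozenset[int], depth: int) -> TreeNode:
        n_pd = int(y[rows].sum())
        n_hs = len(rows) - n_pd
        if n_pd == 0 or n_hs == 0 or depth >= max_depth:
            return TreeNode(n_pd=n_pd, n_hs=n_hs)
        parent_imp = _gini(n_pd, n_hs)
        best = None  # (gain, local_item_pos)
        for j in range(X.shape[1]):
            if j in used:
                continue
            right_mask = X[rows, j] == 1
            n_r = int(right_mask.sum())
            n_l = len(rows) - n_r
            if n_r < min_leaf or n_l < min_leaf:
                continue
            pd_r = int(y[rows[right_mask]].sum())
            pd_l = n_pd - pd_r
            child_imp = (n_l * _gini(pd_l, n_l - pd_l) + n_r * _gini(pd_r, n_r - pd_r)) / len(rows)
            gain = parent_imp - child_imp
            # strictly-better keeps the lowest item number on exact ties
            if gain > 1e-12 and (best is None or gain > best[0] + 1e-12):
                best = (gain, j)
        if best is None:
            return TreeNode(n_pd=n_pd, n_hs=n_hs)
        j = best[1]
        right_mask = X[rows, j] == 1
        return TreeNode(
            n_pd=n_pd, n_hs=n_hs, item=idx[j],
            left=build(rows[~right_mask], used | {j}, depth + 1),
            right=build(rows[right_mask], used | {j}, depth + 1),
        )

    root = build(np.arange(X.shape[0]), frozenset(), 0)
    return TreeModel(items=idx, root=root, max_depth=max_depth, min_leaf=min_leaf)


def predict_tree(model: TreeModel, cohort: CohortMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject leaf PD-fraction score and majority label (tie → PD)."""
    missing = [i for i in model.items if i >= cohort.n_items]
    if missing:
        raise ValueError(f"cohort lacks item indices {missing}")
    X = cohort.responses
    scores = np.empty(cohort.n_subjects)
    labels = np.empty(cohort.n_subjects, dtype=int)
    for s in range(cohort.n_subjects):
        node = model.root
        while not node.is_leaf:
            node = node.right if X[s, node.item] == 1 else node.left
        scores[s] = node.pd_fraction
        labels[s] = node.label
    return scores, labels


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass(frozen=True)
class CvResult:
    """Pooled out-of-fold predictions and the derived diagnostic report."""

    confusion: ConfusionMatrix
    report: DiagnosticReport
    auroc: float
    scores: np.ndarray        # per-subject out-of-fold continuous score
    predictions: np.ndarray   # per-subject out-of-fold 0/1 label
    fold_assignment: np.ndarray
    classifier: str
    n_folds: int
    seed: int
    items: tuple[int, ...] = field(default=())

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "items_1based": [i + 1 for i in self.items],
            "n_folds": self.n_folds,
            "seed": self.seed,
            "auroc": self.auroc,
            "fold_assignment": self.fold_assignment.tolist(),
            "report": self.report.to_dict(),
        }


def cross_validate(
    cohort: CohortMatrix,
    items=None,
    classifier: str = "plsda",
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
    **params,
) -> CvResult:
    """Stratified k-fold CV pooling every out-of-fold prediction.

    ``classifier`` is 'plsda' or 'tree'; ``params`` pass through to the fit
    (n_components / max_depth, min_leaf).
    """
    if classifier not in ("plsda", "tree"):
        raise ValueError(f"unknown classifier {classifier!r}")
    y = cohort.y
    smaller = min(cohort.n_pd, cohort.n_hs)
    if not 2 <= n_folds <= smaller:
        raise ValueError(f"n_folds={n_folds} must be in [2, {smaller}] (smaller class size)")
    _, idx = _select_items(cohort, items)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.full(cohort.n_subjects, np.nan)
    preds = np.full(cohort.n_subjects, -1, dtype=int)
    folds = np.full(cohort.n_subjects, -1, dtype=int)
    for f, (train, test) in enumerate(skf.split(cohort.responses, y)):
        sub = CohortMatrix(
            subject_ids=tuple(cohort.subject_ids[i] for i in train),
            labels=tuple(cohort.labels[i] for i in train),
            responses=cohort.responses[train],
            item_names=cohort.item_names,
        )
        held = CohortMatrix(
            subject_ids=tuple(cohort.subject_ids[i] for i in test),
            labels=tuple(cohort.labels[i] for i in test),
            responses=cohort.responses[test],
            item_names=cohort.item_names,
        )
        if classifier == "plsda":
            model = fit_plsda(sub, items=idx, **params)
            s, l = predict_plsda(model, held)
        else:
            model = fit_tree(sub, items=idx, **params)
            s, l = predict_tree(model, held)
        scores[test] = s
        preds[test] = l
        folds[test] = f
    assert not np.isnan(scores).any() and (preds >= 0).all()

    cm = ConfusionMatrix(
        tp=int(((preds == 1) & (y == 1)).sum()),
        fn=int(((preds == 0) & (y == 1)).sum()),
        fp=int(((preds == 1) & (y == 0)).sum()),
        tn=int(((preds == 0) & (y == 0)).sum()),
    )
    return CvResult(
        confusion=cm,
        report=metrics_from_confusion(cm),
        auroc=mann_whitney_auc(scores, y),
        scores=scores,
        predictions=preds,
        fold_assignment=folds,
        classifier=classifier,
        n_folds=n_folds,
        seed=seed,
        items=idx,
    )
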