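import numpy as np
import pytest

from conftest import make_two_class_cohort
from upsit_panel.cohort import CohortMatrix
from upsit_panel.classifiers import (
    cross_validate,
    fit_plsda,
    fit_tree,
    plsda_scores,
    predict_plsda,
    predict_tree,
)
from upsit_panel.metrics import metrics_from_confusion
from upsit_panel.simulate import default_spec, simulate_cohort


# ---------------------------------------------------------------------------
# PLS-DA


def test_plsda_first_component_weights_match_covariance_oracle(default_cohort):
    """First-component weights ∝ per-item covariance with the centered class
    indicator (direct computation as oracle)."""
    model = fit_plsda(default_cohort, n_components=2)
    X = default_cohort.responses.astype(float)
    y = default_cohort.y.astype(float)
    cov = (X - X.mean(0)).T @ (y - y.mean())
    expected = cov / np.linalg.norm(cov)
    w1 = model.x_weights[:, 0]
    np.testing.assert_allclose(w1 * np.sign(w1 @ expected), expected, atol=1e-10)
    assert np.linalg.norm(w1) == pytest.approx(1.0)


def test_plsda_predictions_match_sklearn_reconstruction(default_cohort):
    """Scores from the stored model pieces equal sklearn's own predict."""
    from sklearn.cross_decomposition import PLSRegression

    model = fit_plsda(default_cohort, n_components=2)
    pls = PLSRegression(n_components=2, scale=False)
    pls.fit(default_cohort.responses.astype(float), default_cohort.y.astype(float))
    np.testing.assert_allclose(
        plsda_scores(model, default_cohort),
        pls.predict(default_cohort.responses.astype(float)).ravel(),
        atol=1e-10,
    )


def test_plsda_weight_mass_on_discriminating_item():
    cohort = make_two_class_cohort([0.02, 0.5], [0.98, 0.5], 100, 100, seed=1)
    model = fit_plsda(cohort, n_components=1)
    w = np.abs(model.x_weights[:, 0])
    assert w[0] > 0.95 and w[1] < 0.3
    _, labels = predict_plsda(model, cohort)
    assert (labels == cohort.y).mean() >= 0.95


def test_plsda_full_rank_limit_equals_least_squares():
    """With n_comp = rank, PLS1 fitted values equal the OLS fit."""
    rng = np.random.default_rng(4)
    X = rng.integers(0, 2, (30, 3))
    y = np.array([1] * 15 + [0] * 15)
    cohort = CohortMatrix(tuple(f"s{i}" for i in range(30)),
                          ("PD",) * 15 + ("HS",) * 15, X)
    model = fit_plsda(cohort, n_components=3)
    Xc = np.column_stack([np.ones(30), X.astype(float)])
    beta, *_ = np.linalg.lstsq(Xc, y.astype(float), rcond=None)
    np.testing.assert_allclose(plsda_scores(model, cohort), Xc @ beta, atol=1e-8)


def test_plsda_invariant_to_cohort_duplication():
    cohort = make_two_class_cohort([0.2, 0.4, 0.6], [0.7, 0.6, 0.8], 40, 40, seed=5)
    model = fit_plsda(cohort, n_components=2)
    doubled = CohortMatrix(
        cohort.subject_ids + tuple(s + "_dup" for s in cohort.subject_ids),
        cohort.labels * 2,
        np.vstack([cohort.responses, cohort.responses]),
    )
    model2 = fit_plsda(doubled, n_components=2)
    np.testing.assert_allclose(
        plsda_scores(model, cohort), plsda_scores(model2, cohort), atol=1e-8
    )


def test_plsda_rank_guard():
    cohort = make_two_class_cohort([0.3, 0.3], [0.8, 0.8], 20, 20, seed=6)
    with pytest.raises(ValueError, match="rank"):
        fit_plsda(cohort, n_components=10)


# ---------------------------------------------------------------------------
# Decision tree


def test_tree_single_perfect_item():
    cohort = make_two_class_cohort([0.0, 0.5], [1.0, 0.5], 20, 20, seed=7)
    model = fit_tree(cohort)
    assert model.root.item == 0
    assert model.depth() == 1
    _, labels = predict_tree(model, cohort)
    assert (labels == cohort.y).all()


def test_tree_useless_items_single_leaf():
    rng = np.random.default_rng(8)
    X = np.tile(rng.integers(0, 2, (1, 3)), (20, 1))  # constant columns
    cohort = CohortMatrix(tuple(f"s{i}" for i in range(20)),
                          ("PD",) * 12 + ("HS",) * 8, X)
    model = fit_tree(cohort)
    assert model.root.is_leaf
    scores, labels = predict_tree(model, cohort)
    assert (labels == 1).all()  # majority class PD
    assert scores == pytest.approx(0.6)


def test_tree_leaf_tie_labels_pd():
    X = np.array([[0], [0], [1], [1]])
    cohort = CohortMatrix(("a", "b", "c", "d"), ("PD", "HS", "PD", "HS"), X)
    model = fit_tree(cohort, min_leaf=1)
    _, labels = predict_tree(model, cohort)
    assert (labels == 1).all()


def test_tree_manual_trace_three_nodes():
    """Hand-traced toy: split on item 0, then item 1 on the left branch."""
    X = np.array([
        [0, 0], [0, 0], [0, 1], [0, 1],   # PD PD HS HS
        [1, 0], [1, 0], [1, 1], [1, 1],   # HS HS HS HS
    ])
    labels = ("PD", "PD", "HS", "HS", "HS", "HS", "HS", "HS")
    cohort = CohortMatrix(tuple(f"s{i}" for i in range(8)), labels, X)
    model = fit_tree(cohort, min_leaf=1)
    assert model.root.item == 0 or model.root.item == 1
    scores, pred = predict_tree(model, cohort)
    assert (pred == cohort.y).all()
    # pure-PD leaf subjects score 1.0
    assert scores[0] == 1.0 and scores[1] == 1.0


def test_tree_dominant_item_is_root_across_replicates():
    """One dominant planted item becomes the root in ≥95% of 50 replicates."""
    hits = 0
    for r in range(50):
        p_pd = np.full(8, 0.45)
        p_hs = np.full(8, 0.6)
        p_pd[2], p_hs[2] = 0.15, 0.9
        cohort = make_two_class_cohort(p_pd, p_hs, 68, 61, seed=5000 + r)
        hits += fit_tree(cohort).root.item == 2
    assert hits / 50 >= 0.95


def test_tree_training_accuracy_nondecreasing_in_depth():
    cohort = simulate_cohort(default_spec(seed=19))
    prev = 0.0
    for depth in (1, 2, 4, 8, 12):
        model = fit_tree(cohort, max_depth=depth, min_leaf=2)
        _, pred = predict_tree(model, cohort)
        acc = (pred == cohort.y).mean()
        assert acc >= prev - 1e-12
        prev = acc


def test_tree_matches_sklearn_on_tie_free_cohort():
    """Same greedy Gini rules as sklearn's CART on a tie-free random cohort."""
    from sklearn.tree import DecisionTreeClassifier

    rng = np.random.default_rng(9)
    p_pd = rng.uniform(0.1, 0.6, 12)
    p_hs = rng.uniform(0.4, 0.9, 12)
    cohort = make_two_class_cohort(p_pd, p_hs, 150, 150, seed=10)
    ours = fit_tree(cohort, max_depth=4, min_leaf=5)
    _, pred = predict_tree(ours, cohort)
    sk = DecisionTreeClassifier(criterion="gini", max_depth=4,
                                min_samples_leaf=5, random_state=0)
    sk.fit(cohort.responses, cohort.y)
    assert (pred == sk.predict(cohort.responses)).mean() >= 0.99
    assert ours.root.item == int(sk.tree_.feature[0])


# ---------------------------------------------------------------------------
# Cross-validation


def test_cv_pooled_matrix_conserves_class_sizes(default_cohort):
    for clf in ("plsda", "tree"):
        cv = cross_validate(default_cohort, classifier=clf, seed=1)
        cm = cv.confusion
        assert cm.n_pd == default_cohort.n_pd and cm.n_hs == default_cohort.n_hs
        assert (cv.fold_assignment >= 0).all()
        assert len(np.unique(cv.fold_assignment)) == 10


def test_cv_deterministic_under_seed(default_cohort):
    a = cross_validate(default_cohort, classifier="plsda", seed=7)
    b = cross_validate(default_cohort, classifier="plsda", seed=7)
    assert a.confusion == b.confusion
    np.testing.assert_array_equal(a.scores, b.scores)
    c = cross_validate(default_cohort, classifier="plsda", seed=8)
    assert not np.array_equal(a.fold_assignment, c.fold_assignment)


def test_cv_report_recomputes_from_pooled_matrix(default_cohort):
    cv = cross_validate(default_cohort, classifier="tree", seed=3)
    fresh = metrics_from_confusion(cv.confusion)
    assert fresh.to_dict() == cv.report.to_dict()


def test_cv_fold_count_validation(default_cohort):
    with pytest.raises(ValueError, match="n_folds"):
        cross_validate(default_cohort, n_folds=62)
    with pytest.raises(ValueError, match="n_folds"):
        cross_validate(default_cohort, n_folds=1)
    with pytest.raises(ValueError, match="classifier"):
        cross_validate(default_cohort, classifier="svm")
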