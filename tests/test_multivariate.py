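import numpy as np
import pytest

from conftest import make_two_class_cohort
from upsit_panel.cohort import CohortMatrix, ContingencyTable
from upsit_panel.multivariate import (
    lda_direction,
    lda_ranking,
    logistic_ranking,
    regularized_pooled_covariance,
)
from upsit_panel.simulate import default_spec, simulate_cohort
from upsit_panel.univariate import diagnostic_odds_ratio


def test_logistic_planted_item_dominates():
    """One strongly discriminating item among noise gets the largest |beta|."""
    p_pd = np.full(10, 0.5)
    p_hs = np.full(10, 0.5)
    p_pd[3], p_hs[3] = 0.1, 0.9
    cohort = make_two_class_cohort(p_pd, p_hs, 200, 200, seed=2)
    ranking = logistic_ranking(cohort)
    assert ranking.order[0] == 3


def test_logistic_duplicated_column_symmetry():
    """Ridge splits the weight equally between two identical columns."""
    p_pd = np.array([0.2, 0.5, 0.5])
    p_hs = np.array([0.8, 0.5, 0.5])
    cohort = make_two_class_cohort(p_pd, p_hs, 150, 150, seed=3)
    resp = np.column_stack([cohort.responses, cohort.responses[:, 0]])
    dup = CohortMatrix(cohort.subject_ids, cohort.labels, resp)
    scores = logistic_ranking(dup).scores
    assert scores[0] == pytest.approx(scores[3], rel=1e-4)


def test_logistic_null_items_selected_at_chance_only():
    """With label-independent items no item enters the top-12 above chance."""
    n_items, n_reps, k = 40, 100, 12
    hits = np.zeros(n_items)
    for r in range(n_reps):
        cohort = make_two_class_cohort(
            np.full(n_items, 0.5), np.full(n_items, 0.5), 100, 100, seed=1000 + r
        )
        top = logistic_ranking(cohort).order[:k]
        hits[list(top)] += 1
    chance = k / n_items
    bound = chance + 3 * np.sqrt(chance * (1 - chance) / n_reps)
    assert (hits / n_reps).max() <= bound


def test_logistic_sign_and_monotone_step():
    """Single-item |beta|: positive effect iff DOR > 1, and moving one PD
    subject to incorrect never lowers |beta| when the item favors PD."""
    def beta(t: ContingencyTable) -> float:
        resp = np.concatenate([np.zeros(t.incorrect_pd), np.ones(t.correct_pd),
                               np.zeros(t.incorrect_hs), np.ones(t.correct_hs)])
        cohort = CohortMatrix(
            tuple(f"s{i}" for i in range(len(resp))),
            ("PD",) * t.n_pd + ("HS",) * t.n_hs,
            resp.reshape(-1, 1).astype(int),
        )
        from sklearn.linear_model import LogisticRegression
        # raw signed coefficient for the sign check
        m = LogisticRegression(C=1.0, solver="newton-cholesky", max_iter=500)
        m.fit(cohort.responses.astype(float), cohort.y)
        return float(m.coef_[0, 0])

    rng = np.random.default_rng(5)
    for _ in range(20):
        a, b, c, d = rng.integers(1, 20, size=4)
        t = ContingencyTable(int(a), int(b), int(c), int(d))
        bt = beta(t)
        dor = diagnostic_odds_ratio(t)
        if abs(np.log(dor)) > 0.2:  # away from the boundary, shrinkage keeps the sign
            assert (bt < 0) == (dor > 1)  # incorrect (0) response predicts PD
        if b > 1 and dor > 1.5:
            t2 = ContingencyTable(int(a + 1), int(b - 1), int(c), int(d))
            assert abs(beta(t2)) >= abs(bt) - 1e-6


def test_lda_only_discriminative_item_weighted():
    """Two independent items, equal variances, only item 1's means differ."""
    cohort = make_two_class_cohort([0.2, 0.5], [0.8, 0.5], 2000, 2000, seed=4)
    w = lda_direction(cohort)
    assert abs(w[0]) > 5 * abs(w[1])


def test_lda_direction_solves_regularized_system():
    cohort = simulate_cohort(default_spec(seed=6))
    for shrinkage in ("ledoit-wolf", 1e-3):
        sigma = regularized_pooled_covariance(cohort, shrinkage=shrinkage)
        w = lda_direction(cohort, shrinkage=shrinkage)
        mask = cohort.is_pd
        delta = (cohort.responses[mask].mean(axis=0)
                 - cohort.responses[~mask].mean(axis=0))
        np.testing.assert_allclose(sigma @ w, delta, atol=1e-10)


def test_lda_diagonal_closed_form():
    """With a fixed-ridge diagonal-dominant design, w ≈ Δμ scaled by the
    regularized variances (closed form for independent items)."""
    p_pd = np.array([0.3, 0.45, 0.55])
    p_hs = np.array([0.8, 0.65, 0.75])
    cohort = make_two_class_cohort(p_pd, p_hs, 2000, 2000, seed=8)
    w = lda_ranking(cohort, shrinkage=1e-6).scores
    mask = cohort.is_pd
    delta = np.abs(cohort.responses[mask].mean(0) - cohort.responses[~mask].mean(0))
    sigma = regularized_pooled_covariance(cohort, shrinkage=1e-6)
    expected = delta / np.diag(sigma)
    # off-diagonal sample covariance is O(1/sqrt(n)); allow 15% relative slack
    np.testing.assert_allclose(w, expected, rtol=0.15)


def test_rankings_invariant_to_subject_order():
    cohort = simulate_cohort(default_spec(seed=10))
    rng = np.random.default_rng(0)
    perm = rng.permutation(cohort.n_subjects)
    shuffled = CohortMatrix(
        tuple(cohort.subject_ids[i] for i in perm),
        tuple(cohort.labels[i] for i in perm),
        cohort.responses[perm],
        cohort.item_names,
    )
    for fn in (logistic_ranking, lda_ranking):
        a, b = fn(cohort), fn(shuffled)
        assert a.order == b.order
        np.testing.assert_allclose(a.scores, b.scores, rtol=1e-6)


def test_lda_planted_recovery_across_replicates():
    """All 8 planted items inside the LDA top-12 in ≥90% of 50 replicates."""
    hits = 0
    for r in range(50):
        spec = default_spec(n_pd=100, n_hs=100, seed=3000 + r)
        cohort = simulate_cohort(spec)
        top12 = set(lda_ranking(cohort).order[:12])
        hits += set(spec.planted_items) <= top12
    assert hits / 50 >= 0.9


def test_lda_requires_two_per_class():
    cohort = CohortMatrix(("a", "b", "c"), ("PD", "HS", "HS"),
                          np.array([[1, 0], [0, 1], [1, 1]]))
    with pytest.raises(ValueError, match="2 subjects"):
        lda_ranking(cohort)
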