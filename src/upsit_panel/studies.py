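"""Seeded replicate studies over synthetic cohorts.

These are the package's calibration/validation experiments: does the
five-method consensus recover the planted discriminative items, does the
selected panel beat the full battery under cross-validation (the
dimension-reduction advantage), and does the Youden cut-off land where the
generating probabilities say it should?  Each study runs the real pipeline on
independently seeded replicates and reports rates.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .classifiers import cross_validate
from .consensus import DEFAULT_K, DEFAULT_MIN_VOTES
from .cutoff import roc_over_cutoffs, sum_score, youden_cutoff
from .pipeline import compute_rankings, consensus_panel
from .simulate import PLANTED_P_HS, PLANTED_P_PD, default_spec, simulate_cohort


def _replicate_seeds(seed: int, n_reps: int) -> list[int]:
    # independent child streams; keep values < 2**31
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n_reps)]


def planted_recovery_study(
    n_reps: int = 50,
    n_pd: int = 100,
    n_hs: int = 100,
    k: int = DEFAULT_K,
    min_votes: int = DEFAULT_MIN_VOTES,
    seed: int = 0,
) -> dict:
    """Fraction of replicates whose consensus panel contains every planted item."""
    hits = 0
    panel_sizes = []
    for s in _replicate_seeds(seed, n_reps):
        spec = default_spec(n_pd=n_pd, n_hs=n_hs, seed=s)
        cohort = simulate_cohort(spec)
        rankings = compute_rankings(cohort)
        _, panel = consensus_panel(rankings, k=k, min_votes=min_votes)
        panel_sizes.append(len(panel.items))
        if set(spec.planted_items) <= set(panel.items):
            hits += 1
    return {
        "recovery_rate": hits / n_reps,
        "n_reps": n_reps,
        "n_pd": n_pd,
        "n_hs": n_hs,
        "mean_panel_size": float(np.mean(panel_sizes)),
    }


def panel_vs_battery_study(
    n_reps: int = 50,
    n_pd: int = 68,
    n_hs: int = 61,
    n_folds: int = 10,
    seed: int = 0,
) -> dict:
    """Per-classifier fraction of replicates where the consensus panel's
    pooled CV accuracy ≥ the 40-item battery's (same cohort, same folds)."""
    wins = {"plsda": 0, "tree": 0}
    acc_panel = {"plsda": [], "tree": []}
    acc_full = {"plsda": [], "tree": []}
    for s in _replicate_seeds(seed, n_reps):
        cohort = simulate_cohort(default_spec(n_pd=n_pd, n_hs=n_hs, seed=s))
        rankings = compute_rankings(cohort)
        _, panel = consensus_panel(rankings)
        for clf in ("plsda", "tree"):
            cv_p = cross_validate(cohort, items=panel, classifier=clf,
                                  n_folds=n_folds, seed=s)
            cv_f = cross_validate(cohort, items=None, classifier=clf,
                                  n_folds=n_folds, seed=s)
            acc_panel[clf].append(cv_p.report.accuracy)
            acc_full[clf].append(cv_f.report.accuracy)
            if cv_p.report.accuracy >= cv_f.report.accuracy:
                wins[clf] += 1
    return {
        "plsda_win_rate": wins["plsda"] / n_reps,
        "tree_win_rate": wins["tree"] / n_reps,
        "n_reps": n_reps,
        "mean_accuracy": {
            f"{clf}_{which}": float(np.mean(vals))
            for clf, d, which in (
                ("plsda", acc_panel, "panel"), ("plsda", acc_full, "full"),
                ("tree", acc_panel, "panel"), ("tree", acc_full, "full"),
            )
            for vals in [(acc_panel if which == "panel" else acc_full)[clf]]
        },
    }


def analytic_youden_optimum(n_planted: int = 8) -> int:
    """Closed-form Youden-optimal integer cut-off for the planted panel.

    The planted-panel sum score is Binomial(n_planted, p) per class, so
    J(t) = F_PD(t) − F_HS(t) is exact; the optimum is its argmax (lowest t
    on ties, matching the empirical tie rule).
    """
    ts = np.arange(-1, n_planted + 1)
    j = stats.binom.cdf(ts, n_planted, PLANTED_P_PD) - stats.binom.cdf(
        ts, n_planted, PLANTED_P_HS
    )
    return int(ts[int(np.argmax(j))])


def youden_stability_study(
    n_reps: int = 50, n_pd: int = 68, n_hs: int = 61, seed: int = 0
) -> dict:
    """How often the empirical Youden cut-off on the planted panel lands
    within ±1 of the analytic optimum."""
    t_star = analytic_youden_optimum()
    hits = 0
    chosen = []
    for s in _replicate_seeds(seed, n_reps):
        spec = default_spec(n_pd=n_pd, n_hs=n_hs, seed=s)
        cohort = simulate_cohort(spec)
        scores = sum_score(cohort, list(spec.planted_items))
        t, _ = youden_cutoff(roc_over_cutoffs(scores, cohort.y))
        chosen.append(t)
        if abs(t - t_star) <= 1:
            hits += 1
    return {
        "within_one_rate": hits / n_reps,
        "analytic_optimum": t_star,
        "n_reps": n_reps,
        "chosen_cutoffs": chosen,
    }
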