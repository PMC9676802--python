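"""Multivariate item rankings: logistic-regression and LDA weights.

Both models are fitted on all items jointly (PD coded 1, HS 0) and items are
ranked by the absolute value of their weight.  Items are left on the raw 0/1
scale — all predictors share it, so raw weights are directly comparable.

Forty binary predictors on ~130 subjects sit near separation, where
unregularized weights diverge and their ordering is noise; both fits are
therefore regularized with standard defaults:

* logistic: unit L2 penalty on the coefficients (sklearn's default C = 1.0,
  intercept unpenalized), exposed as the ``C`` knob;
* LDA: the discriminant direction w solves Σ_reg w = μ_PD − μ_HS with the
  pooled within-class covariance shrunk toward a scaled identity by the
  Ledoit–Wolf optimal intensity, Σ_reg = (1−α)Σ + α·(tr(Σ)/p)·I.  A fixed
  ridge fraction can be substituted via the ``shrinkage`` knob.
"""

from __future__ import annotations

import numpy as np
from sklearn.covariance import ledoit_wolf
from sklearn.linear_model import LogisticRegression

from .cohort import CohortMatrix
from .ranking import MethodRanking, order_from_scores

LOGISTIC_C = 1.0
LOGISTIC_MAX_ITER = 500
LOGISTIC_TOL = 1e-8


class ConvergenceError(RuntimeError):
    """Raised when the logistic fit does not converge within the iteration cap."""


def logistic_ranking(
    cohort: CohortMatrix,
    C: float = LOGISTIC_C,
    max_iter: int = LOGISTIC_MAX_ITER,
) -> MethodRanking:
    """Rank items by |β| of an L2-penalized logistic regression.

    C is the inverse penalty strength on the summed negative log-likelihood.
    """
    X = cohort.responses.astype(float)
    y = cohort.y
    model = LogisticRegression(
        C=C,
        solver="newton-cholesky",  # quadratic convergence; n >> p, L2 only
        max_iter=max_iter,
        tol=LOGISTIC_TOL,
    )
    model.fit(X, y)
    if int(np.max(model.n_iter_)) >= max_iter:
        raise ConvergenceError(f"logistic fit did not converge within {max_iter} iterations")
    scores = np.abs(model.coef_.ravel())
    return MethodRanking(
        method="logistic",
        scores=scores,
        order=order_from_scores(scores, ascending=False),
        direction="descending |beta|",
        notes=(f"L2 penalty, C = {C:g}",),
    )


def regularized_pooled_covariance(
    cohort: CohortMatrix, shrinkage: str | float = "ledoit-wolf"
) -> np.ndarray:
    """Pooled within-class covariance, regularized toward a scaled identity.

    ``shrinkage='ledoit-wolf'`` uses the Ledoit–Wolf optimal intensity on the
    class-centered data; a float gives a fixed ridge Σ + λI with
    λ = shrinkage · trace(Σ)/p.
    """
    X = cohort.responses.astype(float)
    mask = cohort.is_pd
    X_pd, X_hs = X[mask], X[~mask]
    if X_pd.shape[0] < 2 or X_hs.shape[0] < 2:
        raise ValueError("LDA needs at least 2 subjects per class")
    p = X.shape[1]
    centered = np.vstack([X_pd - X_pd.mean(axis=0), X_hs - X_hs.mean(axis=0)])
    if shrinkage == "ledoit-wolf":
        sigma, _ = ledoit_wolf(centered, assume_centered=True)
        return np.atleast_2d(sigma)
    n_pd, n_hs = X_pd.shape[0], X_hs.shape[0]
    sigma = np.atleast_2d(centered.T @ centered / (n_pd + n_hs - 2))
    lam = float(shrinkage) * np.trace(sigma) / p
    return sigma + lam * np.eye(p)


def lda_direction(
    cohort: CohortMatrix, shrinkage: str | float = "ledoit-wolf"
) -> np.ndarray:
    """Regularized Fisher discriminant direction: Σ_reg w = μ_PD − μ_HS."""
    X = cohort.responses.astype(float)
    mask = cohort.is_pd
    delta = X[mask].mean(axis=0) - X[~mask].mean(axis=0)
    sigma = regularized_pooled_covariance(cohort, shrinkage=shrinkage)
    return np.linalg.solve(sigma, delta)


def lda_ranking(
    cohort: CohortMatrix, shrinkage: str | float = "ledoit-wolf"
) -> MethodRanking:
    """Rank items by |w| of the shrinkage-regularized Fisher discriminant."""
    w = lda_direction(cohort, shrinkage=shrinkage)
    scores = np.abs(w)
    return MethodRanking(
        method="lda",
        scores=scores,
        order=order_from_scores(scores, ascending=False),
        direction="descending |w|",
        notes=(f"pooled-covariance shrinkage = {shrinkage}",),
    )
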