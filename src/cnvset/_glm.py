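"""Minimal binomial-logit fitting by iteratively reweighted least squares.

The enrichment statistic is a one-sided likelihood-ratio (deviance) test
between two nested logistic regressions fitted on the same rows.  The fitter
here is deliberately small and deterministic so that its behaviour in the
degenerate corners that matter for that test is fully specified:

* collinear columns are fitted by a least-squares IRLS step (minimum-norm),
  so a redundant covariate changes the deviance by exactly nothing;
* quasi-complete separation does not raise -- iterations stop at the cap and
  the deviance at the cap is reported (the deviance converges even when the
  coefficient diverges);
* convergence is declared when the score (gradient of the log-likelihood)
  is uniformly below ``tol``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.special import expit

MAX_ITER = 50
SCORE_TOL = 1e-8


@dataclass(frozen=True)
class IrlsFit:
    """Raw fit of a logistic regression on a fixed design matrix."""

    beta: np.ndarray
    deviance: float
    cov: np.ndarray          # inverse observed information (pseudo-inverse)
    converged: bool
    n_iter: int

    def se(self, j: int) -> float:
        return float(np.sqrt(max(self.cov[j, j], 0.0)))


def logistic_deviance(eta: np.ndarray, y: np.ndarray) -> float:
    """-2 log-likelihood of a Bernoulli-logit model at linear predictor eta."""
    return float(2.0 * np.sum(np.logaddexp(0.0, eta) - y * eta))


def irls_logistic(
    X: np.ndarray,
    y: np.ndarray,
    *,
    beta0: np.ndarray | None = None,
    max_iter: int = MAX_ITER,
    tol: float = SCORE_TOL,
    compute_cov: bool = True,
) -> IrlsFit:
    """Maximum-likelihood logistic fit of y (0/1) on design X.

    ``beta0`` warm-starts the iteration (used heavily by the permutation
    engine, where the nested model's solution is a good starting point for
    the extended model).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k) if beta0 is None else np.array(beta0, dtype=float)
    dev = logistic_deviance(X @ beta, y)
    converged = False
    n_iter = 0
    xtwx = np.eye(k)
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            n_iter -= 1
            break
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        xtwx = X.T @ (X * w[:, None])
        try:
            step = linalg.solve(xtwx, score, assume_a="pos")
        except linalg.LinAlgError:
            step = linalg.lstsq(xtwx, score)[0]
        if not np.all(np.isfinite(step)):
            step = linalg.lstsq(xtwx, score)[0]
        # step-halving keeps the deviance monotone even near separation
        new_dev = logistic_deviance(X @ (beta + step), y)
        n_halve = 0
        while new_dev > dev + 1e-10 and n_halve < 30:
            step *= 0.5
            new_dev = logistic_deviance(X @ (beta + step), y)
            n_halve += 1
        beta = beta + step
        dev = new_dev
    else:
        n_iter = max_iter
    # information at the final estimate, for Wald intervals
    if compute_cov:
        mu = expit(X @ beta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        xtwx = X.T @ (X * w[:, None])
        cov = linalg.pinvh(xtwx)
    else:
        cov = np.full((k, k), np.nan)
    return IrlsFit(beta=beta, deviance=dev, cov=cov, converged=converged, n_iter=n_iter)
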