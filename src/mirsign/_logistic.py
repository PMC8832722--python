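"""Maximum-likelihood logistic fitting with a ridge fallback for separated data.

Two-fold splits of strongly discriminative biomarker panels are frequently
linearly separable, where the unpenalized MLE diverges.  In that case the fit
is re-run with a tiny L2 penalty (lambda = 1e-6 by default, intercept
unpenalized) and the result is flagged so callers can record it in provenance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

DEFAULT_RIDGE = 1e-6

# |coefficient| beyond this is treated as evidence of (quasi-)separation
_COEF_DIVERGENCE = 1e3


@dataclass
class LogisticFit:
    intercept: float
    coefficients: np.ndarray
    stabilized: bool
    converged: bool

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coefficients


def _ridge_objective(w, X, y, lam):
    eta = w[0] + X @ w[1:]
    # log(1 + e^eta) computed stably
    nll = np.sum(np.logaddexp(0.0, eta)) - np.sum(y * eta)
    grad_eta = expit(eta) - y
    grad = np.empty_like(w)
    grad[0] = grad_eta.sum()
    grad[1:] = X.T @ grad_eta + 2.0 * lam * w[1:]
    return nll + lam * np.sum(w[1:] ** 2), grad


def _fit_ridge(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    w0 = np.zeros(X.shape[1] + 1)
    res = minimize(
        _ridge_objective,
        w0,
        args=(X, y, lam),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
    )
    return res.x


def fit_logistic(X, y, ridge: float = DEFAULT_RIDGE) -> LogisticFit:
    """Fit P(y=1|x) = logistic(b0 + x.b) by maximum likelihood.

    Parameters
    ----------
    X : array-like, shape (n, p)
    y : array-like of {0, 1}
    ridge : L2 penalty applied only when the plain MLE fails or diverges.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit a logistic model")

    import statsmodels.api as sm

    stabilized = False
    converged = False
    params = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(
                disp=0, maxiter=200, warn_convergence=False
            )
            params = np.asarray(res.params, dtype=float)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            params = None

    if (
        params is None
        or not converged
        or not np.all(np.isfinite(params))
        or np.max(np.abs(params)) > _COEF_DIVERGENCE
    ):
        params = _fit_ridge(X, y, ridge)
        stabilized = True
        converged = True

    return LogisticFit(
        intercept=float(params[0]),
        coefficients=np.asarray(params[1:], dtype=float),
        stabilized=stabilized,
        converged=converged,
    )
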