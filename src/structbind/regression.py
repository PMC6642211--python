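"""Nonlinear least-squares fits of the two structure-to-binder laws.

Two functional forms relate a transcript's structural content x to its
number of protein binders y:

* exponential, ``y = exp(alpha + beta * x)`` — used with double-stranded
  content where more structure means more binders (beta > 0);
* reciprocal, ``y = 1 / (alpha + beta * x)`` — used with chemical-reactivity
  scores where higher x means less structure, hence fewer binders.

Both are exposed as scikit-learn-compatible estimators (``fit`` /
``predict`` / ``get_params``) so they compose with sklearn model selection,
and as thin functional wrappers returning a :class:`FitResult`.

Fitting is plain unweighted least squares on the original y scale:
a linearised ordinary regression provides the initial point and damped
Gauss-Newton iterations refine it to a gradient norm below ``tol``.
A Poisson-likelihood variant of the exponential fit (a log-link GLM) is
available via ``loss="poisson"`` for count data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .errors import FitConvergenceError


@dataclass
class FitResult:
    """Fitted coefficients of one structure-to-binder law."""

    model: Literal["exponential", "reciprocal"]
    alpha: float
    beta: float
    rss: float
    n: int


def _as_xy(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    X, y = check_X_y(X, y, ensure_min_samples=3)
    if X.shape[1] != 1:
        raise ValueError("these laws are univariate; X must have one column")
    x = X[:, 0]
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    return x, np.asarray(y, dtype=float)


def _gauss_newton(x, y, predict, jacobian, theta0, tol, max_iter):
    """Damped Gauss-Newton on residuals y - predict(theta).

    Converges when the gradient norm falls below ``tol`` relative to the
    RSS scale, or when step halving can no longer improve the RSS.
    """
    theta = np.asarray(theta0, dtype=float)
    resid = y - predict(theta)
    rss = float(resid @ resid)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        J = jacobian(theta)
        grad = J.T @ resid
        if np.linalg.norm(grad) < tol * (1.0 + rss):
            break
        try:
            step = np.linalg.solve(J.T @ J, grad)
        except np.linalg.LinAlgError:
            raise FitConvergenceError(
                "singular normal equations", *theta, rss=rss, n_iter=n_iter
            )
        lam, improved = 1.0, False
        for _ in range(40):
            cand = theta + lam * step
            r_cand = y - predict(cand)
            rss_cand = float(r_cand @ r_cand)
            if np.isfinite(rss_cand) and rss_cand < rss:
                improved = True
                break
            lam *= 0.5
        if not improved:
            break  # numerical floor reached
        stalled = rss - rss_cand < 1e-13 * (1.0 + rss)
        theta, resid, rss = cand, r_cand, rss_cand
        if stalled:
            break
    else:
        raise FitConvergenceError(
            f"no convergence after {max_iter} iterations",
            alpha=theta[0], beta=theta[1], rss=rss, n_iter=max_iter,
        )
    return theta, rss, n_iter


class ExponentialRegression(RegressorMixin, BaseEstimator):
    """Least-squares fit of ``y = exp(alpha + beta * x)``.

    Parameters
    ----------
    loss : {"ls", "poisson"}
        "ls" minimises squared error on the y scale; "poisson" fits the
        equivalent log-link Poisson GLM (natural for binder counts).
    tol : float
        Gauss-Newton stopping threshold on the gradient norm.
    max_iter : int
        Iteration cap; exceeding it raises :class:`FitConvergenceError`
        carrying the last iterate.

    Attributes
    ----------
    alpha_, beta_ : float
        Fitted intercept and slope inside the exponential.
    rss_ : float
        Residual sum of squares at the solution (y scale).
    n_iter_ : int
        Gauss-Newton iterations used.
    """

    def __init__(self, loss: str = "ls", tol: float = 1e-8, max_iter: int = 200):
        self.loss = loss
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        x, y = _as_xy(X, y)
        if np.any(y < 0):
            raise ValueError("y must be non-negative for the exponential law")
        if self.loss == "poisson":
            import statsmodels.api as sm

            design = sm.add_constant(x)
            res = sm.GLM(y, design, family=sm.families.Poisson()).fit()
            theta = np.asarray(res.params, dtype=float)
            rss = float(np.sum((y - np.exp(theta[0] + theta[1] * x)) ** 2))
            self.n_iter_ = int(res.fit_history.get("iteration", 0)) or 1
        elif self.loss == "ls":
            # initialise from OLS of ln(y+1) on x
            A = np.column_stack([np.ones_like(x), x])
            theta0, *_ = np.linalg.lstsq(A, np.log(y + 1.0), rcond=None)
            predict = lambda t: np.exp(t[0] + t[1] * x)
            def jacobian(t):
                mu = np.exp(t[0] + t[1] * x)
                return np.column_stack([mu, x * mu])
            theta, rss, self.n_iter_ = _gauss_newton(
                x, y, predict, jacobian, theta0, self.tol, self.max_iter
            )
        else:
            raise ValueError(f"unknown loss {self.loss!r}")
        self.alpha_ = float(theta[0])
        self.beta_ = float(theta[1])
        self.rss_ = float(rss)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(np.asarray(X, dtype=float).reshape(-1, 1))
        return np.exp(self.alpha_ + self.beta_ * X[:, 0])

    def fit_result(self, X, y) -> FitResult:
        self.fit(X, y)
        return FitResult("exponential", self.alpha_, self.beta_, self.rss_,
                         len(np.asarray(y)))


class ReciprocalRegression(RegressorMixin, BaseEstimator):
    """Least-squares fit of ``y = 1 / (alpha + beta * x)``.

    The denominator must stay positive over the data range at the solution;
    a sign change raises :class:`FitConvergenceError` as a diagnostic.
    Attributes mirror :class:`ExponentialRegression`.
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 200):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        x, y = _as_xy(X, y)
        if np.any(y <= 0):
            raise ValueError("y must be positive for the reciprocal law")
        # initialise from OLS of 1/y on x
        A = np.column_stack([np.ones_like(x), x])
        theta0, *_ = np.linalg.lstsq(A, 1.0 / y, rcond=None)
        predict = lambda t: 1.0 / (t[0] + t[1] * x)
        def jacobian(t):
            d = t[0] + t[1] * x
            return np.column_stack([-1.0 / d**2, -x / d**2])
        theta, rss, self.n_iter_ = _gauss_newton(
            x, y, predict, jacobian, theta0, self.tol, self.max_iter
        )
        denom = theta[0] + theta[1] * x
        if np.any(denom <= 0):
            raise FitConvergenceError(
                "alpha + beta*x changes sign over the data range",
                alpha=float(theta[0]), beta=float(theta[1]),
                rss=float(rss), n_iter=self.n_iter_,
            )
        self.alpha_ = float(theta[0])
        self.beta_ = float(theta[1])
        self.rss_ = float(rss)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(np.asarray(X, dtype=float).reshape(-1, 1))
        return 1.0 / (self.alpha_ + self.beta_ * X[:, 0])

    def fit_result(self, X, y) -> FitResult:
        self.fit(X, y)
        return FitResult("reciprocal", self.alpha_, self.beta_, self.rss_,
                         len(np.asarray(y)))
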