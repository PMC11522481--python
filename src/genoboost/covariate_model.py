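"""Covariate-only logistic regression used to initialize and evaluate boosting.

The boosting predictor starts from F0 = F_cov, the linear predictor of a
logistic model of disease status on covariates alone, so genetic effects are
fit to the covariate-residualized phenotype.  Fitting is Newton-Raphson
(IRLS) with step-halving; covariates are variance-standardized internally
and coefficients reported back on the natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LogisticFit:
    """MLE of P(y=+1 | x) = 1 / (1 + exp(-(b0 + b'x)))."""

    intercept: float
    coefficients: np.ndarray  # natural (unstandardized) scale
    log_likelihood: float
    converged: bool
    n_iter: int = 0
    # standardization transform recorded at fit time
    center: np.ndarray = field(default_factory=lambda: np.empty(0))
    scale: np.ndarray = field(default_factory=lambda: np.empty(0))
    std_errors: np.ndarray | None = None  # natural scale, incl. intercept first

    @property
    def n_covariates(self) -> int:
        return len(self.coefficients)


def _design(X: np.ndarray) -> np.ndarray:
    return np.hstack([np.ones((X.shape[0], 1)), X])


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
    standardize: bool = True,
    offset: np.ndarray | None = None,
) -> LogisticFit:
    """Newton-Raphson logistic MLE with step-halving on likelihood decrease.

    Parameters
    ----------
    X : (n, c) covariate matrix; c may be zero (intercept-only model).
    y : labels in {+1, -1}.
    offset : fixed per-sample addition to the linear predictor (used when a
        previously fitted score enters the model with coefficient 1).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.size == 0:
        X = X.reshape(len(y), 0)
    y = np.asarray(y)
    n, c = X.shape
    if n < c + 1:
        raise ValueError(f"need at least {c + 1} samples for {c} covariates")
    t = (y == 1).astype(np.float64)  # 0/1 response
    if t.min() == t.max():
        raise ValueError("degenerate labels: only one class present")
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=np.float64)

    if standardize and c > 0:
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        Xs = (X - center) / scale
    else:
        center = np.zeros(c)
        scale = np.ones(c)
        Xs = X

    A = _design(Xs)
    beta = np.zeros(c + 1)
    beta[0] = _safe_logit(t.mean()) - off.mean()
    ll = _log_likelihood(A, beta, t, off)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = A @ beta + off
        p = _sigmoid(eta)
        w = np.clip(p * (1 - p), 1e-12, None)
        grad = A.T @ (t - p)
        H = (A * w[:, None]).T @ A
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving: guards against separation-driven divergence
        new_ll = _log_likelihood(A, beta + step, t, off)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step *= 0.5
            halvings += 1
            new_ll = _log_likelihood(A, beta + step, t, off)
        beta = beta + step
        if abs(new_ll - ll) <= tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll

    # Wald standard errors from observed information at the optimum
    eta = A @ beta + off
    p = _sigmoid(eta)
    w = np.clip(p * (1 - p), 1e-12, None)
    H = (A * w[:, None]).T @ A
    try:
        cov = np.linalg.inv(H)
        se_std = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_std = np.full(c + 1, np.nan)

    coef = beta[1:] / scale
    intercept = beta[0] - float(coef @ center)
    se = se_std.copy()
    se[1:] = se_std[1:] / scale
    return LogisticFit(
        intercept=float(intercept),
        coefficients=coef,
        log_likelihood=float(ll),
        converged=converged,
        n_iter=it,
        center=center,
        scale=scale,
        std_errors=se,
    )


def linear_predictor(fit: LogisticFit, X: np.ndarray) -> np.ndarray:
    """b0 + b'x per sample on the natural covariate scale."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.size == 0:
        X = X.reshape(X.shape[0] if X.ndim == 2 else 0, 0)
    if X.shape[1] != fit.n_covariates:
        raise ValueError(
            f"fit expects {fit.n_covariates} covariate columns, got {X.shape[1]}"
        )
    return fit.intercept + X @ fit.coefficients


def log_likelihood(fit: LogisticFit, X: np.ndarray, y: np.ndarray,
                   offset: np.ndarray | None = None) -> float:
    """Bernoulli log-likelihood of (X, y) under fixed fitted coefficients."""
    eta = linear_predictor(fit, X)
    if offset is not None:
        eta = eta + offset
    t = (np.asarray(y) == 1).astype(np.float64)
    return float(np.sum(t * eta - np.logaddexp(0.0, eta)))


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


def _safe_logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1 - p)))


def _log_likelihood(A: np.ndarray, beta: np.ndarray, t: np.ndarray,
                    off: np.ndarray) -> float:
    eta = A @ beta + off
    return float(np.sum(t * eta - np.logaddexp(0.0, eta)))
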