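"""Predictive-performance metrics for case-control polygenic scores.

The primary metric is the covariate-adjusted pseudo-R2 (Nagelkerke / Cragg-
Uhler form), computed from the likelihoods of a covariate-only logistic
model and a full model that adds the genotype-only PGS:

    R2 = (1 - (L_covars / L_full)^(2/n)) / (1 - L_covars^(2/n))

Both likelihoods are evaluated on the held-out set under coefficients fit
on a separate fitting (validation) set, so the PGS gets no credit for
coefficients tuned on the samples it is judged on.  Ratios of likelihoods
are handled in log space to avoid underflow at large n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .covariate_model import fit_logistic, log_likelihood


@dataclass
class EvalResult:
    pseudo_r2: float
    odds_ratio: dict[float, float] = field(default_factory=dict)
    auc: float = np.nan
    auprc: float = np.nan
    n: int = 0
    log_l_covars: float = np.nan
    log_l_full: float = np.nan


class UndefinedOddsRatioError(ValueError):
    """A contingency cell of the top-q% table is zero."""


def pseudo_r2(
    y: np.ndarray,
    pgs: np.ndarray,
    X_cov: np.ndarray | None = None,
    *,
    y_fitset: np.ndarray | None = None,
    pgs_fitset: np.ndarray | None = None,
    X_cov_fitset: np.ndarray | None = None,
    _return_parts: bool = False,
) -> float:
    """Covariate-adjusted Nagelkerke pseudo-R2 of a PGS on an evaluation set.

    Coefficients of the covariate-only and covariate+PGS logistic models are
    fit on the fitting set (``*_fitset``) and frozen; likelihoods are then
    evaluated on (y, pgs, X_cov).  When no fitting set is supplied the
    evaluation set doubles as the fitting set (toy usage; a warning is
    emitted since this overstates out-of-sample performance).
    """
    y = np.asarray(y)
    pgs = np.asarray(pgs, dtype=np.float64)
    n = len(y)
    X_cov = np.empty((n, 0)) if X_cov is None else np.atleast_2d(np.asarray(X_cov))
    if y_fitset is None:
        warnings.warn("no separate fitting set: coefficients fit on the evaluation set",
                      stacklevel=2)
        y_fitset, pgs_fitset, X_cov_fitset = y, pgs, X_cov
    pgs_fitset = np.asarray(pgs_fitset, dtype=np.float64)
    X_cov_fitset = np.empty((len(y_fitset), 0)) if X_cov_fitset is None else \
        np.atleast_2d(np.asarray(X_cov_fitset))

    fit_cov = fit_logistic(X_cov_fitset, y_fitset)
    full_design_fit = np.column_stack([X_cov_fitset, pgs_fitset])
    fit_full = fit_logistic(full_design_fit, y_fitset)

    ll_cov = log_likelihood(fit_cov, X_cov, y)
    ll_full = log_likelihood(fit_full, np.column_stack([X_cov, pgs]), y)
    if not (np.isfinite(ll_cov) and np.isfinite(ll_full)):
        raise ValueError("non-finite likelihood in pseudo-R2")
    if _return_parts:
        return pseudo_r2_from_log_likelihoods(ll_cov, ll_full, n), ll_cov, ll_full
    return pseudo_r2_from_log_likelihoods(ll_cov, ll_full, n)


def pseudo_r2_from_log_likelihoods(ll_covars: float, ll_full: float, n: int) -> float:
    """Nagelkerke R2 from log-likelihoods, stable at large n.

    (L_covars / L_full)^(2/n) = exp((2/n) (ll_covars - ll_full)).
    """
    ratio_term = np.exp((2.0 / n) * (ll_covars - ll_full))
    denom = 1.0 - np.exp((2.0 / n) * ll_covars)
    if denom <= 0.0:
        return 0.0  # covariate model already perfect
    return float((1.0 - ratio_term) / denom)


def odds_ratio_top(pgs: np.ndarray, y: np.ndarray, q: float = 0.01) -> float:
    """Odds ratio of case status, top ceil(q*n) of PGS vs the remainder.

    Samples are ranked by PGS descending with ties at the cut broken by
    stable input order.  A zero contingency cell raises
    :class:`UndefinedOddsRatioError` rather than returning infinity.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    pgs = np.asarray(pgs, dtype=np.float64)
    y = np.asarray(y)
    n = len(y)
    n_top = int(np.ceil(q * n))
    order = np.argsort(-pgs, kind="stable")
    top = np.zeros(n, dtype=bool)
    top[order[:n_top]] = True
    a = int(((y == 1) & top).sum())      # cases in top
    b = int(((y != 1) & top).sum())      # controls in top
    c = int(((y == 1) & ~top).sum())
    d = int(((y != 1) & ~top).sum())
    if min(a, b, c, d) == 0:
        raise UndefinedOddsRatioError(
            f"zero cell in top-{q:.0%} table: cases/controls top=({a},{b}) rest=({c},{d})"
        )
    return (a / b) / (c / d)


def auc(pgs: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_case > score_control) + 0.5 P(equal)."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("AUC needs both classes")
    return float(roc_auc_score((y == 1).astype(int), np.asarray(pgs)))


def auprc(pgs: np.ndarray, y: np.ndarray) -> float:
    """Non-interpolated average precision over the ranked list."""
    y = np.asarray(y)
    if (y == 1).sum() == 0:
        raise ValueError("AUPRC needs at least one case")
    return float(average_precision_score((y == 1).astype(int), np.asarray(pgs)))


def evaluate_model(
    y: np.ndarray,
    pgs: np.ndarray,
    X_cov: np.ndarray | None = None,
    *,
    y_fitset: np.ndarray | None = None,
    pgs_fitset: np.ndarray | None = None,
    X_cov_fitset: np.ndarray | None = None,
    or_quantiles: tuple[float, ...] = (0.01, 0.03, 0.05, 0.10),
) -> EvalResult:
    """All four metrics on one evaluation set; OR cells that are undefined
    are reported as NaN rather than aborting the whole evaluation."""
    r2, ll_cov, ll_full = pseudo_r2(y, pgs, X_cov, y_fitset=y_fitset,
                                    pgs_fitset=pgs_fitset,
                                    X_cov_fitset=X_cov_fitset, _return_parts=True)
    ors = {}
    for q in or_quantiles:
        try:
            ors[q] = odds_ratio_top(pgs, y, q)
        except UndefinedOddsRatioError:
            ors[q] = np.nan
    return EvalResult(pseudo_r2=r2, odds_ratio=ors, auc=auc(pgs, y),
                      auprc=auprc(pgs, y), n=len(y),
                      log_l_covars=ll_cov, log_l_full=ll_full)
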