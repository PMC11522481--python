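"""Mode-of-inheritance inference from genotype-score triplets and from GWAS.

A variant's cumulative score triplet (S0, S1, S2) — effects of zero, one
and two minor-allele copies — is summarized by the dominance position

    theta = (S1 - S0) / (S2 - S0)

theta = 0.5 is exact additivity; theta near 1 means one minor allele
already carries the full effect (dominant); theta near 0 means the effect
requires two copies (recessive); a heterozygote score outside the range of
both homozygote scores is over-dominant (above both) or over-recessive
(below both).  The classification is invariant to adding a constant to all
three scores and to positive rescaling, and reversing the triplet (an
allele flip) swaps dominant and recessive while fixing the other labels.

The band half-widths (tau_add, tau_over) are configuration, not biological
constants: they instantiate "deviation from additivity" at a chosen
granularity.

An independent comparator fits one logistic regression per genotype coding
(additive, dominant, recessive, heterozygote-only) and labels the variant
by the coding with the most significant Wald test, the classical GWAS way
of probing non-additive effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .covariate_model import fit_logistic
from .geno_io import MISSING

MODE_LABELS = ("additive", "dominant", "recessive", "overdominant",
               "overrecessive", "null")
CODINGS = ("additive", "dominant", "recessive", "hetonly")

DEFAULT_TAU_ADD = 0.125
DEFAULT_TAU_OVER = 0.25
DEFAULT_ZERO_TOL = 1e-8


@dataclass(frozen=True)
class TripletGeometry:
    S: tuple[float, float, float]
    span: float            # S2 - S0, signed
    theta: float           # dominance position, NaN when span ~ 0
    label: str


def classify_mode(S, tau_add: float = DEFAULT_TAU_ADD,
                  tau_over: float = DEFAULT_TAU_OVER,
                  zero_tol: float = DEFAULT_ZERO_TOL) -> str:
    """Label one (S0, S1, S2) triplet with its mode of inheritance."""
    return triplet_geometry(S, tau_add, tau_over, zero_tol).label


def triplet_geometry(S, tau_add: float = DEFAULT_TAU_ADD,
                     tau_over: float = DEFAULT_TAU_OVER,
                     zero_tol: float = DEFAULT_ZERO_TOL) -> TripletGeometry:
    S0, S1, S2 = (float(v) for v in S)
    span = S2 - S0
    spread = max(abs(S1 - S0), abs(S2 - S1), abs(span))
    if spread <= zero_tol:
        return TripletGeometry((S0, S1, S2), span, np.nan, "null")
    if abs(span) <= zero_tol:  # homozygotes tie, heterozygote deviates
        label = "overdominant" if S1 > S0 else "overrecessive"
        return TripletGeometry((S0, S1, S2), span, np.nan, label)
    theta = (S1 - S0) / span
    if abs(theta - 0.5) <= tau_add:
        label = "additive"
    elif 0.5 + tau_add < theta <= 1.0 + tau_over:
        label = "dominant"
    elif -tau_over <= theta < 0.5 - tau_add:
        label = "recessive"
    else:
        # heterozygote beyond both homozygotes: direction decides over-mode
        label = "overdominant" if S1 > max(S0, S2) else "overrecessive"
    return TripletGeometry((S0, S1, S2), span, theta, label)


def code_genotype(g, coding: str):
    """Recode dosage under one inheritance coding; missing propagates."""
    g_arr = np.atleast_1d(np.asarray(g, dtype=np.float64))
    miss = (g_arr == MISSING) | np.isnan(g_arr)
    if coding == "additive":
        out = g_arr.copy()
    elif coding == "dominant":
        out = (g_arr >= 1).astype(np.float64)
    elif coding == "recessive":
        out = (g_arr == 2).astype(np.float64)
    elif coding == "hetonly":
        out = (g_arr == 1).astype(np.float64)
    else:
        raise ValueError(f"unknown coding {coding!r}")
    out[miss] = np.nan
    if np.isscalar(g):
        return float(out[0])
    return out


def gwas_mode_infer(column: np.ndarray, y: np.ndarray,
                    covariates: np.ndarray | None = None,
                    alpha: float = 0.05):
    """Label a variant by its most significant per-coding logistic Wald test.

    Returns ``(label, p_values, significant)``: the coding with minimal
    two-sided Wald p mapped to a mode label (hetonly maps to over-dominant
    for a risk-increasing heterozygote coefficient, over-recessive
    otherwise), the per-coding p-value dict, and whether the winning p
    clears ``alpha``.
    """
    column = np.asarray(column)
    y = np.asarray(y)
    n = len(y)
    cov = np.empty((n, 0)) if covariates is None else np.atleast_2d(np.asarray(covariates))
    pvals: dict[str, float] = {}
    betas: dict[str, float] = {}
    for coding in CODINGS:
        x = code_genotype(column, coding)
        keep = ~np.isnan(x)
        X = np.column_stack([x[keep], cov[keep]])
        try:
            fit = fit_logistic(X, y[keep])
        except Exception as e:  # noqa: BLE001 - one coding failing is tolerable
            warnings.warn(f"coding {coding!r} dropped: {e}", stacklevel=2)
            continue
        se = fit.std_errors[1] if fit.std_errors is not None else np.nan
        beta = fit.coefficients[0]
        if not np.isfinite(se) or se <= 0:
            warnings.warn(f"coding {coding!r} dropped: unstable Wald SE", stacklevel=2)
            continue
        zstat = beta / se
        pvals[coding] = float(2.0 * stats.norm.sf(abs(zstat)))
        betas[coding] = float(beta)
    if not pvals:
        raise RuntimeError("all genotype codings failed to fit")
    best = min(pvals, key=lambda c: (pvals[c], CODINGS.index(c)))
    if best == "hetonly":
        label = "overdominant" if betas[best] > 0 else "overrecessive"
    else:
        label = best
    return label, pvals, bool(pvals[best] < alpha)


def coarse_label(label: str) -> str:
    """Collapse over-modes for 3-class (additive/dominant/recessive) comparison."""
    return {"overdominant": "dominant", "overrecessive": "recessive"}.get(label, label)


def mode_concordance(labels_a, labels_b, classes=MODE_LABELS):
    """Confusion matrix (rows = first labeling) and diagonal agreement."""
    labels_a = list(labels_a)
    labels_b = list(labels_b)
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors differ in length")
    index = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for a, b in zip(labels_a, labels_b):
        M[index[a], index[b]] += 1
    total = M.sum()
    agreement = float(np.trace(M) / total) if total else np.nan
    return M, agreement
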