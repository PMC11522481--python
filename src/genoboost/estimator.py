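"""Scikit-learn-style estimator wrapping the boosting core.

``GenoBoostClassifier`` follows the sklearn estimator contract (get_params /
set_params, fitted attributes with a trailing underscore, ``fit`` /
``decision_function`` / ``predict_proba``) so the model composes with
sklearn pipelines and model selection.  The dosage matrix is the feature
matrix X (NaN or -1 marks a missing genotype); covariates enter through the
``covariates`` fit parameter and initialize the boosting predictor.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .boost_core import (
    GenoBoostModel,
    HyperParams,
    boost_fit,
    predict_genetic_score,
)
from .covariate_model import linear_predictor
from .geno_io import MISSING, GenotypeMatrix, PhenotypeTable, VariantMeta


def _as_genotype_matrix(X) -> GenotypeMatrix:
    if isinstance(X, GenotypeMatrix):
        return X
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x variants)")
    dosages = np.where(np.isnan(X), MISSING, X).astype(np.int8)
    n, d = dosages.shape
    variants = [
        VariantMeta(id=f"v{j}", chrom="1", pos=j + 1, allele_ref="A", allele_alt="G")
        for j in range(d)
    ]
    samples = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(dosages, variants, samples)


class GenoBoostClassifier(BaseEstimator, ClassifierMixin):
    """Sparse polygenic-score classifier with per-genotype scores.

    Parameters
    ----------
    mode : {'additive', 'nonadditive'}
        Whether the three genotype scores are constrained to a line
        (additive) or free (non-additive, capturing genetic dominance).
    learning_rate : float in (0, 1]
        Shrinkage gamma applied to each selected weak learner.
    n_iter : int
        Number of boosting iterations T.
    s2_clip : float or None
        Maximum |s2 - s0|: regularizes the homozygous-minor score, whose raw
        estimate has high variance when minor homozygotes are rare.
    m_batch : int
        Batch size for screening on very wide variant panels; a full scan of
        all variants is used whenever the panel has <= 10,000 variants.
    z_max, w_floor : float
        Working-response clip and weight floor (LogitBoost stabilization).

    Attributes
    ----------
    model_ : GenoBoostModel
        Covariate fit plus the ordered list of shrunken weak learners.
    triplets_ : dict[int, ndarray]
        Cumulative (S0, S1, S2) score triplet per selected variant column.
    selected_ : ndarray of int
        Sorted indices of selected variant columns.
    classes_ : ndarray
        Class labels, always [-1, 1].
    """

    def __init__(self, mode: str = "nonadditive", learning_rate: float = 0.1,
                 n_iter: int = 100, s2_clip: float | None = None,
                 m_batch: int = 50, z_max: float = np.inf, w_floor: float = 1e-10):
        self.mode = mode
        self.learning_rate = learning_rate
        self.n_iter = n_iter
        self.s2_clip = s2_clip
        self.m_batch = m_batch
        self.z_max = z_max
        self.w_floor = w_floor

    def fit(self, X, y, covariates=None):
        G = _as_genotype_matrix(X)
        y = np.asarray(y)
        y = np.where(y > 0, 1, -1)
        cov = np.empty((G.n_samples, 0)) if covariates is None else \
            np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        pheno = PhenotypeTable(list(G.samples), y, cov)
        hp = HyperParams(gamma=self.learning_rate, T=self.n_iter,
                         m_batch=self.m_batch, s2_clip=self.s2_clip,
                         z_max=self.z_max, w_floor=self.w_floor)
        self.model_ = boost_fit(G, pheno, hp, model_kind=self.mode)
        self.triplets_ = self.model_.collapse()
        self.selected_ = np.array(sorted(self.triplets_), dtype=int)
        self.classes_ = np.array([-1, 1])
        self.n_features_in_ = G.n_variants
        return self

    def decision_function(self, X, covariates=None):
        """Full linear predictor: covariate term plus genotype-only PGS."""
        check_is_fitted(self, "model_")
        score = self.genetic_score(X)
        if covariates is not None:
            score = score + linear_predictor(self.model_.covariate_fit,
                                             np.atleast_2d(np.asarray(covariates)))
        else:
            score = score + self.model_.covariate_fit.intercept
        return score

    def genetic_score(self, X) -> np.ndarray:
        """Genotype-only PGS (no covariate contribution)."""
        check_is_fitted(self, "model_")
        return predict_genetic_score(self.model_, _as_genotype_matrix(X))

    def predict_proba(self, X, covariates=None):
        eta = self.decision_function(X, covariates)
        p = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1 - p, p])

    def predict(self, X, covariates=None):
        return np.where(self.decision_function(X, covariates) >= 0, 1, -1)

    def truncated(self, T: int) -> "GenoBoostClassifier":
        """Fitted clone holding only the first T weak learners."""
        check_is_fitted(self, "model_")
        clone = GenoBoostClassifier(**self.get_params())
        clone.n_iter = T
        clone.model_ = self.model_.truncated(T)
        clone.triplets_ = clone.model_.collapse()
        clone.selected_ = np.array(sorted(clone.triplets_), dtype=int)
        clone.classes_ = self.classes_
        clone.n_features_in_ = self.n_features_in_
        return clone
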