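"""The GenoBoost fitting loop.

GenoBoost is a LogitBoost-style procedure over individual-level genotypes:
each iteration converts the current additive predictor F into per-sample
working responses z and weights w (the Newton-step quantities of logistic
loss), summarizes every variant by per-genotype-class sufficient statistics
(W_k, U_k, Q_k), solves the weighted least-squares problem for that
variant's genotype-dependent scores in closed form, selects the variant with
the smallest weighted residual loss, shrinks its scores by the learning rate
and adds them to F.

Two score models are supported.  The additive model constrains the three
genotype scores to lie on a line, f(g) = c + alpha * g, with (c, alpha) the
exact weighted-least-squares minimizer:

    c     = ((W1 + 4 W2) U0 + 2 W2 U1 - W1 U2) / D
    alpha = ((-W1 - 2 W2) U0 + (W0 - W2) U1 + (2 W0 + W1) U2) / D
    D     = W0 W1 + W1 W2 + 4 W2 W0

The non-additive model frees the heterozygote, s_k = U_k / W_k (the
w-weighted mean of z within genotype class k), which captures genetic
dominance; the homozygous-minor score s2 may be clamped toward the baseline
s0 to control its variance at rare homozygote counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .covariate_model import LogisticFit, fit_logistic, linear_predictor
from .geno_io import MISSING, GenotypeMatrix, PhenotypeTable

ModelKind = Literal["additive", "nonadditive"]

FULL_SCAN_MAX_VARIANTS = 10_000  # batch screening only engages above this


@dataclass
class SampleState:
    """Per-sample Newton-step quantities at one boosting iteration."""

    F: np.ndarray
    p: np.ndarray
    z: np.ndarray
    w: np.ndarray


@dataclass
class SufficientStats:
    """Per-genotype-class weighted sums for one variant at one iteration.

    W[k] = sum of w over samples with genotype k, U[k] the matching sum of
    w*z, Q[k] of w*z^2 (needed for the loss), n[k] the class counts.
    Missing genotypes contribute to no class.
    """

    W: np.ndarray
    U: np.ndarray
    Q: np.ndarray = field(default_factory=lambda: np.zeros(3))
    n: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=np.int64))


@dataclass
class WeakLearner:
    """One selected variant with its genotype scores before shrinkage."""

    variant_index: int
    mode: ModelKind
    scores: tuple[float, float, float]
    c: float | None = None
    alpha: float | None = None
    loss: float = np.nan


@dataclass
class HyperParams:
    gamma: float = 0.1
    T: int = 100
    m_batch: int = 50
    s2_clip: float | None = None
    z_max: float = np.inf
    w_floor: float = 1e-10

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("learning rate gamma must be in (0, 1]")
        if self.T < 0 or self.m_batch < 1:
            raise ValueError("T must be >= 0 and m_batch >= 1")


@dataclass
class GenoBoostModel:
    """Ordered weak learners on top of a covariate-only logistic fit."""

    covariate_fit: LogisticFit
    learners: list[tuple[WeakLearner, float]]
    model_kind: ModelKind
    variant_ids: list[str] = field(default_factory=list)
    variant_meta: list = field(default_factory=list)

    def truncated(self, T: int) -> "GenoBoostModel":
        """Model as it stood after the first T iterations (prefix property)."""
        if T > len(self.learners):
            raise ValueError(f"cannot truncate to T={T}: only {len(self.learners)} learners")
        return GenoBoostModel(
            self.covariate_fit, self.learners[:T], self.model_kind,
            self.variant_ids, self.variant_meta,
        )

    def collapse(self) -> dict[int, np.ndarray]:
        """Sum shrunken scores per variant into cumulative triplets (S0,S1,S2)."""
        triplets: dict[int, np.ndarray] = {}
        for learner, gamma in self.learners:
            trip = triplets.setdefault(learner.variant_index, np.zeros(3))
            trip += gamma * np.asarray(learner.scores)
        return triplets

    @property
    def selected_indices(self) -> list[int]:
        return sorted(self.collapse().keys())

    def n_selected(self) -> int:
        return len(self.collapse())


def compute_sample_state(F: np.ndarray, y: np.ndarray, z_max: float = np.inf,
                         w_floor: float = 1e-10) -> SampleState:
    """Working responses and weights of the logistic loss at predictor F.

    p = sigmoid(F); z = 1/p for cases and -1/(1-p) for controls, clipped to
    |z| <= z_max; w = p(1-p), floored at w_floor.  Unclipped (the default),
    w*z = y* - p exactly, making each per-class score a damped Newton step
    on the logistic loss; a finite z_max caps the response of poorly fit
    samples at the cost of that exact-Newton property.
    """
    F = np.asarray(F, dtype=np.float64)
    if not np.isfinite(F).all():
        raise ValueError("non-finite predictor values")
    y = np.asarray(y)
    p = 1.0 / (1.0 + np.exp(-F))
    p_eff = np.clip(p, 1e-8, 1.0 - 1e-8)  # keeps w*z bounded near separation
    z = np.where(y == 1, 1.0 / p_eff, -1.0 / (1.0 - p_eff))
    z = np.clip(z, -z_max, z_max)
    w = np.maximum(p_eff * (1.0 - p_eff), w_floor)
    return SampleState(F=F, p=p, z=z, w=w)


def accumulate_stats(column: np.ndarray, state: SampleState) -> SufficientStats:
    """Sufficient statistics of one dosage column under the current state."""
    col = np.asarray(column)
    W = np.zeros(3)
    U = np.zeros(3)
    Q = np.zeros(3)
    n = np.zeros(3, dtype=np.int64)
    wz = state.w * state.z
    wzz = wz * state.z
    for k in range(3):
        sel = col == k
        W[k] = state.w[sel].sum()
        U[k] = wz[sel].sum()
        Q[k] = wzz[sel].sum()
        n[k] = sel.sum()
    return SufficientStats(W=W, U=U, Q=Q, n=n)


def solve_additive(stats: SufficientStats) -> tuple[float, float]:
    """Closed-form weighted-least-squares line through the class means.

    Returns (c, alpha) minimizing sum_i w_i (c + alpha * g_i - z_i)^2.
    Raises for degenerate variants (at most one populated genotype class).
    """
    W0, W1, W2 = stats.W
    U0, U1, U2 = stats.U
    denom = W0 * W1 + W1 * W2 + 4.0 * W2 * W0
    if denom <= 0.0:
        raise DegenerateVariantError("additive solve needs >= 2 populated genotype classes")
    c = ((W1 + 4.0 * W2) * U0 + 2.0 * W2 * U1 - W1 * U2) / denom
    alpha = ((-W1 - 2.0 * W2) * U0 + (W0 - W2) * U1 + (2.0 * W0 + W1) * U2) / denom
    return float(c), float(alpha)


def solve_nonadditive(stats: SufficientStats,
                      s2_clip: float | None = None) -> tuple[float, float, float]:
    """Per-class weighted means s_k = U_k / W_k, with optional s2 clamping.

    Empty classes get imputed scores that leave the loss unchanged: an empty
    homozygote class takes the heterozygote score and an empty heterozygote
    class the midpoint of the homozygote scores.  If ``s2_clip`` is set, s2
    is clamped so |s2 - s0| <= s2_clip (relative to the homozygous-major
    baseline).
    """
    W = stats.W
    U = stats.U
    s = np.zeros(3)
    populated = W > 0
    s[populated] = U[populated] / W[populated]
    if not populated.any():
        return (0.0, 0.0, 0.0)
    if not populated[1]:
        if populated[0] and populated[2]:
            s[1] = 0.5 * (s[0] + s[2])
        else:
            s[1] = s[0] if populated[0] else s[2]
    if not populated[0]:
        s[0] = s[1]
    if not populated[2]:
        s[2] = s[1]
    if s2_clip is not None:
        lo, hi = s[0] - s2_clip, s[0] + s2_clip
        s[2] = min(max(s[2], lo), hi)
    return (float(s[0]), float(s[1]), float(s[2]))


def learner_loss(stats: SufficientStats, scores: Sequence[float]) -> float:
    """Weighted residual loss sum_i w_i (f(g_i) - z_i)^2 from class sums."""
    f = np.asarray(scores, dtype=np.float64)
    return float(np.sum(stats.Q - 2.0 * f * stats.U + f**2 * stats.W))


class DegenerateVariantError(ValueError):
    pass


class NoSelectableVariantError(RuntimeError):
    pass


def select_variant(losses: np.ndarray) -> int:
    """Argmin of the loss vector; ties and NaNs resolved to the smallest index."""
    losses = np.asarray(losses, dtype=np.float64)
    finite = np.isfinite(losses)
    if not finite.any():
        raise NoSelectableVariantError("every screened variant is degenerate")
    masked = np.where(finite, losses, np.inf)
    return int(np.argmin(masked))


# ---------------------------------------------------------------------------
# Vectorized screening machinery
# ---------------------------------------------------------------------------

class _VariantScreen:
    """Precomputed genotype-class indicators for fast per-iteration scans."""

    def __init__(self, dosages: np.ndarray):
        self.n, self.d = dosages.shape
        # boolean n x d indicator per genotype class; missing in none
        self.masks = [(dosages == k) for k in range(3)]
        self.n_classes = sum(m.sum(axis=0) > 0 for m in self.masks)

    def stats(self, state: SampleState, cols: np.ndarray | None = None):
        """W, U, Q arrays of shape (3, d') for the requested columns."""
        w, wz = state.w, state.w * state.z
        wzz = wz * state.z
        W = np.empty((3, self.d if cols is None else len(cols)))
        U = np.empty_like(W)
        Q = np.empty_like(W)
        for k in range(3):
            m = self.masks[k] if cols is None else self.masks[k][:, cols]
            W[k] = w @ m
            U[k] = wz @ m
            Q[k] = wzz @ m
        return W, U, Q


def _solve_additive_vec(W, U):
    denom = W[0] * W[1] + W[1] * W[2] + 4.0 * W[2] * W[0]
    ok = denom > 0
    safe = np.where(ok, denom, 1.0)
    c = ((W[1] + 4 * W[2]) * U[0] + 2 * W[2] * U[1] - W[1] * U[2]) / safe
    alpha = ((-W[1] - 2 * W[2]) * U[0] + (W[0] - W[2]) * U[1]
             + (2 * W[0] + W[1]) * U[2]) / safe
    scores = np.stack([c, c + alpha, c + 2 * alpha])
    return scores, c, alpha, ok


def _solve_nonadditive_vec(W, U, s2_clip):
    populated = W > 0
    safe = np.where(populated, W, 1.0)
    s = np.where(populated, U / safe, np.nan)
    # empty-class imputation (loss-neutral): hom <- het, het <- midpoint
    het_fill = np.where(
        populated[0] & populated[2], 0.5 * (s[0] + s[2]),
        np.where(populated[0], s[0], s[2]),
    )
    s1 = np.where(populated[1], s[1], het_fill)
    s0 = np.where(populated[0], s[0], s1)
    s2 = np.where(populated[2], s[2], s1)
    if s2_clip is not None:
        s2 = np.clip(s2, s0 - s2_clip, s0 + s2_clip)
    scores = np.stack([s0, s1, s2])
    ok = populated.sum(axis=0) >= 2
    scores = np.where(np.isfinite(scores), scores, 0.0)
    return scores, ok


def _losses(W, U, Q, scores):
    return np.sum(Q - 2.0 * scores * U + scores**2 * W, axis=0)


# ---------------------------------------------------------------------------
# The fitting loop
# ---------------------------------------------------------------------------

def boost_fit(
    G: GenotypeMatrix,
    pheno: PhenotypeTable,
    hp: HyperParams,
    model_kind: ModelKind = "nonadditive",
    trace_callback=None,
) -> GenoBoostModel:
    """Run T boosting iterations and return the fitted model.

    F0 is the covariate-only logistic linear predictor; each iteration scans
    variants (all of them, or the retained batch for very wide panels),
    fits per-variant scores under ``model_kind``, picks the loss-minimizing
    variant and updates F <- F + gamma * f.  The same variant may be picked
    repeatedly; its shrunken contributions accumulate.
    """
    if G.samples != pheno.sample_ids:
        pheno = pheno.align(G.samples)
    y = pheno.y
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present for boosting")

    cov_fit = fit_logistic(pheno.covariates, y)
    F = linear_predictor(cov_fit, pheno.covariates)
    screen = _VariantScreen(G.dosages)
    use_batch = G.n_variants > FULL_SCAN_MAX_VARIANTS and hp.m_batch < G.n_variants

    learners: list[tuple[WeakLearner, float]] = []
    batch_cols: np.ndarray | None = None
    for t in range(hp.T):
        state = compute_sample_state(F, y, hp.z_max, hp.w_floor)
        if use_batch and t % hp.m_batch != 0 and batch_cols is not None:
            cols = batch_cols
        else:
            cols = None  # full scan
        W, U, Q = screen.stats(state, cols)
        if model_kind == "additive":
            scores, c_vec, alpha_vec, ok = _solve_additive_vec(W, U)
        else:
            scores, ok = _solve_nonadditive_vec(W, U, hp.s2_clip)
        losses = np.where(ok, _losses(W, U, Q, scores), np.inf)
        local = select_variant(losses)
        j = int(local if cols is None else cols[local])
        if use_batch and cols is None:
            order = np.argsort(losses, kind="stable")
            batch_cols = np.sort(order[: hp.m_batch])

        triple = tuple(float(v) for v in scores[:, local])
        learner = WeakLearner(
            variant_index=j,
            mode=model_kind,
            scores=triple,
            c=float(c_vec[local]) if model_kind == "additive" else None,
            alpha=float(alpha_vec[local]) if model_kind == "additive" else None,
            loss=float(losses[local]),
        )
        learners.append((learner, hp.gamma))

        col = G.dosages[:, j]
        f = np.zeros(G.n_samples)
        for k in range(3):
            f[col == k] = triple[k]  # missing genotype contributes 0
        F = F + hp.gamma * f
        if trace_callback is not None:
            trace_callback(t, learner, F)

    return GenoBoostModel(
        covariate_fit=cov_fit,
        learners=learners,
        model_kind=model_kind,
        variant_ids=G.variant_ids(),
        variant_meta=list(G.variants),
    )


def predict_genetic_score(model: GenoBoostModel, G: GenotypeMatrix) -> np.ndarray:
    """Genotype-only PGS: per sample, sum of collapsed triplet scores.

    Model variants are matched to G by variant ID; a variant stored with the
    opposite allele orientation is flipped before lookup.  Missing genotypes
    contribute zero.
    """
    triplets = model.collapse()
    if not triplets:
        return np.zeros(G.n_samples)
    pos = {v.id: j for j, v in enumerate(G.variants)}
    scores = np.zeros(G.n_samples)
    missing_ids = []
    for idx, trip in triplets.items():
        vid = model.variant_ids[idx] if model.variant_ids else None
        meta = model.variant_meta[idx] if model.variant_meta else None
        if vid is not None and vid in pos:
            j = pos[vid]
            col = G.dosages[:, j].copy()
            target = G.variants[j]
            if meta is not None and (meta.allele_ref, meta.allele_alt) == (
                target.allele_alt, target.allele_ref
            ):
                obs = col != MISSING
                col[obs] = 2 - col[obs]
            elif meta is not None and (meta.allele_ref, meta.allele_alt) != (
                target.allele_ref, target.allele_alt
            ):
                missing_ids.append(vid)
                continue
        elif vid is None and idx < G.n_variants:
            col = G.dosages[:, idx]
        else:
            missing_ids.append(vid if vid is not None else str(idx))
            continue
        for k in range(3):
            scores[col == k] += trip[k]
    if missing_ids:
        raise KeyError(f"model variants absent from genotypes: {missing_ids}")
    return scores


def training_log_loss(F: np.ndarray, y: np.ndarray) -> float:
    """Mean logistic log-loss of predictor F against labels in {+1, -1}."""
    y = np.where(np.asarray(y) == 1, 1.0, -1.0)
    return float(np.mean(np.logaddexp(0.0, -np.asarray(F) * y)))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_model_tsv(model: GenoBoostModel, path, covariate_path=None) -> None:
    """Write collapsed triplets as TSV; optional covariate sidecar TSV."""
    import pandas as pd

    rows = []
    for idx, trip in sorted(model.collapse().items()):
        meta = model.variant_meta[idx] if model.variant_meta else None
        rows.append({
            "variant_id": model.variant_ids[idx] if model.variant_ids else str(idx),
            "chrom": meta.chrom if meta else ".",
            "pos": meta.pos if meta else 0,
            "a1": meta.allele_ref if meta else ".",
            "a2": meta.allele_alt if meta else ".",
            "score_0": trip[0],
            "score_1": trip[1],
            "score_2": trip[2],
        })
    pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "a1", "a2",
                                "score_0", "score_1", "score_2"]).to_csv(
        path, sep="\t", index=False)
    if covariate_path is not None:
        fit = model.covariate_fit
        names = ["intercept"] + [f"cov_{i}" for i in range(fit.n_covariates)]
        vals = [fit.intercept] + list(fit.coefficients)
        pd.DataFrame({"term": names, "coefficient": vals}).to_csv(
            covariate_path, sep="\t", index=False)


def write_additive_export(model: GenoBoostModel, path) -> None:
    """PGS-catalog-style additive export: effect_weight = (S2 - S0) / 2.

    Dominance information in the triplets is lost in this projection.
    """
    import pandas as pd

    warnings.warn("additive export discards dominance deviation in the triplets",
                  stacklevel=2)
    rows = []
    for idx, trip in sorted(model.collapse().items()):
        meta = model.variant_meta[idx] if model.variant_meta else None
        rows.append({
            "variant_id": model.variant_ids[idx] if model.variant_ids else str(idx),
            "effect_allele": meta.allele_ref if meta else ".",
            "effect_weight": (trip[2] - trip[0]) / 2.0,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
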