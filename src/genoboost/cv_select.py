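"""Data splitting, (gamma, T) grid search, and additive-vs-non-additive choice.

Samples are split once into a held-out test set (default 20%) and a model
development set, which is further partitioned into k folds without
phenotype stratification.  For each fold, every (gamma, model-kind) pair is
fit once at the largest T in the grid; because boosting is a deterministic
prefix algorithm, truncating the learner list at each smaller T recovers
exactly the model an independent run of that length would produce, so the
full T grid costs one run.  The validation metric is the covariate-adjusted
pseudo-R2 on the held-out fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .boost_core import GenoBoostModel, HyperParams, boost_fit, predict_genetic_score
from .evaluate import pseudo_r2
from .geno_io import GenotypeMatrix, PhenotypeTable

GAMMA_GRID = (0.05, 0.1, 0.2, 0.5)

# 29 iteration counts: 5, 10..100 by 10, 200..1000 by 100, 2000..10000 by 1000
T_GRID = tuple([5] + list(range(10, 101, 10)) + list(range(200, 1001, 100))
               + list(range(2000, 10001, 1000)))

MODEL_KINDS = ("additive", "nonadditive")


@dataclass
class SplitPlan:
    test_ids: list[str]
    folds: list[list[str]]
    seed: int

    def __post_init__(self) -> None:
        all_ids = list(self.test_ids)
        for f in self.folds:
            all_ids.extend(f)
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("test set and folds must be disjoint")
        sizes = [len(f) for f in self.folds]
        if sizes and max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes must differ by at most 1")

    def train_ids(self, fold_index: int) -> list[str]:
        return [s for i, f in enumerate(self.folds) if i != fold_index for s in f]

    def validation_ids(self, fold_index: int) -> list[str]:
        return list(self.folds[fold_index])


@dataclass
class GridResult:
    gamma: float
    T: int
    model_kind: str
    validation_metric: float
    fold_index: int


def make_split(sample_ids, k: int = 5, test_fraction: float = 0.2,
               seed: int = 0) -> SplitPlan:
    """Random test/development split plus k CV folds, phenotype-blind."""
    sample_ids = list(sample_ids)
    n = len(sample_ids)
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError("test_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    if n - n_test < k + 1:
        raise ValueError(f"too few samples ({n}) for {k} folds after the test split")
    test_ids = [sample_ids[i] for i in perm[:n_test]]
    dev = perm[n_test:]
    folds = [[sample_ids[i] for i in chunk] for chunk in np.array_split(dev, k)]
    return SplitPlan(test_ids=test_ids, folds=folds, seed=seed)


def path_snapshots(model: GenoBoostModel, T_grid) -> list[GenoBoostModel]:
    """Models truncated at each T of an ascending grid (one run, many T)."""
    T_grid = list(T_grid)
    if T_grid != sorted(T_grid):
        raise ValueError("T grid must be sorted ascending")
    if T_grid and T_grid[-1] > len(model.learners):
        raise ValueError("grid exceeds the number of iterations run")
    return [model.truncated(T) for T in T_grid]


def _subset(G: GenotypeMatrix, pheno: PhenotypeTable, ids):
    pos = {s: i for i, s in enumerate(G.samples)}
    idx = [pos[s] for s in ids]
    sub = GenotypeMatrix(G.dosages[idx], list(G.variants), list(ids))
    return sub, pheno.align(ids)


def grid_search(
    G: GenotypeMatrix,
    pheno: PhenotypeTable,
    split: SplitPlan,
    gammas=GAMMA_GRID,
    T_grid=None,
    kinds=MODEL_KINDS,
    s2_clip: float | None = None,
    primary_fold: int = 0,
):
    """Per-fold grid search over (gamma, T, kind) on validation pseudo-R2.

    Returns ``(best_hp, best_kind, fold_models, results)`` where ``best_*``
    maximize the mean validation metric across folds (ties toward smaller T
    then smaller gamma), ``fold_models`` holds each fold's winning refit
    model, and ``results`` is the full list of :class:`GridResult`.
    """
    T_grid = sorted(T_grid) if T_grid is not None else \
        [t for t in T_GRID if t <= 1000]
    results: list[GridResult] = []
    k = len(split.folds)
    for fold in range(k):
        tr_G, tr_ph = _subset(G, pheno, split.train_ids(fold))
        va_G, va_ph = _subset(G, pheno, split.validation_ids(fold))
        for kind in kinds:
            for gamma in gammas:
                hp = HyperParams(gamma=gamma, T=max(T_grid), s2_clip=s2_clip)
                try:
                    path = boost_fit(tr_G, tr_ph, hp, model_kind=kind)
                except Exception as e:  # noqa: BLE001 - cell skipped, others continue
                    warnings.warn(f"grid cell (fold={fold}, {kind}, gamma={gamma}) "
                                  f"failed: {e}", stacklevel=2)
                    continue
                for snap in path_snapshots(path, T_grid):
                    pgs = predict_genetic_score(snap, va_G)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        metric = pseudo_r2(va_ph.y, pgs, va_ph.covariates)
                    results.append(GridResult(gamma=gamma, T=len(snap.learners),
                                              model_kind=kind,
                                              validation_metric=metric,
                                              fold_index=fold))
    if not results:
        raise RuntimeError("every grid cell failed")

    # mean metric per (kind, gamma, T) across folds; ties -> smaller T, gamma
    agg: dict[tuple, list[float]] = {}
    for r in results:
        agg.setdefault((r.model_kind, r.gamma, r.T), []).append(r.validation_metric)
    best_key = max(agg, key=lambda key: (float(np.mean(agg[key])), -key[2], -key[1]))
    best_kind, best_gamma, best_T = best_key
    best_hp = HyperParams(gamma=best_gamma, T=best_T, s2_clip=s2_clip)

    fold_models = []
    for fold in range(k):
        tr_G, tr_ph = _subset(G, pheno, split.train_ids(fold))
        fold_models.append(boost_fit(tr_G, tr_ph, best_hp, model_kind=best_kind))
    return best_hp, best_kind, fold_models, results


def per_fold_winners(results: list[GridResult]) -> list[GridResult]:
    """Each fold's best cell (ties toward smaller T, then smaller gamma)."""
    winners: dict[int, GridResult] = {}
    for r in results:
        cur = winners.get(r.fold_index)
        if cur is None or (r.validation_metric, -r.T, -r.gamma) > \
                (cur.validation_metric, -cur.T, -cur.gamma):
            winners[r.fold_index] = r
    return [winners[i] for i in sorted(winners)]
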