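"""Synthetic case-control cohorts under a liability-threshold model.

Genotypes are independent biallelic SNVs in Hardy-Weinberg proportions
(no linkage disequilibrium or population structure).  A configurable
number of causal variants receive effects on a latent Gaussian liability;
each causal variant acts through a mode-specific genotype encoding
(additive, dominant, recessive, over-dominant or over-recessive), the
encoding standardized in-sample so the liability-scale heritability h2 is
split evenly across causal variants.  Case status is assigned by the
empirical liability quantile, so the realized case fraction matches the
target prevalence exactly instead of fluctuating binomially.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geno_io import (
    GenotypeMatrix,
    PhenotypeTable,
    VariantMeta,
    write_bed,
    write_phenotype,
)

NONADDITIVE_MODES = ("dominant", "recessive", "overdominant", "overrecessive")


@dataclass
class SimConfig:
    n_samples: int = 2000
    n_variants: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 10
    h2_liability: float = 0.5
    dominance_fraction: float = 0.5
    mode_weights: dict[str, float] = field(
        default_factory=lambda: {m: 0.25 for m in NONADDITIVE_MODES})
    mode_counts: dict[str, int] | None = None  # exact counts; overrides weights
    prevalence: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal cannot exceed n_variants")
        if not 0.0 <= self.h2_liability < 1.0:
            raise ValueError("h2_liability must be in [0, 1)")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must lie within (0, 0.5]")
        total = sum(self.mode_weights.values())
        if total <= 0:
            raise ValueError("mode_weights must have positive mass")
        self.mode_weights = {m: w / total for m, w in self.mode_weights.items()}


@dataclass
class TruthRecord:
    """Generative ground truth: causal variants, modes and effect sizes."""

    causal_ids: list[str]
    causal_indices: np.ndarray
    modes: list[str]
    betas: np.ndarray
    liability: np.ndarray
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"variant_id": self.causal_ids,
                             "variant_index": self.causal_indices,
                             "mode": self.modes, "beta": self.betas})


_BASES = ("A", "C", "G", "T")


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """HWE genotypes with per-variant allele frequency uniform in maf_range."""
    rng = np.random.default_rng(cfg.seed)
    freqs = rng.uniform(*cfg.maf_range, size=cfg.n_variants)
    u = rng.random((cfg.n_samples, cfg.n_variants))
    p_hom_major = (1.0 - freqs) ** 2
    p_het = 2.0 * freqs * (1.0 - freqs)
    dosages = ((u >= p_hom_major).astype(np.int8)
               + (u >= p_hom_major + p_het).astype(np.int8))
    variants = []
    for j in range(cfg.n_variants):
        a1, a2 = rng.choice(4, size=2, replace=False)
        variants.append(VariantMeta(id=f"rs{j}", chrom="1", pos=j * 1000 + 1,
                                    allele_ref=_BASES[a1], allele_alt=_BASES[a2]))
    samples = [f"id{i}" for i in range(cfg.n_samples)]
    return GenotypeMatrix(dosages, variants, samples)


def mode_encoding(g: np.ndarray, mode: str) -> np.ndarray:
    """Mode-specific liability encoding of a dosage vector."""
    g = np.asarray(g, dtype=np.float64)
    if mode == "additive":
        return g
    if mode == "dominant":
        return (g >= 1).astype(np.float64)
    if mode == "recessive":
        return (g == 2).astype(np.float64)
    if mode in ("overdominant", "overrecessive"):
        return (g == 1).astype(np.float64)
    raise ValueError(f"unknown mode {mode!r}")


def simulate_phenotype(G: GenotypeMatrix, cfg: SimConfig,
                       n_covariates: int = 0) -> tuple[PhenotypeTable, TruthRecord]:
    """Liability-threshold phenotype with exact-prevalence case assignment.

    Liability = sum_j beta_j * standardized encoding_j + noise, with
    beta_j ~ N(0, h2 / n_causal), noise ~ N(0, 1 - h2).  Over-recessive
    variants get a negative heterozygote effect (|beta| with flipped sign),
    over-dominant a positive one.  Optional standard-normal covariates with
    a modest liability contribution can be added for covariate-adjustment
    tests.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    causal_idx = np.sort(rng.choice(cfg.n_variants, size=cfg.n_causal, replace=False))
    modes = ["additive"] * cfg.n_causal
    if cfg.mode_counts is not None:
        n_nonadd = sum(cfg.mode_counts.values())
        if n_nonadd > cfg.n_causal:
            raise ValueError("mode_counts exceed n_causal")
        pool = [m for m, cnt in cfg.mode_counts.items() for _ in range(cnt)]
        nonadd_slots = rng.choice(cfg.n_causal, size=n_nonadd, replace=False)
        for slot, mode in zip(nonadd_slots, pool):
            modes[slot] = mode
    else:
        n_nonadd = int(round(cfg.dominance_fraction * cfg.n_causal))
        if n_nonadd > 0:
            nonadd_slots = rng.choice(cfg.n_causal, size=n_nonadd, replace=False)
            names = list(cfg.mode_weights)
            probs = np.array([cfg.mode_weights[m] for m in names])
            drawn = rng.choice(names, size=n_nonadd, p=probs)
            for slot, mode in zip(nonadd_slots, drawn):
                modes[slot] = mode

    betas = rng.normal(0.0, np.sqrt(cfg.h2_liability / max(cfg.n_causal, 1)),
                       size=cfg.n_causal)
    # over-modes act through the heterozygote with a sign-pinned effect
    for i, mode in enumerate(modes):
        if mode == "overdominant":
            betas[i] = abs(betas[i])
        elif mode == "overrecessive":
            betas[i] = -abs(betas[i])

    genetic = np.zeros(G.n_samples)
    for i, j in enumerate(causal_idx):
        enc = mode_encoding(G.dosages[:, j], modes[i])
        sd = enc.std()
        if sd > 0:
            enc = (enc - enc.mean()) / sd
        genetic += betas[i] * enc
    noise = rng.normal(0.0, np.sqrt(1.0 - cfg.h2_liability), size=G.n_samples)
    liability = genetic + noise

    n_cases = int(np.ceil(cfg.prevalence * G.n_samples))
    order = np.argsort(-liability, kind="stable")
    y = np.full(G.n_samples, -1, dtype=np.int64)
    y[order[:n_cases]] = 1
    threshold = float(liability[order[n_cases - 1]])

    if n_covariates > 0:
        cov = rng.normal(size=(G.n_samples, n_covariates))
        names = [f"cov{i}" for i in range(n_covariates)]
    else:
        cov = np.empty((G.n_samples, 0))
        names = []
    pheno = PhenotypeTable(list(G.samples), y, cov, names)
    truth = TruthRecord(
        causal_ids=[G.variants[j].id for j in causal_idx],
        causal_indices=causal_idx, modes=modes, betas=betas,
        liability=liability, threshold=threshold,
    )
    return pheno, truth


def simulate_cohort(cfg: SimConfig, n_covariates: int = 0):
    """Convenience: genotypes + phenotype + truth in one call."""
    G = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotype(G, cfg, n_covariates=n_covariates)
    return G, pheno, truth


def single_variant_cohort(n: int, mode: str, effect: float, maf: float = 0.3,
                          prevalence: float = 0.3, seed: int = 0,
                          n_null: int = 0):
    """One strong causal variant (plus optional null variants): the minimal
    cohort for mode-recovery and selection tests."""
    cfg = SimConfig(n_samples=n, n_variants=1 + n_null, maf_range=(maf, maf),
                    n_causal=1, h2_liability=min(0.99, effect),
                    dominance_fraction=0.0, prevalence=prevalence, seed=seed)
    G = simulate_genotypes(cfg)
    rng = np.random.default_rng(seed + 1)
    enc = mode_encoding(G.dosages[:, 0], mode)
    sd = enc.std()
    if sd > 0:
        enc = (enc - enc.mean()) / sd
    sign = -1.0 if mode == "overrecessive" else 1.0
    beta = sign * np.sqrt(cfg.h2_liability)
    liability = beta * enc + rng.normal(0.0, np.sqrt(1.0 - cfg.h2_liability), size=n)
    n_cases = int(np.ceil(prevalence * n))
    order = np.argsort(-liability, kind="stable")
    y = np.full(n, -1, dtype=np.int64)
    y[order[:n_cases]] = 1
    pheno = PhenotypeTable(list(G.samples), y, np.empty((n, 0)))
    return G, pheno


def write_fixture(G: GenotypeMatrix, pheno: PhenotypeTable, out_dir,
                  prefix: str = "cohort", truth: TruthRecord | None = None):
    """Write bed/bim/fam + phenotype TSV (+ optional truth TSV) to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = write_bed(G, out_dir / prefix)
    paths["pheno"] = write_phenotype(pheno, out_dir / f"{prefix}.pheno.tsv")
    if truth is not None:
        truth_path = out_dir / f"{prefix}.truth.tsv"
        truth.to_frame().to_csv(truth_path, sep="\t", index=False)
        paths["truth"] = truth_path
    return paths
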