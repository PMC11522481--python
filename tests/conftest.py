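import numpy as np
import pytest

from genoboost.geno_io import GenotypeMatrix, PhenotypeTable, VariantMeta
from genoboost.simulate import SimConfig, simulate_cohort


def make_matrix(dosages, ids=None) -> GenotypeMatrix:
    """Small GenotypeMatrix with generated metadata."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, d = dosages.shape
    variants = [
        VariantMeta(id=(ids[j] if ids else f"snp{j}"), chrom="1", pos=j + 1,
                    allele_ref="A", allele_alt="G")
        for j in range(d)
    ]
    return GenotypeMatrix(dosages, variants, [f"s{i}" for i in range(n)])


@pytest.fixture(scope="session")
def small_cohort():
    """n=500, d=30, 3 causal variants: the everyday fitting fixture."""
    cfg = SimConfig(n_samples=500, n_variants=30, n_causal=3,
                    h2_liability=0.5, prevalence=0.3, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def causal_vs_null_cohort():
    """1 strong additive causal variant among 20 nulls (n=500, seeded)."""
    cfg = SimConfig(n_samples=500, n_variants=21, n_causal=1,
                    h2_liability=0.6, dominance_fraction=0.0,
                    prevalence=0.3, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture
def phenotype_for(small_cohort):
    return small_cohort[1]


def make_pheno(y, cov=None, ids=None) -> PhenotypeTable:
    y = np.asarray(y)
    n = len(y)
    ids = ids or [f"s{i}" for i in range(n)]
    cov = np.empty((n, 0)) if cov is None else np.asarray(cov, dtype=float)
    return PhenotypeTable(ids, y, cov)
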