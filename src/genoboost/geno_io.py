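"""PLINK 1 binary genotype I/O, phenotype/covariate tables, and variant QC.

Genotype dosages are stored as the count of the *minor* allele in {0, 1, 2},
with missing entries encoded as -1 in an int8 matrix.  Columns whose counted
(bim A1) allele turns out to be the major allele are flipped on load and the
flip recorded, so downstream per-genotype scores always refer to the
homozygous-minor class relative to the homozygous-major baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

MISSING = np.int8(-1)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# PLINK 1 2-bit codes (SNP-major): 00 hom-A1, 01 missing, 10 het, 11 hom-A2.
# We count A1 copies: 00 -> 2, 10 -> 1, 11 -> 0, 01 -> missing.
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}

_VALID_BASES = frozenset("ACGT")


class BedFormatError(ValueError):
    """Raised for malformed or unsupported .bed payloads."""


@dataclass(frozen=True)
class VariantMeta:
    """Metadata for one biallelic SNV as read from a .bim line."""

    id: str
    chrom: str
    pos: int
    allele_ref: str  # counted (minor/effect) allele after orientation
    allele_alt: str
    is_flipped: bool = False

    def __post_init__(self) -> None:
        if self.allele_ref == self.allele_alt:
            raise ValueError(f"{self.id}: identical alleles {self.allele_ref!r}")
        for a in (self.allele_ref, self.allele_alt):
            if a not in _VALID_BASES:
                raise ValueError(f"{self.id}: allele {a!r} is not an unambiguous SNV base")


@dataclass
class GenotypeMatrix:
    """n_samples x n_variants minor-allele dosage matrix plus metadata."""

    dosages: np.ndarray
    variants: list[VariantMeta]
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, d = self.dosages.shape
        if len(self.samples) != n or len(self.variants) != d:
            raise ValueError("metadata lengths do not match matrix dimensions")
        if len(set(self.samples)) != n:
            raise ValueError("sample IDs are not unique")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("dosages contain values outside {0,1,2,missing}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def subset_variants(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.dosages[:, idx],
            [self.variants[i] for i in idx],
            list(self.samples),
        )

    def as_float(self) -> np.ndarray:
        """Dosages as float64 with missing mapped to NaN."""
        out = self.dosages.astype(np.float64)
        out[self.dosages == MISSING] = np.nan
        return out


@dataclass
class PhenotypeTable:
    """Binary phenotype (+1 case / -1 control) and covariates keyed by sample."""

    sample_ids: list[str]
    y: np.ndarray
    covariates: np.ndarray
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        if not np.isin(self.y, (-1, 1)).all():
            raise ValueError("phenotype must be coded +1 (case) / -1 (control)")
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=np.float64))
        if self.covariates.size == 0:
            self.covariates = np.empty((len(self.sample_ids), 0))
        if self.covariates.shape[0] != len(self.sample_ids):
            raise ValueError("covariate rows do not match sample count")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def align(self, sample_ids: Sequence[str]) -> "PhenotypeTable":
        """Reorder/subset to the given sample IDs (all must be present)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[s] for s in sample_ids]
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} absent from phenotype table") from None
        return PhenotypeTable(
            list(sample_ids), self.y[idx], self.covariates[idx], list(self.covariate_names)
        )


@dataclass(frozen=True)
class QcParams:
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    missing_max: float = 0.05

    def __post_init__(self) -> None:
        for name in ("maf_min", "hwe_p_min", "missing_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


# ---------------------------------------------------------------------------
# PLINK 1 bed/bim/fam
# ---------------------------------------------------------------------------

def read_bed(bed_path, bim_path=None, fam_path=None, orient_minor: bool = True) -> GenotypeMatrix:
    """Read a PLINK 1 binary fileset into a :class:`GenotypeMatrix`.

    Only SNP-major files (third magic byte 0x01) are supported.  When
    ``orient_minor`` is true (default), columns where the counted allele has
    frequency > 0.5 are flipped so dosage counts the minor allele.
    """
    bed_path = Path(bed_path)
    bim_path = Path(bim_path) if bim_path else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path else bed_path.with_suffix(".fam")

    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    samples = fam.iloc[:, 1].tolist()
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None, dtype=str)
    variants = [
        VariantMeta(id=r[1], chrom=str(r[0]), pos=int(r[3]), allele_ref=r[4], allele_alt=r[5])
        for r in bim.itertuples(index=False)
    ]

    n, d = len(samples), len(variants)
    raw = bed_path.read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC[:2]:
        raise BedFormatError(f"{bed_path}: bad magic bytes {raw[:2]!r}")
    if raw[2] != 0x01:
        raise BedFormatError(f"{bed_path}: individual-major bed files are not supported")
    bytes_per_variant = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_variant * d:
        raise BedFormatError(
            f"{bed_path}: payload has {payload.size} bytes, expected {bytes_per_variant * d}"
        )
    codes = payload.reshape(d, bytes_per_variant)
    # unpack 2-bit fields, sample i in bits 2*(i mod 4) of byte i//4
    expanded = np.empty((d, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        expanded[:, k::4] = (codes >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[expanded[:, :n]].T.copy()  # n x d

    if orient_minor:
        dosages, variants = _orient_minor(dosages, variants)
    return GenotypeMatrix(dosages, variants, samples)


def _orient_minor(dosages: np.ndarray, variants: list[VariantMeta]):
    out_variants = []
    for j, v in enumerate(variants):
        col = dosages[:, j]
        obs = col != MISSING
        if obs.any() and col[obs].mean() > 1.0:  # counted-allele freq > 0.5
            col[obs] = 2 - col[obs]
            v = replace(v, allele_ref=v.allele_alt, allele_alt=v.allele_ref, is_flipped=True)
        out_variants.append(v)
    return dosages, out_variants


def write_bed(G: GenotypeMatrix, prefix) -> dict[str, Path]:
    """Write a GenotypeMatrix as SNP-major PLINK 1 bed/bim/fam."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, d = G.dosages.shape
    bytes_per_variant = (n + 3) // 4

    code = np.empty((d, bytes_per_variant * 4), dtype=np.uint8)
    code[:] = _DOSAGE_TO_CODE[0]  # pad slots encode dosage 0 (hom-A2), PLINK convention
    lut = np.empty(256, dtype=np.uint8)
    for dose, c in _DOSAGE_TO_CODE.items():
        lut[dose % 256] = c  # missing (-1) wraps to byte 255
    code[:, :n] = lut[G.dosages.T.astype(np.uint8)]
    packed = np.zeros((d, bytes_per_variant), dtype=np.uint8)
    for k in range(4):
        packed |= code[:, k::4] << (2 * k)

    bed_path = prefix.with_suffix(".bed")
    bed_path.write_bytes(_BED_MAGIC + packed.tobytes())

    bim_lines = [
        f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.allele_ref}\t{v.allele_alt}\n" for v in G.variants
    ]
    bim_path = prefix.with_suffix(".bim")
    bim_path.write_text("".join(bim_lines))
    fam_path = prefix.with_suffix(".fam")
    fam_path.write_text("".join(f"{s}\t{s}\t0\t0\t0\t-9\n" for s in G.samples))
    return {"bed": bed_path, "bim": bim_path, "fam": fam_path}


def read_phenotype(path, phenotype_col: str = "phenotype",
                   covariate_cols: Sequence[str] | None = None) -> PhenotypeTable:
    """Read a tab-separated phenotype/covariate table.

    First column is the sample ID; the phenotype column uses the PLINK
    convention 1=control, 2=case and is recoded to -1/+1 internally.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    id_col = df.columns[0]
    raw = df[phenotype_col].to_numpy()
    if not np.isin(raw, (1, 2)).all():
        raise ValueError("phenotype column must use PLINK coding 1=control, 2=case")
    y = np.where(raw == 2, 1, -1)
    if covariate_cols is None:
        covariate_cols = [c for c in df.columns if c not in (id_col, phenotype_col)]
    cov = df[list(covariate_cols)].to_numpy(dtype=np.float64) if covariate_cols else \
        np.empty((len(df), 0))
    return PhenotypeTable(df[id_col].tolist(), y, cov, list(covariate_cols))


def write_phenotype(pheno: PhenotypeTable, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"sample_id": pheno.sample_ids,
                       "phenotype": np.where(pheno.y == 1, 2, 1)})
    for j, name in enumerate(pheno.covariate_names):
        df[name] = pheno.covariates[:, j]
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Variant QC
# ---------------------------------------------------------------------------

def compute_maf(column: np.ndarray) -> float:
    """Minor allele frequency of one dosage column (missing = -1 ignored)."""
    col = np.asarray(column)
    obs = col[col != MISSING]
    if obs.size == 0:
        raise ValueError("MAF undefined for an all-missing column")
    p = float(obs.sum()) / (2.0 * obs.size)
    return min(p, 1.0 - p)


def hwe_test(n0: int, n1: int, n2: int) -> float:
    """Chi-square (1 df) goodness-of-fit p-value against Hardy-Weinberg.

    Genotype counts are for 0, 1, 2 copies of an allele; monomorphic input
    returns p = 1.  Symmetric under allele relabeling (n0 <-> n2).
    """
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    p = (2 * n2 + n1) / (2.0 * n)
    if p <= 0.0 or p >= 1.0:
        return 1.0
    expected = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    observed = np.array([n0, n1, n2], dtype=float)
    statistic = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(statistic, df=1))


def genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    col = np.asarray(column)
    return (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))


def qc_filter(G: GenotypeMatrix, params: QcParams = QcParams()) -> np.ndarray:
    """Boolean mask of variants passing MAF, HWE, missingness and SNV checks."""
    n, d = G.dosages.shape
    mask = np.zeros(d, dtype=bool)
    for j in range(d):
        col = G.dosages[:, j]
        n_missing = int((col == MISSING).sum())
        if n_missing / n >= params.missing_max:
            continue
        if n_missing == n:
            continue
        if compute_maf(col) <= params.maf_min:
            continue
        if hwe_test(*genotype_counts(col)) <= params.hwe_p_min:
            continue
        v = G.variants[j]
        if v.allele_ref not in _VALID_BASES or v.allele_alt not in _VALID_BASES:
            continue
        mask[j] = True
    return mask
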