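"""Core containers shared across the pipeline.

Two quantitative traits are carried everywhere in a fixed order:
trait 1 = ADG (average daily gain, kg/day), trait 2 = WBSF
(Warner-Bratzler shear force, kgf).  Genotypes are additive dosages
(count of the alternate allele, 0/1/2) with ``-1`` encoding a missing
call; phenotype records live in a plain :class:`pandas.DataFrame` with
the column contract in :data:`PHENO_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

TRAITS = ("adg", "wbsf")

#: Required columns of a phenotype table (cg_adg / cg_wbsf are added by QC).
PHENO_COLUMNS = [
    "animal_id",
    "adg",
    "wbsf",
    "birth_year",
    "birth_month",
    "herd_birth",
    "herd_weaning",
    "herd_yearling",
    "slaughter_date",
]

MISSING = -1  # dosage code for a missing genotype call


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


class EmptyPanelError(RuntimeError):
    """Raised when quality control removes every marker or sample."""


@dataclass(frozen=True)
class SnpMap:
    """Genomic map of the SNP panel.

    Positions are 1-based base pairs, strictly increasing within a
    chromosome; chromosome labels are integer BTA numbers.
    """

    snp_id: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray

    def __post_init__(self) -> None:
        snp_id = np.asarray(self.snp_id, dtype=object)
        chrom = np.asarray(self.chromosome, dtype=np.int64)
        pos = np.asarray(self.position, dtype=np.int64)
        if not (len(snp_id) == len(chrom) == len(pos)):
            raise ValueError("SnpMap fields must have equal length")
        if len(np.unique(snp_id)) != len(snp_id):
            raise ValueError("SNP ids must be unique")
        for c in np.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
        object.__setattr__(self, "snp_id", snp_id)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position", pos)

    def __len__(self) -> int:
        return len(self.snp_id)

    def subset(self, idx: np.ndarray) -> "SnpMap":
        return SnpMap(self.snp_id[idx], self.chromosome[idx], self.position[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_id, "chromosome": self.chromosome, "position": self.position}
        )


@dataclass
class GenotypeMatrix:
    """Animals x SNPs additive dosage matrix plus its map.

    ``dosages`` is int8 with values in {0, 1, 2, -1(missing)}.
    """

    sample_ids: np.ndarray
    snp_map: SnpMap
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_map)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snp_map)} SNPs"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2,-1}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def dosage_float(self) -> np.ndarray:
        """Dosages as float64 with NaN for missing calls."""
        out = self.dosages.astype(np.float64)
        out[self.dosages == MISSING] = np.nan
        return out

    def subset_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sample_ids, self.snp_map.subset(idx), self.dosages[:, idx])

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sample_ids[idx], self.snp_map, self.dosages[idx, :])


# QTL pleiotropy mask codes
QTL_NULL = 0
QTL_SHARED = 1
QTL_TRAIT1 = 2
QTL_TRAIT2 = 3


@dataclass
class QtlEffects:
    """Per-SNP additive allele-substitution effects for the two traits.

    ``effects`` is SNPs x 2 (trait units per alternate-allele copy);
    ``pleiotropy_mask`` flags each SNP as null / shared / trait-specific.
    """

    effects: np.ndarray
    pleiotropy_mask: np.ndarray

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=np.float64)
        self.pleiotropy_mask = np.asarray(self.pleiotropy_mask, dtype=np.int8)
        if self.effects.shape[0] != self.pleiotropy_mask.shape[0] or self.effects.shape[1] != 2:
            raise ValueError("effects must be SNPs x 2 aligned with the mask")
        null = self.pleiotropy_mask == QTL_NULL
        if np.any(self.effects[null] != 0.0):
            raise ValueError("null rows must be exactly zero")
        shared = self.pleiotropy_mask == QTL_SHARED
        if np.any(np.any(self.effects[shared] == 0.0, axis=1)):
            raise ValueError("shared rows must be nonzero in both traits")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults emulate the real study's structure at desk scale: two traits
    with phenotypic variances 0.004 (kg/day)^2 and 2.03 kgf^2, target
    heritabilities 0.23 and 0.13, genetic correlation -0.17, contemporary
    groups from year x birth season x herd, and the WBSF trait observed on
    only ~91% of animals.
    """

    n_animals: int = 1000
    n_snps: int = 5000
    n_chromosomes: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    snp_spacing_bp: int = 5_000
    ld_block_length: int = 50_000
    recomb_prob: float = 0.08  # per adjacent SNP pair within a block
    sire_family_size: int = 20  # paternal half-sib family size (<=1: unrelated)
    n_qtl: int = 150
    shared_fraction: float = 0.3
    qtl_effect_corr: float = -0.17  # correlation of shared-QTL effect pairs
    target_h2: tuple[float, float] = (0.23, 0.13)
    target_rg: float = -0.17
    phenotypic_variance: tuple[float, float] = (0.004, 2.03)
    trait_means: tuple[float, float] = (0.63, 6.27)
    n_herds: int = 6
    cg_effect_sd: tuple[float, float] = (0.06, 1.0)
    missing_trait2_fraction: float = 0.086
    birth_year_range: tuple[int, int] = (2008, 2018)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ConfigurationError("shared_fraction must be in [0, 1]")
        for h in self.target_h2:
            if not (0.0 <= h < 1.0):
                raise ConfigurationError("target_h2 components must be in [0, 1)")
        if not (-1.0 <= self.target_rg <= 1.0):
            raise ConfigurationError("target_rg must be in [-1, 1]")
        if self.n_qtl > self.n_snps:
            raise ConfigurationError("n_qtl cannot exceed n_snps")
        if self.n_snps % self.n_chromosomes != 0:
            raise ConfigurationError("n_snps must be divisible by n_chromosomes")

    @property
    def genetic_variance(self) -> tuple[float, float]:
        return tuple(h * s for h, s in zip(self.target_h2, self.phenotypic_variance))

    @property
    def residual_variance(self) -> tuple[float, float]:
        return tuple((1.0 - h) * s for h, s in zip(self.target_h2, self.phenotypic_variance))

    def genetic_covariance(self) -> np.ndarray:
        """Target 2x2 genetic covariance; raises if not positive definite."""
        sa1, sa2 = self.genetic_variance
        cov = self.target_rg * np.sqrt(sa1 * sa2)
        g = np.array([[sa1, cov], [cov, sa2]])
        if sa1 > 0 and sa2 > 0:
            if np.linalg.eigvalsh(g).min() < -1e-12 or abs(self.target_rg) >= 1.0:
                raise ConfigurationError("target_rg incompatible with a PD genetic covariance")
        return g

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class VarianceComponents:
    """2x2 genetic covariance and diagonal residual covariance.

    The residual off-diagonal is structurally zero: the model's residual
    (co)variance is I*se1^2 and I*se2^2 with no covariance term.
    """

    genetic_cov: np.ndarray
    residual_var: np.ndarray  # length-2 vector (se1^2, se2^2)

    def __post_init__(self) -> None:
        self.genetic_cov = np.asarray(self.genetic_cov, dtype=np.float64)
        self.residual_var = np.asarray(self.residual_var, dtype=np.float64).ravel()
        if self.genetic_cov.shape != (2, 2):
            raise ValueError("genetic_cov must be 2x2")
        if not np.allclose(self.genetic_cov, self.genetic_cov.T):
            raise ValueError("genetic_cov must be symmetric")

    @property
    def heritabilities(self) -> np.ndarray:
        sa = np.diag(self.genetic_cov)
        return sa / (sa + self.residual_var)

    @property
    def genetic_correlation(self) -> float:
        sa = np.diag(self.genetic_cov)
        denom = np.sqrt(sa[0] * sa[1])
        return float(self.genetic_cov[0, 1] / denom) if denom > 0 else 0.0


def validate_phenotypes(pheno: pd.DataFrame) -> None:
    missing = [c for c in PHENO_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
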