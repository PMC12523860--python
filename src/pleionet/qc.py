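"""Marker, sample, and phenotype quality control.

Filter order is fixed: samples -> markers -> contemporary-group build ->
phenotype filters.  Marker thresholds default to the study's values:
call rate < 0.90, MAF < 0.05, HWE deviation (|observed - expected
heterozygosity|) > 0.15, and monomorphic markers removed.  The HWE rule
is applied as "deviation exceeding 0.15" (the removal direction that
makes the filter meaningful).  Phenotype records are dropped when they
lie more than 3.5 SD from their contemporary-group mean, then
contemporary groups with fewer than 5 remaining records are dropped.

In a QC report every removed marker is attributed to exactly one filter,
the first that triggers in the order: call-rate, monomorphic, MAF, HWE
deviation.  Monomorphic precedes MAF because a monomorphic marker always
has MAF 0 and would otherwise never be counted as monomorphic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import EmptyPanelError, GenotypeMatrix

__all__ = [
    "MarkerQcThresholds",
    "PhenotypeQcThresholds",
    "QcReport",
    "marker_statistics",
    "filter_markers",
    "filter_samples",
    "build_contemporary_groups",
    "filter_phenotypes",
]

#: birth months mapped to the two birth seasons (Aug-Jan vs Feb-Jul)
AUG_JAN_MONTHS = frozenset({8, 9, 10, 11, 12, 1})


@dataclass(frozen=True)
class MarkerQcThresholds:
    min_call_rate: float = 0.90
    min_maf: float = 0.05
    max_hwe_deviation: float = 0.15
    drop_monomorphic: bool = True

    def __post_init__(self) -> None:
        for v in (self.min_call_rate, self.min_maf, self.max_hwe_deviation):
            if not (0.0 <= v <= 1.0):
                raise ValueError("marker QC thresholds must be in [0, 1]")


@dataclass(frozen=True)
class PhenotypeQcThresholds:
    sd_limit: float = 3.5
    min_cg_size: int = 5

    def __post_init__(self) -> None:
        if self.sd_limit <= 0:
            raise ValueError("sd_limit must be positive")
        if self.min_cg_size < 1:
            raise ValueError("min_cg_size must be >= 1")


@dataclass
class QcReport:
    """Removal accounting for one QC operation.

    ``removed_by`` maps filter name -> count; removed + kept equals the
    input count for the filtered axis.
    """

    n_input: int
    n_kept: int
    removed_by: dict[str, int] = field(default_factory=dict)
    removed_ids: dict[str, list] = field(default_factory=dict)
    statistics: pd.DataFrame | None = None

    @property
    def n_removed(self) -> int:
        return sum(self.removed_by.values())

    def check_conserved(self) -> None:
        if self.n_kept + self.n_removed != self.n_input:
            raise AssertionError("QC counts not conserved")

    def to_json_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "removed_by": dict(self.removed_by),
        }


def marker_statistics(geno: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP call rate, allele frequency, MAF, heterozygosities.

    A SNP with zero calls gets call rate 0, NaN frequency, and is
    flagged monomorphic so the filters treat it as unusable.
    """
    import warnings

    dos = geno.dosage_float()
    n = geno.n_samples
    n_called = np.sum(~np.isnan(dos), axis=0)
    call_rate = n_called / n
    with warnings.catch_warnings():
        # zero-call SNPs produce all-NaN columns by design; they come out
        # NaN here and are flagged monomorphic below
        warnings.simplefilter("ignore", RuntimeWarning)
        p_alt = np.nanmean(dos, axis=0) / 2.0
        het_obs = np.nanmean(dos == 1.0, axis=0)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    het_exp = 2.0 * p_alt * (1.0 - p_alt)
    hwe_dev = np.abs(het_obs - het_exp)
    monomorphic = (maf == 0.0) | (n_called == 0)
    return pd.DataFrame(
        {
            "snp_id": geno.snp_map.snp_id,
            "n_called": n_called,
            "call_rate": call_rate,
            "freq_alt": p_alt,
            "maf": maf,
            "het_obs": het_obs,
            "het_exp": het_exp,
            "hwe_dev": hwe_dev,
            "monomorphic": monomorphic,
        }
    )


def filter_markers(
    geno: GenotypeMatrix, thresholds: MarkerQcThresholds = MarkerQcThresholds()
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove markers failing any marker filter; keep original order."""
    stats = marker_statistics(geno)
    t = thresholds
    fail_call = stats["call_rate"].to_numpy() < t.min_call_rate
    fail_mono = stats["monomorphic"].to_numpy() & t.drop_monomorphic
    with np.errstate(invalid="ignore"):
        fail_maf = stats["maf"].to_numpy() < t.min_maf
        fail_hwe = stats["hwe_dev"].to_numpy() > t.max_hwe_deviation
    fail_maf &= ~np.isnan(stats["maf"].to_numpy())
    fail_hwe &= ~np.isnan(stats["hwe_dev"].to_numpy())
    # zero-call SNPs are treated as monomorphic even if drop_monomorphic off
    fail_mono |= stats["n_called"].to_numpy() == 0

    # first-triggering attribution
    attributed = np.zeros(geno.n_snps, dtype=bool)
    report = QcReport(n_input=geno.n_snps, n_kept=0, statistics=stats)
    for name, fail in (
        ("call_rate", fail_call),
        ("monomorphic", fail_mono),
        ("maf", fail_maf),
        ("hwe_deviation", fail_hwe),
    ):
        hit = fail & ~attributed
        report.removed_by[name] = int(hit.sum())
        report.removed_ids[name] = list(geno.snp_map.snp_id[hit])
        attributed |= hit
    keep = ~attributed
    report.n_kept = int(keep.sum())
    report.check_conserved()
    if report.n_kept == 0:
        raise EmptyPanelError("all markers removed by QC")
    return geno.subset_snps(np.flatnonzero(keep)), report


def filter_samples(
    geno: GenotypeMatrix, min_sample_call_rate: float = 0.90
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove samples with genotype call rate below threshold."""
    called = np.sum(geno.dosages != -1, axis=1)
    rate = called / geno.n_snps
    keep = rate >= min_sample_call_rate
    report = QcReport(
        n_input=geno.n_samples,
        n_kept=int(keep.sum()),
        removed_by={"sample_call_rate": int((~keep).sum())},
        removed_ids={"sample_call_rate": list(geno.sample_ids[~keep])},
    )
    report.check_conserved()
    return geno.subset_samples(np.flatnonzero(keep)), report


def birth_season(month: int | np.ndarray) -> np.ndarray:
    """Two birth seasons: Aug-Jan and Feb-Jul."""
    return np.where(np.isin(month, tuple(AUG_JAN_MONTHS)), "AugJan", "FebJul")


def build_contemporary_groups(pheno: pd.DataFrame) -> tuple[pd.DataFrame, QcReport]:
    """Fill cg_adg / cg_wbsf labels.

    cg_adg = year _ season _ herd(birth) _ herd(weaning) _ herd(yearling);
    cg_wbsf additionally includes the slaughter date.  A record whose
    trait value is present but whose CG-defining fields are incomplete is
    invalidated (trait set to NaN) and counted.
    """
    out = pheno.copy()
    cg_fields_adg = ["birth_year", "birth_month", "herd_birth", "herd_weaning", "herd_yearling"]
    have_adg_fields = out[cg_fields_adg].notna().all(axis=1)
    have_wbsf_fields = have_adg_fields & out["slaughter_date"].notna()

    season = birth_season(out["birth_month"].to_numpy())
    base = (
        out["birth_year"].astype("Int64").astype(str)
        + "_"
        + pd.Series(season, index=out.index)
        + "_"
        + out["herd_birth"].astype(str)
        + "_"
        + out["herd_weaning"].astype(str)
        + "_"
        + out["herd_yearling"].astype(str)
    )
    out["cg_adg"] = base.where(have_adg_fields & out["adg"].notna())
    out["cg_wbsf"] = (base + "_" + out["slaughter_date"].astype(str)).where(
        have_wbsf_fields & out["wbsf"].notna()
    )

    invalid_adg = out["adg"].notna() & ~have_adg_fields
    invalid_wbsf = out["wbsf"].notna() & ~have_wbsf_fields
    out.loc[invalid_adg, "adg"] = np.nan
    out.loc[invalid_wbsf, "wbsf"] = np.nan
    n_rec = int(pheno["adg"].notna().sum() + pheno["wbsf"].notna().sum())
    report = QcReport(
        n_input=n_rec,
        n_kept=n_rec - int(invalid_adg.sum() + invalid_wbsf.sum()),
        removed_by={
            "missing_cg_fields_adg": int(invalid_adg.sum()),
            "missing_cg_fields_wbsf": int(invalid_wbsf.sum()),
        },
    )
    report.check_conserved()
    return out, report


def filter_phenotypes(
    pheno: pd.DataFrame, thresholds: PhenotypeQcThresholds = PhenotypeQcThresholds()
) -> tuple[pd.DataFrame, QcReport]:
    """Per-trait outlier and small-CG removal.

    Single pass per trait: (1) drop records more than ``sd_limit`` sample
    SDs (n-1 denominator) from their CG mean, statistics computed with
    the record included; (2) then drop whole CGs with fewer than
    ``min_cg_size`` remaining records.  A CG of size 1 has undefined SD:
    its record survives step 1 and the CG is dropped at step 2 (for any
    ``min_cg_size`` > 1).  Removing a trait record never touches the
    animal's other trait.
    """
    out = pheno.copy()
    report = QcReport(n_input=0, n_kept=0)
    for trait, cg_col in (("adg", "cg_adg"), ("wbsf", "cg_wbsf")):
        if cg_col not in out.columns:
            raise ValueError(f"{cg_col} missing; run build_contemporary_groups first")
        has = out[trait].notna() & out[cg_col].notna()
        report.n_input += int(out[trait].notna().sum())
        vals = out.loc[has, trait]
        groups = out.loc[has, cg_col]
        mean = vals.groupby(groups).transform("mean")
        sd = vals.groupby(groups).transform("std")  # ddof=1; NaN for size-1 CG
        with np.errstate(invalid="ignore"):
            outlier = (vals - mean).abs() > thresholds.sd_limit * sd
        outlier &= sd.notna() & (sd > 0)
        out.loc[outlier[outlier].index, trait] = np.nan

        still = out[trait].notna() & out[cg_col].notna()
        sizes = out.loc[still, cg_col].map(out.loc[still, cg_col].value_counts())
        small = sizes < thresholds.min_cg_size
        out.loc[small[small].index, trait] = np.nan

        report.removed_by[f"{trait}_outlier_3.5sd"] = int(outlier.sum())
        report.removed_by[f"{trait}_small_cg"] = int(small.sum())
        report.n_kept += int(out[trait].notna().sum())
    report.check_conserved()
    return out, report
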