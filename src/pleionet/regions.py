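"""Window clustering of significant SNPs and candidate-gene annotation.

Each significant SNP spawns a +/-100 kb window (clamped at position 1);
overlapping or touching windows on the same chromosome are merged
transitively into regions.  A gene is assigned to a region when their
1-based closed intervals share at least one base pair.  The per-trait
region tables mirror the usual GWAS report layout (BTA, n SNP, region in
Mb, size, importance-score summary, genes), and the cross-trait gene set
is the exact intersection of the two per-trait gene-id sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "cluster_windows",
    "annotate_genes",
    "shared_genes",
    "region_table",
    "export_reports",
]

DEFAULT_FLANK = 100_000  # bp on each side of a significant SNP


@dataclass
class Region:
    """Merged window on one chromosome (1-based closed coordinates)."""

    chromosome: int
    start: int
    end: int
    snp_ids: list[str]
    ris: np.ndarray  # member RIS values, same order as snp_ids
    genes: list[str] = field(default_factory=list)

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    @property
    def size_mb(self) -> float:
        return (self.end - self.start) / 1e6

    def ris_summary(self) -> tuple[float, float, float]:
        return float(self.ris.mean()), float(self.ris.min()), float(self.ris.max())


def cluster_windows(
    snps: pd.DataFrame, flank: int = DEFAULT_FLANK, ris_col: str = "ris"
) -> list[Region]:
    """Merge per-SNP windows into disjoint regions.

    ``snps`` needs columns snp_id, chromosome, position and a RIS column.
    The result is independent of the input row order; every SNP belongs
    to exactly one region.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    regions: list[Region] = []
    df = snps.sort_values(["chromosome", "position"], kind="mergesort")
    for chrom, grp in df.groupby("chromosome", sort=True):
        cur: dict | None = None
        for row in grp.itertuples(index=False):
            lo = max(1, int(row.position) - flank)
            hi = int(row.position) + flank
            if cur is not None and lo <= cur["end"]:  # touching counts as overlap
                cur["end"] = max(cur["end"], hi)
                cur["ids"].append(row.snp_id)
                cur["ris"].append(getattr(row, ris_col))
            else:
                if cur is not None:
                    regions.append(_close(chrom, cur))
                cur = {"start": lo, "end": hi, "ids": [row.snp_id], "ris": [getattr(row, ris_col)]}
        if cur is not None:
            regions.append(_close(chrom, cur))
    return regions


def _close(chrom, cur) -> Region:
    return Region(
        chromosome=int(chrom),
        start=cur["start"],
        end=cur["end"],
        snp_ids=list(cur["ids"]),
        ris=np.asarray(cur["ris"], dtype=float),
    )


def annotate_genes(regions: list[Region], genes: pd.DataFrame) -> list[Region]:
    """Attach overlapping genes (any >= 1 bp overlap) in genomic order.

    Raises if a region's chromosome label does not occur in the
    annotation at all (guards against coordinate-system mix-ups).
    """
    known = set(genes["chromosome"].unique())
    missing = sorted({r.chromosome for r in regions} - known)
    if missing:
        raise ValueError(
            f"chromosome labels absent from the annotation: {missing}"
        )
    gsort = genes.sort_values(["chromosome", "start"], kind="mergesort")
    for r in regions:
        sub = gsort[gsort["chromosome"] == r.chromosome]
        hit = (sub["start"] <= r.end) & (sub["end"] >= r.start)
        r.genes = list(sub.loc[hit, "gene_id"])
    return regions


def shared_genes(regions_a: list[Region], regions_b: list[Region]) -> list[str]:
    """Exact intersection of the two per-trait gene-id sets, sorted."""
    ga = {g for r in regions_a for g in r.genes}
    gb = {g for r in regions_b for g in r.genes}
    return sorted(ga & gb)


def region_table(regions: list[Region], trait: str) -> pd.DataFrame:
    """Flat report table (Mb coordinates to 2 decimals, RIS mean and range)."""
    rows = []
    for r in regions:
        mean, lo, hi = r.ris_summary() if r.n_snp else (np.nan,) * 3
        rows.append(
            {
                "trait": trait,
                "bta": r.chromosome,
                "n_snp": r.n_snp,
                "region_start_mb": round(r.start / 1e6, 2),
                "region_end_mb": round(r.end / 1e6, 2),
                "size_mb": round(r.size_mb, 2),
                "ris_mean": round(mean, 2),
                "ris_min": round(lo, 2),
                "ris_max": round(hi, 2),
                "genes": ",".join(r.genes),
            }
        )
    cols = [
        "trait",
        "bta",
        "n_snp",
        "region_start_mb",
        "region_end_mb",
        "size_mb",
        "ris_mean",
        "ris_min",
        "ris_max",
        "genes",
    ]
    return pd.DataFrame(rows, columns=cols)


def export_reports(
    regions_by_trait: dict[str, list[Region]],
    manhattan: pd.DataFrame,
    out_dir,
    threshold: float = 1.0,
) -> dict[str, str]:
    """Write the region TSV, shared-gene list, and Manhattan TSV.

    The Manhattan table carries per-SNP RIS for both traits plus the
    significance threshold value (the dashed-line level in the plot).
    Output bytes are stable given identical inputs.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = [region_table(regs, trait) for trait, regs in regions_by_trait.items()]
    non_empty = [t for t in tables if len(t)]
    merged = pd.concat(non_empty, ignore_index=True) if non_empty else tables[0]
    region_path = out_dir / "regions.tsv"
    merged.to_csv(region_path, sep="\t", index=False)

    paths = {"regions": str(region_path)}
    if len(regions_by_trait) == 2:
        a, b = regions_by_trait.values()
        shared_path = out_dir / "shared_genes.txt"
        shared_path.write_text("\n".join(shared_genes(a, b)) + "\n")
        paths["shared_genes"] = str(shared_path)

    man = manhattan.copy()
    man["threshold"] = threshold
    man_path = out_dir / "manhattan.tsv"
    man.to_csv(man_path, sep="\t", index=False, float_format="%.6g")
    paths["manhattan"] = str(man_path)
    return paths
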