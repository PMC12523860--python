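"""Readers and writers for the standard formats at the pipeline boundary.

Genotypes: PLINK .bed/.bim/.fam (2-bit SNP-major codec) and VCF
(written as text, read through cyvcf2).  Annotation: GFF3 (1-based
closed) and 6-column BED (0-based half-open); both converge on the same
internal 1-based closed gene frame.  Phenotypes: TSV.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, PHENO_COLUMNS, SnpMap

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major mode
# 2-bit codes (per PLINK spec): 00 hom A1, 01 missing, 10 het, 11 hom A2.
# We store the alternate allele as A1, so dosage 2 -> 00, 1 -> 10, 0 -> 11.
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    smap = geno.snp_map
    bim = pd.DataFrame(
        {
            "chrom": smap.chromosome,
            "snp_id": smap.snp_id,
            "cm": 0,
            "pos": smap.position,
            "a1": "B",  # alternate (counted) allele
            "a2": "A",
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": geno.sample_ids,
            "iid": geno.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n = geno.n_samples
    codes = np.empty_like(geno.dosages, dtype=np.uint8)
    for d, c in _DOSAGE_TO_CODE.items():
        codes[geno.dosages == d] = c
    n_bytes = (n + 3) // 4
    padded = np.zeros((n_bytes * 4, geno.n_snps), dtype=np.uint8)
    padded[:n] = codes
    # little-endian within a byte: sample 0 in bits 0-1
    packed = (
        padded[0::4]
        | (padded[1::4] << 2)
        | (padded[2::4] << 4)
        | (padded[3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.T.tobytes())  # SNP-major


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep="\t",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep="\t",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
    )
    smap = SnpMap(
        bim["snp_id"].to_numpy(dtype=object),
        bim["chrom"].to_numpy(),
        bim["pos"].to_numpy(),
    )
    n, p = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
    n_bytes = (n + 3) // 4
    body = raw[3:].reshape(p, n_bytes)
    codes = np.empty((p, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0b11
    codes[:, 1::4] = (body >> 2) & 0b11
    codes[:, 2::4] = (body >> 4) & 0b11
    codes[:, 3::4] = (body >> 6) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T
    return GenotypeMatrix(fam["iid"].to_numpy(dtype=object), smap, dosages)


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gt = {2: "1/1", 1: "0/1", 0: "0/0", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in np.unique(geno.snp_map.chromosome):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, geno.sample_ids))
            + "\n"
        )
        smap = geno.snp_map
        for j in range(geno.n_snps):
            calls = "\t".join(gt[int(d)] for d in geno.dosages[:, j])
            fh.write(
                f"{smap.chromosome[j]}\t{smap.position[j]}\t{smap.snp_id[j]}"
                f"\tA\tB\t.\t.\t.\tGT\t{calls}\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)  # gt_types: 0/1/2 = dosage, 3 = missing
    samples = np.array(vcf.samples, dtype=object)
    ids, chroms, poss, rows = [], [], [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(int(var.CHROM))
        poss.append(var.POS)
        d = var.gt_types.astype(np.int8)
        d[d == 3] = MISSING
        rows.append(d)
    vcf.close()
    smap = SnpMap(np.array(ids, dtype=object), np.array(chroms), np.array(poss))
    return GenotypeMatrix(samples, smap, np.array(rows, dtype=np.int8).T)


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t", dtype={"animal_id": object, "slaughter_date": object})
    missing = [c for c in PHENO_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype TSV missing columns: {missing}")
    return pheno


# --- gene annotation -------------------------------------------------------
# Internal representation: DataFrame(gene_id, chromosome, start, end, name),
# 1-based closed coordinates.

def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            attrs = f"ID={row.gene_id};Name={row.name}"
            fh.write(
                f"{row.chromosome}\tpleionet\tgene\t{row.start}\t{row.end}"
                f"\t.\t+\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}")
            rows.append((gid, int(f[0]), int(f[3]), int(f[4]), attrs.get("Name", gid)))
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "name"])


def write_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """6-column BED; converts 1-based closed to 0-based half-open."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = pd.DataFrame(
        {
            "chrom": genes["chromosome"],
            "start": genes["start"] - 1,
            "end": genes["end"],
            "name": genes["gene_id"],
            "score": 0,
            "strand": "+",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return pd.DataFrame(
        {
            "gene_id": bed["name"],
            "chromosome": bed["chrom"].astype(int),
            "start": bed["start"] + 1,
            "end": bed["end"],
            "name": bed["name"],
        }
    )
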