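"""Synthetic genotypes, pleiotropic QTL effects, and bivariate phenotypes.

The generator emulates the structure the downstream analysis assumes:
biallelic SNPs on several autosomes with block-wise linkage
disequilibrium and paternal half-sib family structure, a polygenic
architecture with partly pleiotropic QTLs, contemporary-group fixed
effects from year x birth-season x herd, additive genetic values with
target heritabilities/genetic correlation, and one trait recorded on
only a subset of animals.

LD model: within fixed-length blocks each haplotype carries a latent
ancestry uniform ``u`` that is re-drawn at recombination points (per
adjacent SNP pair with probability ``recomb_prob``); the allele at SNP j
is ``u < f_j``.  This haplotype-copying scheme preserves per-SNP allele
frequencies exactly in expectation while correlating neighbouring SNPs;
distinct blocks are independent.

Genetic values are constructed as dosages x QTL effects (planting true
positives at known loci for the GWAS) and then conditioned so their
realized (co)variances equal the targets exactly in the metric the
animal model estimates — see :func:`simulate_phenotypes` and
docs/methods.md for the second-moment-matching construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    QTL_NULL,
    QTL_SHARED,
    QTL_TRAIT1,
    QTL_TRAIT2,
    ConfigurationError,
    GenotypeMatrix,
    PHENO_COLUMNS,
    QtlEffects,
    SimulationConfig,
    SnpMap,
)

__all__ = [
    "simulate_genotypes",
    "assign_qtl_effects",
    "simulate_phenotypes",
    "make_annotation",
    "inject_artifacts",
    "SimTruth",
]


def _snp_map(config: SimulationConfig) -> SnpMap:
    per_chrom = config.n_snps // config.n_chromosomes
    chrom = np.repeat(np.arange(1, config.n_chromosomes + 1), per_chrom)
    pos = np.tile(
        (np.arange(per_chrom) + 1) * config.snp_spacing_bp, config.n_chromosomes
    )
    ids = np.array(
        [f"snp{c}_{p}" for c, p in zip(chrom, pos)], dtype=object
    )
    return SnpMap(ids, chrom, pos)


def _block_starts(config: SimulationConfig, smap: SnpMap) -> np.ndarray:
    """SNPs at which linkage is broken (chromosome starts, block edges)."""
    p = len(smap)
    pos, chrom = smap.position, smap.chromosome
    new_chrom = np.ones(p, dtype=bool)
    new_chrom[1:] = chrom[1:] != chrom[:-1]
    if config.ld_block_length > 0:
        block = pos // config.ld_block_length
        new_block = np.ones(p, dtype=bool)
        new_block[1:] = (block[1:] != block[:-1]) | new_chrom[1:]
        return new_block
    return np.ones(p, dtype=bool)  # every SNP independent


def _population_haplotypes(
    rng: np.random.Generator,
    n_hap: int,
    freqs: np.ndarray,
    new_block: np.ndarray,
    recomb_prob: float,
) -> np.ndarray:
    """Haplotype-copying draw of ``n_hap`` haplotypes.

    Each haplotype carries a latent ancestry uniform re-drawn at
    recombination points; allele_j = u < f_j, so marginal frequencies are
    exact while neighbours within a block are correlated.
    """
    p = len(freqs)
    recomb = rng.random((n_hap, p)) < recomb_prob
    recomb |= new_block[None, :]
    idx = np.where(recomb, np.arange(p)[None, :], -1)
    idx = np.maximum.accumulate(idx, axis=1)
    u = rng.random((n_hap, p))
    u_eff = np.take_along_axis(u, idx, axis=1)
    return u_eff < freqs[None, :]


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw an animals x SNPs dosage matrix with block-wise LD and
    paternal half-sib family structure.

    With ``sire_family_size`` k > 1, animals come in families of k that
    share a sire: each offspring receives one recombined sire gamete and
    one population haplotype (dams unrelated), emulating the strong
    paternal family structure of artificial-insemination breeding
    programs.  ``sire_family_size <= 1`` gives unrelated individuals.
    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    smap = _snp_map(config)
    p, n = config.n_snps, config.n_animals
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=p)
    new_block = _block_starts(config, smap)

    maternal = _population_haplotypes(rng, n, freqs, new_block, config.recomb_prob)
    k = max(int(config.sire_family_size), 1)
    if k == 1:
        paternal = _population_haplotypes(rng, n, freqs, new_block, config.recomb_prob)
    else:
        n_sires = -(-n // k)  # ceil
        sire_haps = _population_haplotypes(
            rng, 2 * n_sires, freqs, new_block, config.recomb_prob
        )
        sire_of = np.repeat(np.arange(n_sires), k)[:n]
        # meiosis: switch between the sire's two haplotypes with prob
        # recomb_prob per adjacent pair; independent inheritance per block
        flips = (rng.random((n, p)) < config.recomb_prob).astype(np.int8)
        fresh = rng.random((n, p)) < 0.5
        flips[:, new_block] = fresh[:, new_block]
        state = np.cumsum(flips, axis=1, dtype=np.int64) % 2 == 1
        hap_a = sire_haps[2 * sire_of]
        hap_b = sire_haps[2 * sire_of + 1]
        paternal = np.where(state, hap_b, hap_a)
    dosage = (maternal.astype(np.int8) + paternal.astype(np.int8))

    ids = np.array([f"animal{i:05d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(ids, smap, dosage)


def assign_qtl_effects(smap: SnpMap, config: SimulationConfig) -> QtlEffects:
    """Pick QTL positions and draw their additive effects.

    ``round(shared_fraction * n_qtl)`` QTLs are pleiotropic with effect
    pairs drawn from a bivariate normal (correlation
    ``qtl_effect_corr``); the remainder are split evenly between
    trait-specific QTLs.  All other SNPs get exactly zero effects.
    """
    rng = np.random.default_rng(config.seed + 1)
    p = len(smap)
    if config.n_qtl > p:
        raise ConfigurationError("n_qtl cannot exceed the number of SNPs")
    qtl_idx = rng.choice(p, size=config.n_qtl, replace=False)
    n_shared = int(round(config.shared_fraction * config.n_qtl))
    n_rest = config.n_qtl - n_shared
    n_t1 = n_rest // 2 + n_rest % 2
    n_t2 = n_rest // 2

    mask = np.full(p, QTL_NULL, dtype=np.int8)
    effects = np.zeros((p, 2))

    shared_idx = qtl_idx[:n_shared]
    t1_idx = qtl_idx[n_shared : n_shared + n_t1]
    t2_idx = qtl_idx[n_shared + n_t1 :]

    rho = float(np.clip(config.qtl_effect_corr, -0.99, 0.99))
    cov = np.array([[1.0, rho], [rho, 1.0]])
    if n_shared:
        pairs = rng.multivariate_normal(np.zeros(2), cov, size=n_shared)
        # avoid structurally-zero shared effects (prob 0, but enforce invariant)
        pairs[pairs == 0.0] = 1e-12
        effects[shared_idx] = pairs
        mask[shared_idx] = QTL_SHARED
    if n_t1:
        effects[t1_idx, 0] = rng.standard_normal(n_t1)
        mask[t1_idx] = QTL_TRAIT1
    if n_t2:
        effects[t2_idx, 1] = rng.standard_normal(n_t2)
        mask[t2_idx] = QTL_TRAIT2
    return QtlEffects(effects, mask)


@dataclass
class SimTruth:
    """Latent draws of the simulator, kept for validation.

    ``genetic_values`` are the realized breeding values (n x 2) whose
    sample covariance equals the target genetic covariance exactly;
    ``cg_effects`` maps each animal to its contemporary-group effect.
    """

    genetic_values: np.ndarray
    residuals: np.ndarray
    cg_effects: np.ndarray  # n x 2
    cg_labels: pd.DataFrame  # per-animal CG-defining fields


def _exact_moment_transform(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Linearly transform columns of x so the realized second-moment
    matrix x'x/m equals ``target`` exactly.  Zero target rows/cols come
    out zero."""
    m = x.shape[0]
    live = np.diag(target) > 0
    out = np.zeros_like(x)
    if not live.any():
        return out
    k = int(live.sum())
    xs = x[:, live]
    s = (xs.T @ xs) / m
    lc = np.linalg.cholesky(s)
    lt = np.linalg.cholesky(target[np.ix_(live, live)])
    # whiten with lc^{-1}, recolour with lt
    out[:, live] = np.linalg.solve(lc, xs.T).T @ lt.T
    return out


def _eigen_bands(d: np.ndarray, n_bands: int) -> list[np.ndarray]:
    """Split eigencomponent indices into contiguous bands of similar d."""
    n = len(d)
    edges = np.linspace(0, n, n_bands + 1).astype(int)
    return [np.arange(edges[i], edges[i + 1]) for i in range(n_bands) if edges[i + 1] > edges[i]]


def _pin_contrast_moments(
    g: np.ndarray,
    e: np.ndarray,
    rows: np.ndarray,
    codes_sub: np.ndarray,
    grm: np.ndarray,
    target_g: np.ndarray,
    se_target: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pin genetic/residual second moments on one contrast geometry.

    ``rows`` selects the records whose restricted likelihood is being
    conditioned; the contrast space is the orthocomplement of that row
    set's CG indicator design.  Per eigen-band of the projected GRM, the
    d-profile-normalized genetic components get second moment exactly
    ``target_g``, the residual components (orthogonalized against them)
    exactly ``se_target``.
    """
    g = g.copy()
    e = e.copy()
    codes, _levels = pd.factorize(pd.Series(codes_sub))
    nr = len(rows)
    q = int(codes.max()) + 1
    m = nr - q
    if m < 8:  # too few contrasts to condition on
        return g, e
    x = np.zeros((nr, q))
    x[np.arange(nr), codes] = 1.0
    qf, _ = np.linalg.qr(x, mode="complete")
    qc = qf[:, q:]
    d, u = np.linalg.eigh(qc.T @ grm[np.ix_(rows, rows)] @ qc)
    d = np.maximum(d, 1e-8)
    # bands narrow enough that d is nearly constant within each, so the
    # d-weighted statistics the model estimates from are pinned tightly
    bands = _eigen_bands(d, max(1, m // 25))
    sq = np.sqrt(d)[:, None]

    gs, es = g[rows], e[rows]
    gq = qc.T @ gs
    beta = (u.T @ gq) / sq
    eq = u.T @ (qc.T @ es)
    for band in bands:
        beta[band] = _exact_moment_transform(beta[band], target_g)
        bb = beta[band]
        live = np.abs(bb).sum(axis=0) > 0
        if live.any():
            coef, *_ = np.linalg.lstsq(bb[:, live], eq[band], rcond=None)
            eq[band] = eq[band] - bb[:, live] @ coef
        eq[band] = _exact_moment_transform(eq[band], se_target)
    g[rows] = gs - qc @ gq + qc @ (u @ (beta * sq))
    e[rows] = es - qc @ (qc.T @ es) + qc @ (u @ eq)
    return g, e


def simulate_phenotypes(
    geno: GenotypeMatrix, qtl: QtlEffects, config: SimulationConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Build the bivariate phenotype table.

    phenotype = trait mean + CG effect + genetic value + residual.

    The construction is second-moment matched in the metric the animal
    model estimates: with flat fixed-effect priors the variance-component
    posterior depends on the data only through its projection onto the
    orthocomplement of the contemporary-group design (the REML error
    contrasts).  There, in the eigenbasis of the projected genomic
    relationship matrix, eigencomponents are grouped into bands and, per
    band, the genetic values are transformed so their profile-normalized
    second moment equals the target genetic covariance exactly, while
    the residuals (orthogonalized against the genetic values band-wise)
    hit the diagonal residual covariance exactly.  Variance-component
    estimators therefore see their nominal conditions — the desk-scale
    analog of the large-n limit the real study operates in; without this
    conditioning the realized between-family and between-LD-segment
    components fluctuate enough at n~1000 to dominate parameter-recovery
    comparisons.  A ``missing_trait2_fraction`` of animals lack the WBSF
    record.
    """
    from .varcomp import build_grm  # local import: varcomp does not import simulate

    rng = np.random.default_rng(config.seed + 2)
    n = geno.n_samples
    if qtl.effects.shape[0] != geno.n_snps:
        raise ValueError("QTL effect rows must match the SNP panel")

    target_g = config.genetic_covariance()
    se_target = np.diag(np.asarray(config.residual_variance, dtype=float))
    dos = geno.dosages.astype(np.float64)
    g_raw = dos @ qtl.effects
    g_raw = g_raw - g_raw.mean(axis=0)
    e_raw = rng.standard_normal((n, 2))

    # contemporary-group structure: year, birth month (-> season), herds
    years = rng.integers(config.birth_year_range[0], config.birth_year_range[1] + 1, size=n)
    months = rng.integers(1, 13, size=n)
    herd = rng.integers(0, config.n_herds, size=n)
    herd_names = np.array([f"H{h:02d}" for h in herd], dtype=object)
    # same farm + birth year cohorts are slaughtered on the same date
    slaughter = np.array(
        [f"{y + 2}-{(h % 12) + 1:02d}-15" for y, h in zip(years, herd)], dtype=object
    )

    season = np.where(np.isin(months, (8, 9, 10, 11, 12, 1)), "AugJan", "FebJul")
    cg_key = pd.Series(
        [f"{y}_{s}_{h}" for y, s, h in zip(years, season, herd_names)], dtype=object
    )
    cg_codes, cg_uniques = pd.factorize(cg_key)
    cg_fx = np.column_stack(
        [
            rng.normal(0.0, config.cg_effect_sd[0], size=len(cg_uniques))[cg_codes],
            rng.normal(0.0, config.cg_effect_sd[1], size=len(cg_uniques))[cg_codes],
        ]
    )

    n_miss = int(round(config.missing_trait2_fraction * n))
    miss_idx = rng.choice(n, size=n_miss, replace=False)
    obs2 = np.setdiff1d(np.arange(n), miss_idx)

    grm = build_grm(geno)
    g, e = g_raw, e_raw
    # alternate the pinning between the full-sample contrast geometry
    # (trait-1 records) and the trait-2-observed one; each pass perturbs
    # the other by O(missing fraction), so a few rounds pin both
    spaces = [np.arange(n), obs2] * 2 if n_miss else [np.arange(n)]
    for rows in spaces:
        g, e = _pin_contrast_moments(
            g, e, rows, cg_codes[rows], grm, target_g, se_target
        )
    # CG-space components are absorbed by the fixed effects in every
    # downstream analysis; rescale them to the nominal trait scales so
    # raw phenotype values stay realistic
    x_cg = np.zeros((n, len(cg_uniques)))
    x_cg[np.arange(n), cg_codes] = 1.0
    q_full, _r = np.linalg.qr(x_cg, mode="complete")
    qc = q_full[:, len(cg_uniques):]
    g_cg = g - qc @ (qc.T @ g)
    if np.any(g_cg.std(axis=0) > 0) and np.any(np.diag(target_g) > 0):
        g_cg_new = _exact_moment_transform(g_cg - g_cg.mean(axis=0), target_g)
    else:
        g_cg_new = np.zeros_like(g_cg)
    g = g - g_cg + g_cg_new
    e_cg = e - qc @ (qc.T @ e)
    e_cg_sd = np.where(e_cg.std(axis=0) > 0, e_cg.std(axis=0), 1.0)
    e = e - e_cg + e_cg / e_cg_sd * np.sqrt(np.diag(se_target))[None, :]

    g[:, np.diag(target_g) == 0.0] = 0.0  # zero-heritability traits exactly

    y = np.asarray(config.trait_means) + cg_fx + g + e
    adg = y[:, 0]
    wbsf = y[:, 1].copy()
    wbsf[miss_idx] = np.nan

    pheno = pd.DataFrame(
        {
            "animal_id": geno.sample_ids,
            "adg": adg,
            "wbsf": wbsf,
            "birth_year": years,
            "birth_month": months,
            "herd_birth": herd_names,
            "herd_weaning": herd_names,
            "herd_yearling": herd_names,
            "slaughter_date": slaughter,
        }
    )[PHENO_COLUMNS]
    truth = SimTruth(
        genetic_values=g,
        residuals=e,
        cg_effects=cg_fx,
        cg_labels=pheno[["birth_year", "birth_month", "herd_birth"]].copy(),
    )
    return pheno, truth


def make_annotation(
    smap: SnpMap, gene_density: float, seed: int = 0
) -> pd.DataFrame:
    """Place non-overlapping toy genes along each chromosome.

    ``gene_density`` is genes per Mb.  Returns a frame with columns
    (gene_id, chromosome, start, end, name); coordinates are 1-based
    closed, within chromosome bounds (1 .. max SNP position).
    """
    if gene_density <= 0:
        raise ConfigurationError("gene_density must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for c in np.unique(smap.chromosome):
        length = int(smap.position[smap.chromosome == c].max())
        n_genes = int(round(gene_density * length / 1e6))
        if n_genes == 0:
            continue
        # slot each gene in an equal subdivision so intervals never overlap
        slot = length / n_genes
        for k in range(n_genes):
            lo = int(np.floor(k * slot)) + 1
            hi = int(np.floor((k + 1) * slot))
            span = hi - lo
            glen = max(1, int(span * rng.uniform(0.2, 0.6)))
            start = int(lo + rng.integers(0, max(1, span - glen)))
            end = min(hi, start + glen - 1)
            rows.append((f"GENE{c}_{k:04d}", int(c), start, max(start, end), f"gene{c}.{k}"))
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "name"])


def inject_artifacts(
    geno: GenotypeMatrix,
    missing_rate: float = 0.0,
    n_monomorphic: int = 0,
    n_low_maf: int = 0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, dict[str, np.ndarray]]:
    """Corrupt a clean panel so that QC filters have work to do.

    Designates ``n_monomorphic`` SNPs as single-allele and ``n_low_maf``
    SNPs with MAF ~0.02 (< 0.05), then sprinkles missing calls at
    ``missing_rate`` over the whole matrix.  Designations are disjoint
    (monomorphic takes precedence).  Returns the corrupted matrix and a
    manifest of corrupted SNP ids.
    """
    if n_monomorphic + n_low_maf > geno.n_snps:
        raise ConfigurationError("cannot designate more SNPs than exist")
    rng = np.random.default_rng(seed)
    dos = geno.dosages.copy()
    n = geno.n_samples
    chosen = rng.choice(geno.n_snps, size=n_monomorphic + n_low_maf, replace=False)
    mono_idx = chosen[:n_monomorphic]
    low_idx = chosen[n_monomorphic:]

    dos[:, mono_idx] = 0
    for j in low_idx:
        col = np.zeros(n, dtype=np.int8)
        k = max(1, int(round(0.02 * 2 * n)))  # alt-allele count -> MAF ~0.02
        carriers = rng.choice(n, size=min(k, n), replace=False)
        col[carriers] = 1
        dos[:, j] = col
    if missing_rate > 0:
        mask = rng.random(dos.shape) < missing_rate
        dos[mask] = MISSING
    manifest = {
        "monomorphic": geno.snp_map.snp_id[np.sort(mono_idx)],
        "low_maf": geno.snp_map.snp_id[np.sort(low_idx)],
    }
    return GenotypeMatrix(geno.sample_ids, geno.snp_map, dos), manifest
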