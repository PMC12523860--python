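"""End-to-end orchestration: simulate -> qc -> varcomp -> gwas -> annotate.

A run is configured by a TOML file (or an in-memory dict) validated into
:class:`PipelineConfig`; every stage writes its artifacts under the
output directory and the run closes with a manifest (config snapshot,
per-file checksums, stage wall-clock, QC counts).  Identical configs and
seeds reproduce identical checksums for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gwas, io, qc, regions, simulate, varcomp
from .datatypes import ConfigurationError, SimulationConfig

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]


@dataclass(frozen=True)
class QcSettings:
    min_call_rate: float = 0.90
    min_maf: float = 0.05
    max_hwe_deviation: float = 0.15
    min_sample_call_rate: float = 0.90
    sd_limit: float = 3.5
    min_cg_size: int = 5

    def __post_init__(self) -> None:
        for key in ("min_call_rate", "min_maf", "max_hwe_deviation", "min_sample_call_rate"):
            v = getattr(self, key)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"qc.{key} must be in [0, 1], got {v}")
        if self.sd_limit <= 0:
            raise ValueError("qc.sd_limit must be positive")
        if self.min_cg_size < 1:
            raise ValueError("qc.min_cg_size must be >= 1")


@dataclass(frozen=True)
class ChainSettings:
    n_iter: int = 50_000
    burn_in: int = 5_000
    thin: int = 10


@dataclass(frozen=True)
class GwasSettings:
    cutoff_year: int = 2016
    n_candidates: int = 30
    n_perm_per_snp: int = 10
    null_reps: int = 0  # 0 disables the (expensive) null study
    ris_threshold: float = 1.0
    flank: int = 100_000


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str
    seed: int = 0
    genotypes: str | None = None  # PLINK prefix or .vcf path
    phenotypes: str | None = None
    annotation: str | None = None  # .gff3 or .bed
    simulation: SimulationConfig | None = None
    gene_density: float = 5.0  # genes per Mb for simulated annotation
    qc: QcSettings = field(default_factory=QcSettings)
    chain: ChainSettings = field(default_factory=ChainSettings)
    gwas: GwasSettings = field(default_factory=GwasSettings)
    run_varcomp: bool = True

    def __post_init__(self) -> None:
        has_paths = self.genotypes is not None and self.phenotypes is not None
        if not has_paths and self.simulation is None:
            raise ConfigurationError(
                "config needs either input paths (genotypes+phenotypes) or a "
                "[simulation] section"
            )


_SECTION_TYPES = {
    "qc": QcSettings,
    "chain": ChainSettings,
    "gwas": GwasSettings,
    "simulation": SimulationConfig,
}


def _build_section(cls, data: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ConfigurationError(f"unknown keys under [{path}]: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid [{path}] section: {exc}") from exc


def validate_config(raw: str | dict) -> PipelineConfig:
    """Parse and validate a TOML config text (or pre-parsed dict).

    Defaults are the study's printed thresholds (call rate 0.90, MAF
    0.05, HWE deviation 0.15, 3.5 SD, CG >= 5, flank 100 kb, RIS
    threshold 1%).  Unknown keys are rejected with their paths.
    """
    data = tomllib.loads(raw) if isinstance(raw, str) else dict(raw)
    top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - top_fields
    if unknown:
        raise ConfigurationError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ConfigurationError(f"[{key}] must be a table")
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, key)
        else:
            kwargs[key] = value
    if "out_dir" not in kwargs:
        raise ConfigurationError("config must set out_dir")
    return PipelineConfig(**kwargs)


def config_to_toml(cfg: PipelineConfig) -> str:
    """Serialize a config back to TOML (round-trips through validate_config)."""
    def fmt(v):
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, (int, float)):
            return repr(v)
        if isinstance(v, (tuple, list)):
            return "[" + ", ".join(fmt(x) for x in v) + "]"
        return json.dumps(str(v))

    lines = []
    sections = []
    for f in dataclasses.fields(PipelineConfig):
        v = getattr(cfg, f.name)
        if v is None:
            continue
        if f.name in _SECTION_TYPES:
            sections.append((f.name, v))
        else:
            lines.append(f"{f.name} = {fmt(v)}")
    for name, section in sections:
        lines.append(f"\n[{name}]")
        for sf in dataclasses.fields(section):
            lines.append(f"{sf.name} = {fmt(getattr(section, sf.name))}")
    return "\n".join(lines) + "\n"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order with fail-fast errors.

    Returns the manifest dict (also written to ``out_dir/manifest.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config_to_toml(cfg),
        "seed": cfg.seed,
        "stages": {},
        "files": {},
        "completed": False,
    }
    t0 = time.time()

    def finish_stage(name: str, files: dict[str, Path]) -> None:
        nonlocal t0
        manifest["stages"][name] = {"wall_seconds": round(time.time() - t0, 3)}
        for key, p in files.items():
            manifest["files"][f"{name}:{key}"] = _sha256(Path(p))
        t0 = time.time()

    def write_manifest() -> None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    try:
        # --- inputs ------------------------------------------------------
        if cfg.simulation is not None:
            sim = cfg.simulation
            geno = simulate.simulate_genotypes(sim)
            qtl = simulate.assign_qtl_effects(geno.snp_map, sim)
            pheno, _truth = simulate.simulate_phenotypes(geno, qtl, sim)
            genes = simulate.make_annotation(geno.snp_map, cfg.gene_density, seed=sim.seed + 3)
            io.write_plink(geno, out / "sim_genotypes")
            io.write_phenotypes(pheno, out / "sim_phenotypes.tsv")
            io.write_gff3(genes, out / "sim_genes.gff3")
            finish_stage(
                "simulate",
                {
                    "bed": out / "sim_genotypes.bed",
                    "pheno": out / "sim_phenotypes.tsv",
                    "gff3": out / "sim_genes.gff3",
                },
            )
        else:
            gpath = str(cfg.genotypes)
            geno = io.read_vcf(gpath) if gpath.endswith(".vcf") else io.read_plink(gpath)
            pheno = io.read_phenotypes(cfg.phenotypes)
            if cfg.annotation is None:
                raise ConfigurationError("annotation path required with real inputs")
            genes = (
                io.read_bed(cfg.annotation)
                if str(cfg.annotation).endswith(".bed")
                else io.read_gff3(cfg.annotation)
            )
            finish_stage("load", {})

        # --- qc -----------------------------------------------------------
        geno, rep_samples = qc.filter_samples(geno, cfg.qc.min_sample_call_rate)
        thresholds = qc.MarkerQcThresholds(
            min_call_rate=cfg.qc.min_call_rate,
            min_maf=cfg.qc.min_maf,
            max_hwe_deviation=cfg.qc.max_hwe_deviation,
        )
        geno, rep_markers = qc.filter_markers(geno, thresholds)
        pheno, rep_cg = qc.build_contemporary_groups(pheno)
        pheno, rep_pheno = qc.filter_phenotypes(
            pheno, qc.PhenotypeQcThresholds(cfg.qc.sd_limit, cfg.qc.min_cg_size)
        )
        qc_report = {
            "samples": rep_samples.to_json_dict(),
            "markers": rep_markers.to_json_dict(),
            "contemporary_groups": rep_cg.to_json_dict(),
            "phenotypes": rep_pheno.to_json_dict(),
            "skipped": ["mendelian_conflict (requires pedigree, not modeled)"],
        }
        (out / "qc_report.json").write_text(json.dumps(qc_report, indent=2))
        rep_markers.statistics.to_csv(out / "marker_statistics.tsv", sep="\t", index=False)
        io.write_phenotypes(pheno, out / "phenotypes_qc.tsv")
        manifest["qc_counts"] = qc_report
        finish_stage(
            "qc",
            {
                "report": out / "qc_report.json",
                "marker_stats": out / "marker_statistics.tsv",
                "pheno": out / "phenotypes_qc.tsv",
            },
        )

        # --- variance components -----------------------------------------
        chain = None
        if cfg.run_varcomp:
            grm = varcomp.build_grm(geno)
            frame = varcomp.make_model_frame(pheno, geno.sample_ids)
            chain = varcomp.gibbs_sampler(
                frame,
                grm,
                varcomp.GibbsConfig(
                    n_iter=cfg.chain.n_iter,
                    burn_in=cfg.chain.burn_in,
                    thin=cfg.chain.thin,
                    seed=cfg.seed,
                ),
            )
            summary = varcomp.summarize_posterior(chain)
            summary.to_csv(out / "varcomp_summary.tsv", sep="\t", index=False)
            varcomp.descriptive_table(pheno, chain).to_csv(
                out / "genetic_parameters.tsv", sep="\t", index=False
            )
            pd.DataFrame(chain.scalar_draws()).to_csv(
                out / "varcomp_chain.tsv.gz", sep="\t", index=False
            )
            finish_stage("varcomp", {"summary": out / "varcomp_summary.tsv"})

        # --- gwas ----------------------------------------------------------
        # responses: GEBVs from the animal model when available (the
        # importance scores then read as % of GEBV variability), else
        # CG-adjusted phenotypes
        pheno_idx = pheno.set_index("animal_id").reindex(geno.sample_ids).reset_index()
        responses = chain.gebv if chain is not None else gwas.adjust_for_cg(pheno_idx)
        x, y, _scaler = gwas.standardize(
            np.nan_to_num(geno.dosage_float(), nan=0.0), responses
        )
        split = gwas.forward_split(pheno_idx, cfg.gwas.cutoff_year)
        lam, alpha, tuning = gwas.random_search_tune(
            x[split.train_idx],
            y[split.train_idx],
            n_candidates=cfg.gwas.n_candidates,
            seed=cfg.seed + 10,
            groups=pheno_idx["cg_adg"].to_numpy()[split.train_idx],
        )
        sol = gwas.mt_enet_fit(x[split.train_idx], y[split.train_idx], lam, alpha)
        scores = gwas.permutation_importance(
            sol,
            x[split.validation_idx],
            y[split.validation_idx],
            n_perm_per_snp=cfg.gwas.n_perm_per_snp,
            seed=cfg.seed + 11,
        )
        snp_table = gwas.select_significant(scores, geno.snp_map, cfg.gwas.ris_threshold)
        tuning.to_csv(out / "tuning.tsv", sep="\t", index=False)
        snp_table.to_csv(out / "snp_scores.tsv", sep="\t", index=False)
        gwas_files = {"tuning": out / "tuning.tsv", "scores": out / "snp_scores.tsv"}
        if cfg.gwas.null_reps > 0:
            null = gwas.null_calibration(
                x, y, split, lam, alpha, n_null=cfg.gwas.null_reps, seed=cfg.seed + 12
            )
            (out / "null_calibration.json").write_text(
                json.dumps({"p95": null["p95"], "p99": null["p99"]}, indent=2)
            )
            gwas_files["null"] = out / "null_calibration.json"
        finish_stage("gwas", gwas_files)

        # --- regions -------------------------------------------------------
        regions_by_trait = {}
        for trait in ("adg", "wbsf"):
            sig = snp_table[snp_table[f"significant_{trait}"]]
            regs = regions.cluster_windows(
                sig.rename(columns={f"ris_{trait}": "ris"}), flank=cfg.gwas.flank
            )
            regions_by_trait[trait] = regions.annotate_genes(regs, genes) if len(regs) else regs
        paths = regions.export_reports(
            regions_by_trait, snp_table, out, threshold=cfg.gwas.ris_threshold
        )
        finish_stage("annotate", {k: Path(v) for k, v in paths.items()})

        manifest["completed"] = True
        write_manifest()
        manifest["files"]["manifest"] = _sha256(out / "manifest.json")
        return manifest
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        write_manifest()
        raise
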