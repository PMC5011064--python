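"""Configuration, input loading and the end-to-end pipeline.

The pipeline runs quantification, then splits into two residual branches:
the direct phenotype-association scan and the trans interaction scan use
family/technical-corrected residuals WITHOUT latent-factor correction (factor
correction removes broadly acting variance, including multi-gene trans
regulators), while the cis interaction scan runs on factor-corrected
residuals. Trans seed variants are the FDR-significant step-1 cis hits on
the non-factor branch; mediation is then tested for every trans hit through
its seed variant's cis gene.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .association import residualize_family_technical, transcriptome_scan
from .datatypes import ExpressionMatrix, GenotypeMatrix, MetaExon, SampleMetadata
from .downstream import mediation_table
from .factors import estimate_latent_factors, residualize
from .interaction import cis_interaction_scan, permutation_fdr, trans_interaction_scan
from .quantify import filter_expressed, int_transform_matrix, merge_meta_exons, normalize_depth

log = logging.getLogger(__name__)

__version__ = "0.1.0"


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated pipeline settings; unknown keys are rejected."""

    genotypes: str = ""
    counts: str = ""
    annotation: str = ""
    metadata: str = ""
    depths: str | None = None
    output_dir: str = "results"
    phenotype: str = "bmi"
    tissue: str = "adipose"
    counts_are_raw: bool = False
    min_expressed_fraction: float = 0.90
    window_bp: int = 1_000_000
    min_distance_bp: int = 5_000_000
    n_latent_factors: int = 50
    exclude_factor_corr: float | None = None
    n_perm: int = 100
    n_strata: int = 4
    fdr: float = 0.05
    sobel_p_threshold: float = 0.001
    run_association: bool = True
    run_cis: bool = True
    run_trans: bool = True
    run_mediation: bool = True
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if not 0 < cfg.min_expressed_fraction <= 1:
            raise ConfigError("min_expressed_fraction must lie in (0, 1]")
        if cfg.n_perm < 20:
            raise ConfigError("n_perm must be >= 20")
        if cfg.fdr <= 0 or cfg.fdr >= 1:
            raise ConfigError("fdr must lie in (0, 1)")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_inputs(config: PipelineConfig) -> tuple[GenotypeMatrix, ExpressionMatrix,
                                                 SampleMetadata, list[MetaExon]]:
    """Read all inputs and intersect sample IDs (sorted lexicographically)."""
    geno = gio.read_genotypes(config.genotypes)
    expr = gio.read_counts_tsv(config.counts, state="raw" if config.counts_are_raw else "filtered")
    meta = gio.read_metadata_tsv(config.metadata, phenotype_columns=(config.phenotype,))
    ann_path = Path(config.annotation)
    annotation = gio.read_gtf(ann_path) if ann_path.suffix == ".gtf" else gio.read_bed(ann_path)

    shared = sorted(set(geno.sample_ids) & set(expr.sample_ids) & set(meta.sample_ids))
    for name, ids in (("genotypes", geno.sample_ids), ("expression", expr.sample_ids),
                      ("metadata", meta.sample_ids)):
        dropped = sorted(set(ids) - set(shared))
        if dropped:
            log.info("%s: dropping %d samples absent elsewhere (e.g. %s)",
                     name, len(dropped), dropped[:3])
    if len(shared) < 20:
        raise ConfigError(f"only {len(shared)} samples shared across inputs; need >= 20")
    geno = geno.subset_samples(shared)
    expr = ExpressionMatrix(expr.values[shared], expr.state, expr.gene_ids)
    meta = meta.subset(shared)
    return geno, expr, meta, annotation


@dataclass
class PipelineResults:
    association: pd.DataFrame | None = None
    association_genes: pd.DataFrame | None = None
    cis_interactions: pd.DataFrame | None = None
    trans_interactions: pd.DataFrame | None = None
    trans_threshold: float = np.nan
    mediation: pd.DataFrame | None = None
    factor_phenotype_corr: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig,
                 inputs: tuple | None = None) -> PipelineResults:
    """Execute the full analysis; writes result TSVs plus a JSON manifest.

    ``inputs`` may supply an in-memory ``(geno, expr, meta, annotation)``
    tuple (e.g. a simulated cohort) to skip file loading.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "stages": [],
        "input_checksums": {},
    }
    if inputs is None:
        for key in ("genotypes", "counts", "annotation", "metadata"):
            manifest["input_checksums"][key] = _sha256(getattr(config, key))
        geno, expr, meta, annotation = load_inputs(config)
    else:
        geno, expr, meta, annotation = inputs
    annotation = merge_meta_exons(annotation)
    results = PipelineResults(manifest=manifest)

    def stage(name: str, **info) -> None:
        log.info("stage %s: %s", name, info)
        manifest["stages"].append({"stage": name, **info})

    # quantification ------------------------------------------------------
    if expr.state == "raw":
        if config.depths is None:
            raise ConfigError("raw counts require a per-sample depths file")
        depths = gio.read_depths_tsv(config.depths)
        expr = normalize_depth(expr, depths)
        stage("normalize_depth", n_exons=expr.values.shape[0])
        expr = filter_expressed(expr, config.min_expressed_fraction)
        stage("filter_expressed", n_exons=expr.values.shape[0])
        expr = int_transform_matrix(expr)
    elif expr.state == "filtered":
        expr = int_transform_matrix(expr)
    stage("int_transform", n_exons=expr.values.shape[0], n_samples=expr.n_samples)

    # association branch: no latent-factor correction ----------------------
    if config.run_association:
        assoc, genes = transcriptome_scan(expr, meta, config.phenotype, fdr=config.fdr)
        results.association, results.association_genes = assoc, genes
        assoc.to_csv(outdir / "association.tsv", sep="\t")
        genes.to_csv(outdir / "association_genes.tsv", sep="\t")
        stage("association", n_exons=len(assoc),
              n_genes_associated=int(genes["associated"].sum()))

    # residual branches ----------------------------------------------------
    base_resid = residualize_family_technical(expr, meta)
    stage("residualize_family_technical", n_exons=base_resid.values.shape[0])

    if config.run_cis:
        k = min(config.n_latent_factors, min(base_resid.values.shape) - 1)
        if k != config.n_latent_factors:
            log.warning("reducing latent factor count from %d to %d (matrix size)",
                        config.n_latent_factors, k)
        model = estimate_latent_factors(base_resid, k=k, seed=config.seed,
                                        phenotype=meta.phenotype(config.phenotype))
        results.factor_phenotype_corr = model.phenotype_corr
        model.scores.to_csv(outdir / "factor_scores.tsv", sep="\t")
        stage("latent_factors", k=k,
              max_abs_phenotype_corr=float(model.phenotype_corr["r"].abs().max()))
        cis_input = residualize(base_resid, factors=model,
                                exclude_phenotype_correlated=config.exclude_factor_corr)
        cis = cis_interaction_scan(cis_input, geno, meta, annotation,
                                   config.phenotype, config.window_bp)
        if not cis.empty:
            cis, fdr_summary = permutation_fdr(cis, cis_input, geno, meta,
                                               n_perm=config.n_perm, n_strata=config.n_strata,
                                               seed=config.seed, fdr_threshold=config.fdr,
                                               phenotype_name=config.phenotype)
        results.cis_interactions = cis
        cis.to_csv(outdir / "cis_interactions.tsv", sep="\t", index=False)
        stage("cis_scan", n_pairs=len(cis),
              n_significant=int(cis["significant"].sum()) if "significant" in cis else 0)

    if config.run_trans:
        step1 = cis_interaction_scan(base_resid, geno, meta, annotation,
                                     config.phenotype, config.window_bp)
        seeds: list[str] = []
        if not step1.empty:
            step1, _ = permutation_fdr(step1, base_resid, geno, meta,
                                       n_perm=config.n_perm, n_strata=config.n_strata,
                                       seed=config.seed, fdr_threshold=config.fdr,
                                       phenotype_name=config.phenotype)
            seeds = sorted(step1.loc[step1["significant"], "snp_id"].unique())
        trans, threshold = trans_interaction_scan(seeds, base_resid, geno, meta, annotation,
                                                  config.phenotype, config.min_distance_bp)
        results.trans_interactions, results.trans_threshold = trans, threshold
        trans.to_csv(outdir / "trans_interactions.tsv", sep="\t", index=False)
        stage("trans_scan", n_seed_variants=len(seeds), threshold=threshold,
              n_significant=int(trans["significant"].sum()) if len(trans) else 0)

        if config.run_mediation and len(trans) and trans["significant"].any():
            med_frames = []
            hits = trans[trans["significant"]]
            for snp_id in hits["snp_id"].unique():
                cis_hits = step1[(step1["snp_id"] == snp_id) & step1["significant"]]
                if cis_hits.empty:
                    continue
                mediator_exon = cis_hits.sort_values("p_interaction").iloc[0]["meta_exon_id"]
                med = mediation_table(
                    hits[hits["snp_id"] == snp_id], base_resid.values, mediator_exon,
                    geno.dosages, meta.table[config.phenotype].to_numpy(dtype=float),
                    meta.table["age"].to_numpy(dtype=float),
                    p_threshold=config.sobel_p_threshold,
                )
                med_frames.append(med)
            if med_frames:
                results.mediation = pd.concat(med_frames, ignore_index=True)
                results.mediation.to_csv(outdir / "mediation.tsv", sep="\t", index=False)
                stage("mediation", n_tests=len(results.mediation),
                      n_significant=int(results.mediation["significant"].sum()))
    else:
        stage("trans_scan", skipped=True)

    manifest_json = json.dumps(manifest, indent=1, default=str)
    manifest["manifest_sha256"] = hashlib.sha256(manifest_json.encode()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return results
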