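"""Synthetic twin-cohort generator with planted regulatory effects.

Generates MZ/DZ twin-pair structure, biallelic dosages (optionally in AR(1)
LD blocks), a continuous BMI-like phenotype, exon-level expression with
planted main eQTLs and genotype-by-phenotype interactions (sign-flipping
slopes across homozygote classes), latent confounders correlated with the
phenotype, technical covariates, and cis-mediated trans networks. Every
planted effect is recorded in a :class:`~gxeqtl.datatypes.TruthTable` so
downstream stages can be tested for recovery without external data.

The expression model mirrors the analysis model: on the latent (Gaussian)
scale each meta-exon is a sum of age terms, a phenotype slope, SNP main and
interaction effects, latent-factor loadings, family/zygosity random
intercepts, small technical-covariate effects and Gaussian noise. The
interaction term is generated as ``beta_interaction * (G - 1) * (P - mean P)``
so that the two homozygote classes carry expression-on-phenotype slopes of
opposite sign (+-beta) and the fitted phenotype-x-dosage coefficient equals
``beta_interaction`` whatever the dosage coding, since main effects absorb
the centering terms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    ExpressionMatrix,
    GenotypeMatrix,
    MetaExon,
    PlantedEffect,
    SampleMetadata,
    TruthTable,
)

N_CHROMOSOMES = 22
GENE_SPACING_BP = 200_000
GENE_SPAN_BP = 60_000


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate a single-tissue slice of a two-series female twin
    cohort: 700 samples (240 MZ + 340 DZ twins + 120 unrelated), a BMI-like
    phenotype (mean 25, SD 4), ages uniform on 38-84 years, and dosages with
    MAF in [0.05, 0.5]. Latent-factor defaults plant three phenotype-
    correlated confounders (r = 0.5, 0.35, 0.2) among ``n_latent_factors``,
    matching the situation where a handful of leading expression factors
    track adiposity. Variance components (family 0.06, zygosity 0.06, noise
    0.09 on the latent scale) give MZ/DZ within-pair expression correlations
    of roughly 0.57/0.29 for a purely familial gene.
    """

    n_mz_pairs: int = 120
    n_dz_pairs: int = 170
    n_unrelated: int = 120
    n_snps: int = 20_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int = 1_000
    exons_per_gene_range: tuple[int, int] = (1, 12)
    phenotype_name: str = "bmi"
    phenotype_mean: float = 25.0
    phenotype_sd: float = 4.0
    phenotype_family_frac: float = 0.4  # fraction of phenotype variance shared in-pair
    age_range: tuple[float, float] = (38.0, 84.0)
    n_latent_factors: int = 10
    latent_phenotype_corr: tuple[float, ...] = (0.5, 0.35, 0.2)
    latent_affected_fraction: float = 0.3
    latent_loading_sd: float = 0.25
    var_family: float = 0.06
    var_zygosity: float = 0.06
    var_noise: float = 0.09
    age_effect_sd: float = 0.002   # per year, per exon
    age2_effect_sd: float = 5e-5
    technical_effect_sd: float = 0.03
    ld_rho: float = 0.0            # AR(1) latent-haplotype correlation; 0 = independent loci
    emit_counts: bool = False      # add a negative-binomial-like count layer
    effect_grid: list[PlantedEffect] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mz_pairs", "n_dz_pairs", "n_unrelated", "n_snps", "n_genes",
                     "n_latent_factors"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        lo, hi = self.maf_range
        if not (0.05 - 1e-12 <= lo <= hi <= 0.5 + 1e-12):
            raise ConfigurationError("maf_range must lie within [0.05, 0.5]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigurationError("ld_rho must lie in [0, 1)")
        if self.exons_per_gene_range[0] < 1 or self.exons_per_gene_range[0] > self.exons_per_gene_range[1]:
            raise ConfigurationError("exons_per_gene_range must be 1 <= lo <= hi")

    @property
    def n_samples(self) -> int:
        return 2 * self.n_mz_pairs + 2 * self.n_dz_pairs + self.n_unrelated


@dataclass
class SimulatedCohort:
    """Bundle returned by :func:`simulate_cohort`.

    Iterating yields ``(genotypes, expression, metadata, truth)``; the exon
    annotation and (optional) per-sample read depths ride along as
    attributes.
    """

    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    metadata: SampleMetadata
    truth: TruthTable
    annotation: list[MetaExon]
    well_mapped_reads: pd.Series | None = None
    config: SimulationConfig | None = None

    def __iter__(self):
        return iter((self.genotypes, self.expression, self.metadata, self.truth))


# ---------------------------------------------------------------------------
# layout helpers


def _sample_ids(config: SimulationConfig) -> list[str]:
    ids = []
    for i in range(config.n_mz_pairs):
        ids += [f"MZ{i:04d}a", f"MZ{i:04d}b"]
    for i in range(config.n_dz_pairs):
        ids += [f"DZ{i:04d}a", f"DZ{i:04d}b"]
    ids += [f"S{i:04d}" for i in range(config.n_unrelated)]
    return ids


def _family_structure(config: SimulationConfig) -> pd.DataFrame:
    """family / zygosity codes: co-twins share family; only MZ co-twins share zygosity."""
    rows = []
    fam = 0
    zyg = 0
    for i in range(config.n_mz_pairs):
        rows.append((f"MZ{i:04d}a", f"F{fam:05d}", f"Z{zyg:05d}"))
        rows.append((f"MZ{i:04d}b", f"F{fam:05d}", f"Z{zyg:05d}"))
        fam += 1
        zyg += 1
    for i in range(config.n_dz_pairs):
        rows.append((f"DZ{i:04d}a", f"F{fam:05d}", f"Z{zyg:05d}"))
        zyg += 1
        rows.append((f"DZ{i:04d}b", f"F{fam:05d}", f"Z{zyg:05d}"))
        zyg += 1
        fam += 1
    for i in range(config.n_unrelated):
        rows.append((f"S{i:04d}", f"F{fam:05d}", f"Z{zyg:05d}"))
        fam += 1
        zyg += 1
    df = pd.DataFrame(rows, columns=["sample_id", "family", "zygosity"])
    return df.set_index("sample_id")


def simulate_annotation(config: SimulationConfig) -> list[MetaExon]:
    """Deterministic gene/meta-exon layout across 22 autosomes.

    Genes are laid out round-robin along chromosomes with 200 kb spacing;
    each gene gets 1..k pairwise non-overlapping meta-exons inside a 60 kb
    span, on a random strand.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    lo, hi = config.exons_per_gene_range
    exons: list[MetaExon] = []
    per_chrom = -(-config.n_genes // N_CHROMOSOMES)  # ceil
    for g in range(config.n_genes):
        chrom = f"chr{g % N_CHROMOSOMES + 1}"
        slot = g // N_CHROMOSOMES
        g0 = 1_000_000 + slot * GENE_SPACING_BP
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(lo, hi + 1))
        # partition the span into n_ex disjoint windows, one exon per window
        width = GENE_SPAN_BP // max(n_ex, 1)
        for j in range(n_ex):
            w0 = g0 + j * width
            length = int(rng.integers(80, min(1500, width - 10)))
            start = w0 + int(rng.integers(0, width - length))
            exons.append(MetaExon(f"G{g:04d}", chrom, start, start + length - 1, strand))
    return exons


def _snp_positions(config: SimulationConfig, annotation: list[MetaExon],
                   rng: np.random.Generator) -> pd.DataFrame:
    """Place SNPs gene-anchored (uniform within +-800 kb of each TSS) so every
    gene has cis coverage, with any remainder spread uniformly."""
    tss = {}
    for ex in annotation:
        tss.setdefault(ex.gene_id, (ex.chromosome, ex.tss))
    genes = sorted(tss)
    rows = []
    per_gene = config.n_snps // max(len(genes), 1)
    i = 0
    for g in genes:
        chrom, pos = tss[g]
        for _ in range(per_gene):
            offset = int(rng.integers(-800_000, 800_001))
            rows.append((f"snp{i:06d}", chrom, max(1, pos + offset)))
            i += 1
    while i < config.n_snps:
        g = genes[int(rng.integers(0, len(genes)))]
        chrom, pos = tss[g]
        rows.append((f"snp{i:06d}", chrom, max(1, pos + int(rng.integers(-800_000, 800_001)))))
        i += 1
    df = pd.DataFrame(rows, columns=["snp_id", "chromosome", "position"])
    df = df.sort_values(["chromosome", "position"], kind="mergesort").reset_index(drop=True)
    df["effect_allele"] = "A"
    df["other_allele"] = "G"
    return df.set_index("snp_id")


# ---------------------------------------------------------------------------
# genotypes


def _draw_haplotypes(n_hap: int, freqs: np.ndarray, rho: float,
                     rng: np.random.Generator, chrom_labels: np.ndarray) -> np.ndarray:
    """Haplotype matrix (n_hap x n_snps) of 0/1 alleles.

    With ``rho > 0``, alleles arise by thresholding a latent AR(1) Gaussian
    run left-to-right within each chromosome, giving decaying LD between
    nearby SNPs (a haplotype-block surrogate, not a coalescent model).
    """
    n_snps = len(freqs)
    if rho == 0.0:
        return (rng.random((n_hap, n_snps)) < freqs).astype(np.int8)
    z = np.empty((n_hap, n_snps))
    innov = rng.standard_normal((n_hap, n_snps))
    scale = np.sqrt(1 - rho ** 2)
    prev_chrom = None
    for j in range(n_snps):
        if chrom_labels[j] != prev_chrom:
            z[:, j] = innov[:, j]
            prev_chrom = chrom_labels[j]
        else:
            z[:, j] = rho * z[:, j - 1] + scale * innov[:, j]
    thresh = stats.norm.ppf(freqs)
    return (z < thresh).astype(np.int8)


def simulate_genotypes(config: SimulationConfig,
                       annotation: list[MetaExon] | None = None) -> GenotypeMatrix:
    """Biallelic dosages with twin sharing.

    MZ co-twins receive identical genotype vectors. DZ co-twins share, per
    haplotype, either the whole co-twin haplotype or an independent draw with
    probability 1/2 each (per-locus resampling when loci are independent),
    giving the expected allele-sharing of one half per locus.
    """
    if config.n_samples == 0:
        raise ConfigurationError("cohort has zero samples")
    if config.n_snps == 0:
        raise ConfigurationError("cohort has zero SNPs")
    ss = np.random.SeedSequence([config.seed, 23])
    rng = np.random.default_rng(ss)
    if annotation is None:
        annotation = simulate_annotation(config)
    snp_info = _snp_positions(config, annotation, rng)
    lo, hi = config.maf_range
    if config.ld_rho == 0.0:
        freqs = rng.uniform(lo, hi, size=config.n_snps)
    else:
        # in LD mode neighbouring SNPs need similar allele frequencies, or the
        # attainable dosage correlation is capped well below the latent rho;
        # let the frequency drift slowly along each block
        z = np.empty(config.n_snps)
        z[0] = rng.standard_normal()
        drift = np.sqrt(1 - 0.99 ** 2)
        for j in range(1, config.n_snps):
            z[j] = 0.99 * z[j - 1] + drift * rng.standard_normal()
        freqs = lo + (hi - lo) * stats.norm.cdf(z)
    chrom = snp_info["chromosome"].to_numpy()

    n_founder = config.n_mz_pairs + config.n_dz_pairs + config.n_unrelated
    hap_a = _draw_haplotypes(n_founder, freqs, config.ld_rho, rng, chrom)
    hap_b = _draw_haplotypes(n_founder, freqs, config.ld_rho, rng, chrom)

    rows = []
    idx = 0
    for _ in range(config.n_mz_pairs):
        g = hap_a[idx] + hap_b[idx]
        rows.append(g)
        rows.append(g.copy())
        idx += 1
    if config.n_dz_pairs:
        fresh_a = _draw_haplotypes(config.n_dz_pairs, freqs, config.ld_rho, rng, chrom)
        fresh_b = _draw_haplotypes(config.n_dz_pairs, freqs, config.ld_rho, rng, chrom)
    for k in range(config.n_dz_pairs):
        a1, b1 = hap_a[idx], hap_b[idx]
        if config.ld_rho == 0.0:
            keep_a = rng.random(config.n_snps) < 0.5
            keep_b = rng.random(config.n_snps) < 0.5
            a2 = np.where(keep_a, a1, fresh_a[k])
            b2 = np.where(keep_b, b1, fresh_b[k])
        else:  # whole-haplotype sharing keeps LD intact
            a2 = a1 if rng.random() < 0.5 else fresh_a[k]
            b2 = b1 if rng.random() < 0.5 else fresh_b[k]
        rows.append(a1 + b1)
        rows.append(a2 + b2)
        idx += 1
    for _ in range(config.n_unrelated):
        rows.append(hap_a[idx] + hap_b[idx])
        idx += 1

    dosages = pd.DataFrame(
        np.asarray(rows, dtype=float), index=_sample_ids(config), columns=snp_info.index
    )
    return GenotypeMatrix(dosages, snp_info)


# ---------------------------------------------------------------------------
# metadata / phenotype


def simulate_metadata(config: SimulationConfig) -> SampleMetadata:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 37]))
    fam = _family_structure(config)
    n = config.n_samples
    # phenotype with a within-family shared component
    frac = config.phenotype_family_frac
    fam_codes, fam_idx = np.unique(fam["family"], return_inverse=True)
    shared = rng.standard_normal(len(fam_codes))[fam_idx]
    pheno_z = np.sqrt(frac) * shared + np.sqrt(1 - frac) * rng.standard_normal(n)
    ages = rng.uniform(*config.age_range, size=n)
    # co-twins share age
    half = 2 * (config.n_mz_pairs + config.n_dz_pairs)
    ages[1:half:2] = ages[0:half:2]
    table = pd.DataFrame(
        {
            config.phenotype_name: config.phenotype_mean + config.phenotype_sd * pheno_z,
            "age": np.round(ages, 1),
            "family": fam["family"].to_numpy(),
            "zygosity": fam["zygosity"].to_numpy(),
            "mean_gc": np.round(rng.normal(0.45, 0.012, size=n), 5),
            "insert_size_mode": rng.integers(150, 220, size=n),
            "primer_index": rng.integers(1, 9, size=n).astype(str),
            "batch": rng.integers(1, 5, size=n).astype(str),
        },
        index=fam.index,
    )
    return SampleMetadata(
        table,
        phenotype_columns=(config.phenotype_name,),
        technical_columns=("mean_gc", "insert_size_mode"),
    )


# ---------------------------------------------------------------------------
# expression


def _resolve_effects(config: SimulationConfig, annotation: list[MetaExon],
                     geno: GenotypeMatrix) -> list[PlantedEffect]:
    """Fill in unset gene/SNP IDs: unused genes; the SNP nearest the TSS."""
    tss = {}
    for ex in annotation:
        if ex.gene_id not in tss:
            tss[ex.gene_id] = (ex.chromosome, ex.tss)
    used = {e.gene_id for e in config.effect_grid if e.gene_id}
    free = [g for g in sorted(tss) if g not in used]
    resolved = []
    snp_by_chrom = {c: sub for c, sub in geno.snp_info.groupby("chromosome")}
    first_gxe: str | None = None
    for eff in config.effect_grid:
        eff = dataclasses.replace(eff)
        if eff.kind == "trans_mediated":
            if eff.mediator_gene_id == "__first_gxe__":
                if first_gxe is None:
                    raise ConfigurationError(
                        "trans network requested before any gxe_interaction in the grid"
                    )
                eff.mediator_gene_id = first_gxe
            resolved.append(eff)
            continue
        if not eff.gene_id:
            if not free:
                raise ConfigurationError("no free genes left to assign planted effects")
            eff.gene_id = free.pop(0)
        if eff.gene_id not in tss:
            raise ConfigurationError(f"planted effect references unknown gene {eff.gene_id!r}")
        if not eff.snp_id:
            chrom, pos = tss[eff.gene_id]
            cand = snp_by_chrom.get(chrom)
            if cand is None or cand.empty:
                if eff.beta_snp == 0.0 and eff.beta_interaction == 0.0:
                    # purely phenotypic effect: any placeholder SNP will do
                    eff.snp_id = geno.snp_info.index[0]
                else:
                    raise ConfigurationError(f"no SNPs on {chrom} for gene {eff.gene_id}")
            else:
                eff.snp_id = (cand["position"] - pos).abs().idxmin()
        if eff.snp_id not in geno.snp_info.index:
            raise ConfigurationError(f"planted effect references unknown SNP {eff.snp_id!r}")
        if eff.kind == "gxe_interaction" and first_gxe is None:
            first_gxe = eff.gene_id
        resolved.append(eff)
    return resolved


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate genotypes, expression, metadata and the truth table.

    Expression is produced on a latent Gaussian scale (see module docstring).
    With ``emit_counts=True`` an additional overdispersed count layer is
    written instead, with per-sample sequencing depths in
    ``cohort.well_mapped_reads``; otherwise the continuous matrix is returned
    in the ``filtered`` state, ready for inverse-normal transformation.
    """
    annotation = simulate_annotation(config)
    geno = simulate_genotypes(config, annotation)
    meta = simulate_metadata(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 53]))

    n = config.n_samples
    exon_ids = [ex.meta_exon_id for ex in annotation]
    gene_of_exon = np.array([ex.gene_id for ex in annotation])
    n_exons = len(annotation)

    pheno = meta.table[config.phenotype_name].to_numpy()
    pheno_c = pheno - pheno.mean()
    pheno_z = pheno_c / pheno.std()
    age_c = meta.table["age"].to_numpy() - meta.table["age"].mean()

    # latent confounders: scores sample x k, phenotype-correlated per config
    k = config.n_latent_factors
    corr = np.zeros(k)
    corr[: len(config.latent_phenotype_corr)] = config.latent_phenotype_corr[:k]
    scores = np.empty((n, k))
    for j in range(k):
        scores[:, j] = corr[j] * pheno_z + np.sqrt(1 - corr[j] ** 2) * rng.standard_normal(n)
    loadings = np.zeros((n_exons, k))
    for j in range(k):
        hit = rng.random(n_exons) < config.latent_affected_fraction
        loadings[hit, j] = rng.normal(0, config.latent_loading_sd, size=hit.sum())

    # family / zygosity random intercepts (gene-level, shared by a gene's exons)
    genes = sorted(set(gene_of_exon))
    fam_codes, fam_idx = np.unique(meta.table["family"], return_inverse=True)
    zyg_codes, zyg_idx = np.unique(meta.table["zygosity"], return_inverse=True)
    gene_pos = {g: i for i, g in enumerate(genes)}
    u_fam = rng.normal(0, np.sqrt(config.var_family), size=(len(genes), len(fam_codes)))
    u_zyg = rng.normal(0, np.sqrt(config.var_zygosity), size=(len(genes), len(zyg_codes)))

    beta_age = rng.normal(0, config.age_effect_sd, size=n_exons)
    beta_age2 = rng.normal(0, config.age2_effect_sd, size=n_exons)
    gc_z = (meta.table["mean_gc"].to_numpy() - 0.45) / 0.012
    beta_gc = rng.normal(0, config.technical_effect_sd, size=n_exons)

    values = (
        beta_age[:, None] * age_c[None, :]
        + beta_age2[:, None] * (age_c[None, :] ** 2)
        + beta_gc[:, None] * gc_z[None, :]
        + loadings @ scores.T
    )
    gene_row = np.array([gene_pos[g] for g in gene_of_exon])
    values += u_fam[gene_row][:, fam_idx]
    values += u_zyg[gene_row][:, zyg_idx]
    values += rng.normal(0, np.sqrt(config.var_noise), size=(n_exons, n))

    truth = TruthTable(latent_scores=pd.DataFrame(
        scores, index=meta.sample_ids, columns=[f"LF{j + 1}" for j in range(k)]
    ))
    effects = _resolve_effects(config, annotation, geno)
    exprs = pd.DataFrame(values, index=exon_ids, columns=meta.sample_ids)

    trans_effects = []
    for eff in effects:
        if eff.kind == "trans_mediated":
            trans_effects.append(eff)
            continue
        g = geno.dosages[eff.snp_id].to_numpy()
        rows = gene_of_exon == eff.gene_id
        contrib = (
            eff.beta_snp * (g - g.mean())
            + eff.beta_pheno * pheno_c
            + eff.beta_interaction * (g - 1.0) * pheno_c
        )
        exprs.loc[rows] += contrib
        truth.add(eff)

    expression = ExpressionMatrix(exprs, state="filtered")
    cohort = SimulatedCohort(geno, expression, meta, truth, annotation, config=config)

    for eff in trans_effects:
        cohort = plant_trans_network(
            cohort,
            mediator_gene=eff.mediator_gene_id,
            n_targets=eff.n_trans_targets,
            mediation_fraction=eff.mediation_fraction,
            beta_interaction=eff.beta_interaction,
        )

    if config.emit_counts:
        _add_count_layer(cohort, rng)
    return cohort


def _add_count_layer(cohort: SimulatedCohort, rng: np.random.Generator) -> None:
    """Overdispersed count layer: Poisson around a per-exon base abundance
    scaled by sample depth and exp(latent expression)."""
    y = cohort.expression.values.to_numpy()
    n_exons, n = y.shape
    base = np.exp(rng.normal(3.2, 1.1, size=n_exons))
    # a slice of lowly expressed exons to exercise the expressed-fraction filter
    base[rng.random(n_exons) < 0.05] *= 0.01
    depths = rng.uniform(1.2e7, 3.2e7, size=n)
    lam = base[:, None] * (depths[None, :] / 2.0e7) * np.exp(0.6 * y)
    counts = rng.poisson(lam).astype(float)
    cohort.expression = ExpressionMatrix(
        pd.DataFrame(counts, index=cohort.expression.meta_exon_ids,
                     columns=cohort.expression.sample_ids),
        state="raw",
    )
    cohort.well_mapped_reads = pd.Series(
        depths.round().astype(int), index=cohort.expression.sample_ids, name="well_mapped_reads"
    )


def plant_trans_network(cohort: SimulatedCohort, mediator_gene: str,
                        n_targets: int, mediation_fraction: float,
                        beta_interaction: float = 0.06,
                        target_genes: list[str] | None = None) -> SimulatedCohort:
    """Route an interaction signal through a cis mediator into trans targets.

    Each target gene's expression gains ``mediation_fraction`` of its
    interaction signal transmitted through the realized mediator expression
    (its first meta-exon) and ``1 - mediation_fraction`` directly, so that
    conditioning on the mediator removes exactly the mediated share. Targets
    default to unused genes on other chromosomes than the mediator SNP.
    """
    if not 0.0 <= mediation_fraction <= 1.0:
        raise ConfigurationError("mediation_fraction must lie in [0, 1]")
    med_effects = [e for e in cohort.truth.by_gene(mediator_gene)
                   if e.kind == "gxe_interaction" and e.beta_interaction != 0]
    if not med_effects:
        raise ConfigurationError(
            f"mediator gene {mediator_gene!r} carries no planted gxe_interaction"
        )
    med = med_effects[0]
    snp_chrom = cohort.genotypes.snp_info.loc[med.snp_id, "chromosome"]

    exon_gene = cohort.expression.gene_ids
    mediator_exon = exon_gene[exon_gene == mediator_gene].index[0]
    e_m = cohort.expression.values.loc[mediator_exon].to_numpy()

    if target_genes is None:
        taken = {e.gene_id for e in cohort.truth.effects} | {mediator_gene}
        chrom_of_gene = {}
        for ex in cohort.annotation:
            chrom_of_gene.setdefault(ex.gene_id, ex.chromosome)
        target_genes = [g for g in sorted(chrom_of_gene)
                        if g not in taken and chrom_of_gene[g] != snp_chrom][:n_targets]
    if len(target_genes) < n_targets:
        raise ConfigurationError("not enough free genes for the requested trans targets")

    g = cohort.genotypes.dosages[med.snp_id].to_numpy()
    pheno = cohort.metadata.table[cohort.metadata.phenotype_columns[0]].to_numpy()
    pheno_c = pheno - pheno.mean()
    direct = (1.0 - mediation_fraction) * beta_interaction * (g - 1.0) * pheno_c
    c_med = mediation_fraction * beta_interaction / med.beta_interaction

    values = cohort.expression.values.copy()
    for tg in target_genes:
        rows = exon_gene[exon_gene == tg].index
        values.loc[rows] += c_med * e_m + direct
        cohort.truth.add(PlantedEffect(
            kind="trans_mediated", gene_id=tg, snp_id=med.snp_id,
            beta_interaction=beta_interaction, mediator_gene_id=mediator_gene,
            mediation_fraction=mediation_fraction,
        ))
    new_expr = ExpressionMatrix(values, cohort.expression.state, cohort.expression.gene_ids)
    return SimulatedCohort(cohort.genotypes, new_expr, cohort.metadata, cohort.truth,
                           cohort.annotation, cohort.well_mapped_reads, cohort.config)


def standard_effect_grid(n_main: int = 10, n_gxe: int = 8,
                         trans_targets: int = 20, seed: int = 0) -> list[PlantedEffect]:
    """A representative planted-effect grid: main eQTLs (0.2-0.5 SD/allele),
    interactions spanning the 0.02-0.06 SD/(allele x phenotype-unit) range,
    and one mediated trans network seeded by the first interaction gene."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 71]))
    grid: list[PlantedEffect] = []
    for _ in range(n_main):
        grid.append(PlantedEffect("main_eqtl", gene_id="", snp_id="",
                                  beta_snp=float(rng.uniform(0.2, 0.5))))
    for i in range(n_gxe):
        sign = -1.0 if rng.random() < 0.5 else 1.0
        # the first interaction seeds the trans network, so it gets the top of
        # the magnitude range — a multi-gene trans regulator is only
        # discoverable when its own cis interaction is decisive
        beta = 0.06 if i == 0 else float(rng.uniform(0.02, 0.06))
        grid.append(PlantedEffect("gxe_interaction", gene_id="", snp_id="",
                                  beta_snp=float(rng.uniform(0.1, 0.3)),
                                  beta_interaction=sign * beta))
    if trans_targets:
        grid.append(PlantedEffect(
            "trans_mediated", gene_id="", snp_id="", beta_interaction=0.06,
            mediator_gene_id="__first_gxe__", n_trans_targets=trans_targets,
        ))
    return grid
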