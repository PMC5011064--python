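"""Genotype-by-phenotype interaction scans with permutation FDR.

The cis scan tests, for every meta-exon, each SNP within a window of the
gene's TSS under the interaction model

    y ~ intercept + age + age^2 + phenotype + dosage + phenotype x dosage

by OLS, with a Wald t-test on the interaction coefficient. Significance is
calibrated by an approximate permutation scheme: per exon-SNP pair, the
residuals after regressing out all main effects (phenotype, dosage, age) are
permuted across samples and the interaction p-value is recomputed, so the
null preserves genotype structure. Because multi-exon genes get more shots
at a small p-value, the empirical FDR is computed within strata of genes
with similar expressed-exon counts. The trans scan tests a small set of
cis-significant seed variants against all exons beyond a 5 Mb exclusion zone
(or on other chromosomes), Bonferroni-corrected for variants x exons.

Interaction terms are fitted with mean-centered phenotype and dosage; with
all main effects in the model the interaction coefficient, its SE and its
p-value are identical to the raw-product parameterization, but the design is
far better conditioned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .datatypes import ExpressionMatrix, GenotypeMatrix, MetaExon, SampleMetadata

log = logging.getLogger(__name__)

INTERACTION_COLUMNS = [
    "meta_exon_id", "gene_id", "snp_id", "beta_pheno", "beta_snp",
    "beta_interaction", "se_interaction", "p_interaction", "p_main",
]


@dataclass
class PermutationFDRResult:
    """Per-stratum permutation-FDR summary."""

    strata: pd.DataFrame         # stratum, exon-count range, n pairs, n significant
    n_permutations: int
    n_strata: int


def _ols_stats(X: np.ndarray, Y: np.ndarray):
    """OLS for one design and one-or-many response columns.

    Returns (beta (p x m), se (p x m), t, p, df). ``Y`` may be 1-D.
    """
    y2d = Y if Y.ndim == 2 else Y[:, None]
    n, p = X.shape
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ y2d)
    resid = y2d - X @ beta
    df = n - p
    sigma2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    # stdtr is the t CDF; two-sided p without the rv-machinery overhead
    pvals = 2.0 * special.stdtr(df, -np.abs(t))
    if Y.ndim == 1:
        return beta[:, 0], se[:, 0], t[:, 0], pvals[:, 0], df
    return beta, se, t, pvals, df


def interaction_design(age: np.ndarray, pheno: np.ndarray, dosage: np.ndarray) -> np.ndarray:
    """Model-2 design matrix: [1, age_c, age_c^2, pheno_c, dosage_c, pheno_c*dosage_c]."""
    age_c = age - age.mean()
    p_c = pheno - pheno.mean()
    g_c = dosage - dosage.mean()
    return np.column_stack([np.ones_like(age_c), age_c, age_c ** 2, p_c, g_c, p_c * g_c])


def fit_interaction_model(age: np.ndarray, pheno: np.ndarray, dosage: np.ndarray,
                          y: np.ndarray) -> dict:
    """One exon-SNP pair: interaction model plus the no-interaction model
    (whose dosage p-value is the main-effect eQTL test)."""
    X = interaction_design(age, pheno, dosage)
    beta, se, t, p, _ = _ols_stats(X, y)
    Xm = X[:, :5]
    bm, sm, tm, pm, _ = _ols_stats(Xm, y)
    return {
        "beta_pheno": beta[3], "beta_snp": beta[4],
        "beta_interaction": beta[5], "se_interaction": se[5],
        "p_interaction": p[5],
        "beta_main": bm[4], "p_main": pm[4],
    }


def _tss_index(annotation: list[MetaExon]) -> dict[str, MetaExon]:
    return {ex.meta_exon_id: ex for ex in annotation}


def cis_interaction_scan(expr: ExpressionMatrix, geno: GenotypeMatrix,
                         metadata: SampleMetadata, annotation: list[MetaExon],
                         phenotype_name: str = "bmi",
                         window_bp: int = 1_000_000) -> pd.DataFrame:
    """Test every SNP within ``window_bp`` of each meta-exon's TSS."""
    expr.require_state("residualized", "int_transformed")
    meta = metadata.subset(expr.sample_ids)
    geno = geno.subset_samples(expr.sample_ids)
    age = meta.table["age"].to_numpy(dtype=float)
    pheno = meta.table[phenotype_name].to_numpy(dtype=float)
    exon_map = _tss_index(annotation)
    snp_pos = geno.snp_info.sort_values(["chromosome", "position"])
    by_chrom = {c: sub for c, sub in snp_pos.groupby("chromosome")}
    dosage_np = geno.dosages.to_numpy(dtype=float)
    snp_col = {s: j for j, s in enumerate(geno.dosages.columns)}

    rows = []
    vals = expr.values.to_numpy(dtype=float)
    for i, mid in enumerate(expr.meta_exon_ids):
        ex = exon_map.get(str(mid))
        if ex is None:
            raise KeyError(f"meta-exon {mid!r} absent from the annotation")
        sub = by_chrom.get(ex.chromosome)
        if sub is None:
            log.info("no SNPs on %s for %s", ex.chromosome, mid)
            continue
        near = sub[(sub["position"] - ex.tss).abs() <= window_bp]
        if near.empty:
            log.info("no cis SNPs within %d bp of %s", window_bp, mid)
            continue
        y = vals[i]
        for snp_id in near.index:
            g = dosage_np[:, snp_col[snp_id]]
            if g.std() == 0:
                log.info("monomorphic SNP %s skipped for %s", snp_id, mid)
                continue
            st = fit_interaction_model(age, pheno, g, y)
            rows.append({"meta_exon_id": str(mid), "gene_id": ex.gene_id,
                         "snp_id": snp_id, **st})
    cols = INTERACTION_COLUMNS + ["beta_main"]
    out = pd.DataFrame(rows, columns=cols if rows else cols)
    return out.sort_values(["meta_exon_id", "snp_id"], kind="mergesort").reset_index(drop=True)


def _exon_count_strata(expr: ExpressionMatrix, n_strata: int) -> pd.Series:
    """Gene-level stratum labels from quantiles of expressed-exon counts."""
    exon_counts = expr.gene_ids.value_counts()
    qs = np.quantile(exon_counts.to_numpy(), np.linspace(0, 1, n_strata + 1))
    qs[0], qs[-1] = -np.inf, np.inf
    # collapse duplicate boundaries (many genes can share an exon count)
    edges = np.unique(qs)
    labels = pd.cut(exon_counts, bins=edges, labels=False, duplicates="drop")
    return labels.astype(int)


def permutation_fdr(observed: pd.DataFrame, expr: ExpressionMatrix, geno: GenotypeMatrix,
                    metadata: SampleMetadata, n_perm: int = 100, n_strata: int = 4,
                    seed: int = 0, fdr_threshold: float = 0.05,
                    phenotype_name: str = "bmi") -> tuple[pd.DataFrame, PermutationFDRResult]:
    """Exon-count-stratified empirical FDR for an interaction-scan table.

    Per pair, main effects (phenotype, dosage, age) are regressed out, the
    residuals are permuted (the same ``n_perm`` sample permutations across
    all pairs, preserving genotype structure) and the interaction p-value is
    recomputed. FDR(t) = mean permuted count of p <= t per permutation,
    divided by the observed count of p <= t, within stratum, then monotonized
    to be non-decreasing in p. FDR estimates of exactly zero mean no permuted
    statistic beat the threshold: the resolution floor is
    1 / (n_perm * observed count).
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20 for a usable FDR estimate")
    if observed.empty:
        raise ValueError("observed interaction table is empty")
    meta = metadata.subset(expr.sample_ids)
    geno = geno.subset_samples(expr.sample_ids)
    age = meta.table["age"].to_numpy(dtype=float)
    pheno = meta.table[phenotype_name].to_numpy(dtype=float)
    n = len(age)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)], axis=1)  # n x n_perm

    gene_strata = _exon_count_strata(expr, n_strata)
    pair_strata = observed["gene_id"].map(gene_strata).to_numpy()

    vals = expr.values.to_numpy(dtype=float)
    exon_row = {m: i for i, m in enumerate(expr.meta_exon_ids)}
    dosage_np = geno.dosages.to_numpy(dtype=float)
    snp_col = {s: j for j, s in enumerate(geno.dosages.columns)}
    perm_ps = np.empty((len(observed), n_perm))
    for row_i, row in enumerate(observed.itertuples(index=False)):
        y = vals[exon_row[row.meta_exon_id]]
        g = dosage_np[:, snp_col[row.snp_id]]
        X = interaction_design(age, pheno, g)
        # regress out all main effects for this pair, permute the residuals
        Xm = X[:, :5]
        bm, *_ = np.linalg.lstsq(Xm, y, rcond=None)
        r = y - Xm @ bm
        Yp = r[perms]  # n x n_perm
        _, _, _, pcols, _ = _ols_stats(X, Yp)
        perm_ps[row_i] = pcols[5]

    obs_p = observed["p_interaction"].to_numpy(dtype=float)
    fdr = np.ones(len(observed))
    strat_rows = []
    for s in np.unique(pair_strata):
        mask = pair_strata == s
        po = obs_p[mask]
        pp = np.sort(perm_ps[mask].ravel())
        order = np.argsort(po, kind="mergesort")
        ranked = po[order]
        perm_count = np.searchsorted(pp, ranked, side="right") / n_perm
        raw = perm_count / np.arange(1, len(ranked) + 1)
        mono = np.minimum.accumulate(raw[::-1])[::-1]
        mono = np.clip(mono, 0.0, 1.0)
        out = np.empty(len(ranked))
        out[order] = mono
        fdr[mask] = out
        strat_rows.append({
            "stratum": int(s), "n_pairs": int(mask.sum()),
            "n_significant": int((out <= fdr_threshold).sum()),
        })

    annotated = observed.copy()
    annotated["stratum"] = pair_strata
    annotated["fdr"] = fdr
    annotated["significant"] = annotated["fdr"] <= fdr_threshold
    summary = PermutationFDRResult(pd.DataFrame(strat_rows), n_perm, n_strata)
    return annotated, summary


def trans_interaction_scan(seed_variants: list[str], expr: ExpressionMatrix,
                           geno: GenotypeMatrix, metadata: SampleMetadata,
                           annotation: list[MetaExon], phenotype_name: str = "bmi",
                           min_distance_bp: int = 5_000_000) -> tuple[pd.DataFrame, float]:
    """Test each seed variant against every expressed exon farther than
    ``min_distance_bp`` (or on another chromosome).

    The significance threshold is the Bonferroni bound
    0.05 / (n_variants x n_exons), where n_exons counts all expressed exons,
    and is returned alongside the table.
    """
    if not seed_variants:
        log.warning("empty seed-variant list; trans scan skipped")
        return pd.DataFrame(columns=INTERACTION_COLUMNS + ["beta_main", "significant"]), np.nan
    expr.require_state("residualized", "int_transformed")
    meta = metadata.subset(expr.sample_ids)
    geno = geno.subset_samples(expr.sample_ids)
    age = meta.table["age"].to_numpy(dtype=float)
    pheno = meta.table[phenotype_name].to_numpy(dtype=float)
    exon_map = _tss_index(annotation)
    n_exons = expr.values.shape[0]
    threshold = 0.05 / (len(seed_variants) * n_exons)

    vals = expr.values.to_numpy(dtype=float)
    rows = []
    for snp_id in seed_variants:
        chrom = geno.snp_info.loc[snp_id, "chromosome"]
        pos = geno.snp_info.loc[snp_id, "position"]
        g = geno.dosages[snp_id].to_numpy(dtype=float)
        for i, mid in enumerate(expr.meta_exon_ids):
            ex = exon_map[str(mid)]
            if ex.chromosome == chrom and abs(ex.tss - pos) <= min_distance_bp:
                continue
            st = fit_interaction_model(age, pheno, g, vals[i])
            rows.append({"meta_exon_id": str(mid), "gene_id": ex.gene_id,
                         "snp_id": snp_id, **st})
    out = pd.DataFrame(rows, columns=INTERACTION_COLUMNS + ["beta_main"])
    out["significant"] = out["p_interaction"] < threshold
    out = out.sort_values(["snp_id", "meta_exon_id"], kind="mergesort").reset_index(drop=True)
    return out, threshold


def bonferroni_threshold(alpha: float, n_variants: int, n_exons: int) -> float:
    """Family-wise threshold alpha / (variants x exons) for the trans scan."""
    return alpha / (n_variants * n_exons)
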