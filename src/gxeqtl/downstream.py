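"""Mediation of trans networks, RTC colocalization, and annotation matching.

Mediation: for a trans target gene, the interaction model is fitted twice,
without (Model A) and with (Model B) the cis mediator's expression as a
covariate. The mediation score is the relative drop of the interaction
coefficient, (bA - bB) / bA, and the significance of the change is assessed
with Sobel's statistic Z = bA*bB / sqrt(bB^2 sA^2 + bA^2 sB^2) against the
standard normal (two-sided).

RTC (regulatory trait concordance): within a window around a GWAS index SNP,
the eQTL interaction signal is refitted conditioning on each window SNP in
turn; SNPs are ranked by how strongly their conditioning abrogates the
signal (rank 1 = the conditional p left LEAST significant), and
RTC = (N - rank_of_GWAS_SNP) / N, approaching 1 when the GWAS SNP explains
the regulatory signal and ~0.5 for independent signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, MetaExon
from .interaction import _ols_stats


@dataclass
class MediationResult:
    beta_unconditioned: float   # interaction coefficient without the mediator
    se_unconditioned: float
    beta_conditioned: float     # interaction coefficient given the mediator
    se_conditioned: float
    mediation_score: float      # (bA - bB) / bA
    sobel_z: float
    sobel_p: float
    significant: bool
    undefined: bool = False


def mediation_test(trans_expr: np.ndarray, cis_expr: np.ndarray, genotype: np.ndarray,
                   phenotype: np.ndarray, age: np.ndarray,
                   p_threshold: float = 0.001) -> MediationResult:
    """Sobel mediation of a trans interaction through a cis mediator gene.

    Model A: y ~ 1 + A + A^2 + P + G + PxG.
    Model B: the same plus the mediator expression E.
    ``p_threshold`` is the call threshold on the Sobel p-value (default
    0.001).
    """
    y = np.asarray(trans_expr, dtype=float)
    e = np.asarray(cis_expr, dtype=float)
    g = np.asarray(genotype, dtype=float)
    p = np.asarray(phenotype, dtype=float)
    a = np.asarray(age, dtype=float)
    a_c, p_c, g_c = a - a.mean(), p - p.mean(), g - g.mean()
    ones = np.ones_like(y)
    XA = np.column_stack([ones, a_c, a_c ** 2, p_c, g_c, p_c * g_c])
    XB = np.column_stack([ones, e, a_c, a_c ** 2, p_c, g_c, p_c * g_c])
    bA, sA, *_ = _ols_stats(XA, y)
    bB, sB, *_ = _ols_stats(XB, y)
    b5, s5 = float(bA[5]), float(sA[5])
    b6, s6 = float(bB[6]), float(sB[6])
    undefined = b5 == 0.0
    score = np.nan if undefined else (b5 - b6) / b5
    denom = np.sqrt(b6 ** 2 * s5 ** 2 + b5 ** 2 * s6 ** 2)
    z = (b5 * b6) / denom if denom > 0 else np.nan
    pz = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
    return MediationResult(
        beta_unconditioned=b5, se_unconditioned=s5,
        beta_conditioned=b6, se_conditioned=s6,
        mediation_score=float(score), sobel_z=float(z), sobel_p=float(pz),
        significant=bool(np.isfinite(pz) and pz <= p_threshold),
        undefined=undefined,
    )


def mediation_table(trans_hits: pd.DataFrame, expr_values: pd.DataFrame,
                    mediator_exon: str, geno_dosages: pd.DataFrame,
                    phenotype: np.ndarray, age: np.ndarray,
                    p_threshold: float = 0.001) -> pd.DataFrame:
    """Run :func:`mediation_test` for every (trans exon, seed SNP) hit."""
    rows = []
    e = expr_values.loc[mediator_exon].to_numpy(dtype=float)
    for hit in trans_hits.itertuples(index=False):
        if hit.meta_exon_id == mediator_exon:
            continue
        res = mediation_test(
            expr_values.loc[hit.meta_exon_id].to_numpy(dtype=float), e,
            geno_dosages[hit.snp_id].to_numpy(dtype=float), phenotype, age,
            p_threshold=p_threshold,
        )
        rows.append({"meta_exon_id": hit.meta_exon_id, "gene_id": hit.gene_id,
                     "snp_id": hit.snp_id, "mediator_exon": mediator_exon,
                     **res.__dict__})
    return pd.DataFrame(rows)


@dataclass
class RTCResult:
    n_snps: int
    rank_gwas: int
    rtc: float
    conditional_pvalues: pd.DataFrame  # per window SNP: conditional p of the eQTL interaction


def rtc_score(target_expr: np.ndarray, phenotype: np.ndarray,
              window_genotypes: GenotypeMatrix, eqtl_snp_id: str, gwas_snp_id: str,
              mode: str = "interaction") -> RTCResult:
    """Regulatory trait concordance for an eQTL/GWAS SNP pair.

    For every window SNP_N the conditional model is fitted:
    mode='interaction':  y ~ 1 + P x SNP_N + P x eQTL,
    mode='main':         y ~ 1 + SNP_N     + P x eQTL,
    and the p-value of the P x eQTL term is recorded. SNPs are ranked by
    DECREASING conditional p (rank 1 = conditioning abrogated the signal
    most); ties break by genomic position. A window SNP numerically collinear
    with the eQTL regressor (e.g. the eQTL SNP itself) is assigned
    conditional p = 1.
    """
    if mode not in ("interaction", "main"):
        raise ValueError(f"mode must be 'interaction' or 'main', got {mode!r}")
    snps = window_genotypes.snp_ids
    if len(snps) < 10:
        raise ValueError("need at least 10 SNPs in the RTC window")
    for sid in (eqtl_snp_id, gwas_snp_id):
        if sid not in snps:
            raise KeyError(f"SNP {sid!r} absent from the window genotypes")
    y = np.asarray(target_expr, dtype=float)
    p = np.asarray(phenotype, dtype=float)
    p_c = p - p.mean()
    g_e = window_genotypes.dosages[eqtl_snp_id].to_numpy(dtype=float)
    inter_e = p_c * (g_e - g_e.mean())
    ones = np.ones_like(y)

    rows = []
    for sid in snps:
        g_n = window_genotypes.dosages[sid].to_numpy(dtype=float)
        g_n = g_n - g_n.mean()
        cond = p_c * g_n if mode == "interaction" else g_n
        X = np.column_stack([ones, cond, inter_e])
        corr = np.corrcoef(cond, inter_e)[0, 1] if cond.std() > 0 else 1.0
        if cond.std() == 0 or abs(corr) > 1 - 1e-10:
            pv = 1.0
        else:
            _, _, _, pvals, _ = _ols_stats(X, y)
            pv = float(pvals[2])
        rows.append({"snp_id": sid, "conditional_p": pv,
                     "position": int(window_genotypes.snp_info.loc[sid, "position"])})
    table = pd.DataFrame(rows)
    # rank 1 = least significant residual p; ties by ascending position
    table = table.sort_values(["conditional_p", "position"],
                              ascending=[False, True], kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    table = table.set_index("snp_id")
    n = len(table)
    rank_gwas = int(table.loc[gwas_snp_id, "rank"])
    return RTCResult(n_snps=n, rank_gwas=rank_gwas, rtc=(n - rank_gwas) / n,
                     conditional_pvalues=table)


def match_meta_exons(annotation_a: list[MetaExon], annotation_b: list[MetaExon],
                     min_overlap_fraction: float = 0.90) -> pd.DataFrame:
    """Match meta-exons across two annotation sets by reciprocal overlap.

    Genes are aligned by ID; each meta-exon in A is paired with the
    same-gene B meta-exon of maximal overlap. With overlap fractions
    f_a = overlap / len_a and f_b = overlap / len_b, the pair is ``matched``
    when both exceed ``min_overlap_fraction``, ``unmatched`` when there is no
    overlap, and ``partial`` otherwise.
    """
    by_gene_b: dict[str, list[MetaExon]] = {}
    for ex in annotation_b:
        by_gene_b.setdefault(ex.gene_id, []).append(ex)
    rows = []
    for ex in annotation_a:
        best, best_ovl = None, 0
        for cand in by_gene_b.get(ex.gene_id, ()):
            if cand.chromosome != ex.chromosome:
                continue
            ovl = min(ex.end, cand.end) - max(ex.start, cand.start) + 1
            if ovl > best_ovl:
                best, best_ovl = cand, ovl
        if best is None or best_ovl <= 0:
            rows.append({"meta_exon_a": ex.meta_exon_id, "meta_exon_b": None,
                         "fraction_a": 0.0, "fraction_b": 0.0, "match_class": "unmatched"})
            continue
        fa = best_ovl / ex.length
        fb = best_ovl / best.length
        cls = "matched" if (fa > min_overlap_fraction and fb > min_overlap_fraction) else "partial"
        rows.append({"meta_exon_a": ex.meta_exon_id, "meta_exon_b": best.meta_exon_id,
                     "fraction_a": fa, "fraction_b": fb, "match_class": cls})
    return pd.DataFrame(rows)


def bonferroni_corrected_p(p: float, n_tests: int) -> float:
    """Bonferroni correction capped at 1 (used e.g. when re-testing all exons
    of one replication gene)."""
    return min(1.0, p * n_tests)
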