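"""Simulation-based validation of the pipeline's statistical machinery.

Each routine regenerates synthetic data under the study conditions it
checks, runs the corresponding pipeline stage from scratch, and returns the
measured quantity: OLS agreement with an independent solver, null
calibration of the twin-LMM likelihood-ratio test and of the permutation
FDR, recovery of planted interaction / mediation / sharing / colocalization
signals. The routines are deliberately deterministic given a seed; problem
sizes are chosen to be informative on a single CPU (documented in the
methods note) and are exposed as arguments.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .association import transcriptome_scan, residualize_family_technical
from .datatypes import PlantedEffect
from .downstream import bonferroni_corrected_p, mediation_test, rtc_score
from .interaction import (
    _ols_stats,
    bonferroni_threshold,
    cis_interaction_scan,
    fit_interaction_model,
    interaction_design,
    permutation_fdr,
)
from .quantify import int_transform_matrix
from .qvalues import estimate_pi0_qvalues
from .simulate import SimulationConfig, simulate_cohort, plant_trans_network


def _child_seed(seed: int, label: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed) % (2 ** 31), label])


# -- multiple-testing arithmetic ---------------------------------------------

def trans_threshold_value(n_variants: int = 4, n_exons: int = 116_643) -> float:
    """Bonferroni p threshold for the two-step trans scan."""
    return bonferroni_threshold(0.05, n_variants, n_exons)


def replication_exonwise_correction(nominal_p: float = 0.001, n_exons: int = 30) -> float:
    """Bonferroni correction when all exons of one replication gene are tested."""
    return bonferroni_corrected_p(nominal_p, n_exons)


# -- OLS oracle equivalence --------------------------------------------------

def ols_oracle_max_rel_error(seed: int = 0, n_designs: int = 1000) -> dict:
    """Max relative error of the normal-equations OLS against statsmodels
    (coefficients, SEs, p-values) over random small interaction/mediation/RTC
    style designs (n = 12..30)."""
    import statsmodels.api as sm

    rng = np.random.default_rng(_child_seed(seed, 301))
    worst = 0.0
    for _ in range(n_designs):
        n = int(rng.integers(12, 31))
        age = rng.uniform(38, 84, n)
        pheno = rng.normal(25, 4, n)
        g = rng.binomial(2, rng.uniform(0.1, 0.5), n).astype(float)
        e = rng.normal(size=n)
        kind = rng.integers(0, 4)
        if kind == 0:    # interaction model
            X = interaction_design(age, pheno, g)
        elif kind == 1:  # mediation, conditioned
            D = interaction_design(age, pheno, g)
            X = np.column_stack([D[:, :1], e, D[:, 1:]])
        elif kind == 2:  # RTC interaction conditioning
            g2 = rng.binomial(2, 0.3, n).astype(float)
            pc = pheno - pheno.mean()
            X = np.column_stack([np.ones(n), pc * (g2 - g2.mean()), pc * (g - g.mean())])
        else:            # RTC main-effect conditioning
            g2 = rng.binomial(2, 0.3, n).astype(float)
            pc = pheno - pheno.mean()
            X = np.column_stack([np.ones(n), g2 - g2.mean(), pc * (g - g.mean())])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            continue
        y = X @ rng.normal(0, 0.3, X.shape[1]) + rng.normal(0, 1, n)
        beta, se, t, p, _ = _ols_stats(X, y)
        ref = sm.OLS(y, X).fit()
        for mine, theirs in ((beta, ref.params), (se, ref.bse), (p, ref.pvalues)):
            denom = np.maximum(np.abs(theirs), 1e-12)
            worst = max(worst, float(np.max(np.abs(mine - theirs) / denom)))
    return {"max_rel_error": worst, "n": n_designs}


# -- null calibration (LMM type-I, permutation FDR, stratification) ---------

def _null_config(seed: int, n_genes: int, n_snps: int,
                 exons_per_gene: tuple[int, int]) -> SimulationConfig:
    # latent factors off: factor scores are shared across exons, so leaving
    # them in would correlate the "independent" null tests cohort-wide and
    # void the binomial calibration bands
    return SimulationConfig(
        n_mz_pairs=120, n_dz_pairs=170, n_unrelated=120,
        n_snps=n_snps, n_genes=n_genes, exons_per_gene_range=exons_per_gene,
        latent_phenotype_corr=(), n_latent_factors=0,
        effect_grid=[], seed=seed,
    )


def null_calibration(seed: int = 0, n_cohorts: int = 20, n_genes: int = 100,
                     n_snps: int = 200, lmm_tests_per_cohort: int = 500,
                     n_perm: int = 100, alpha: float = 0.05) -> dict:
    """Twenty null twin cohorts (no planted effects, n = 700 samples):

    * type-I error of the twin-LMM phenotype LRT at ``alpha`` pooled across
      cohorts,
    * fraction of cis pairs flagged at permutation FDR <= 5%,
    * a chi-square comparison of per-stratum flagged fractions (the
      exon-count stratification should penalize multi-exon genes into
      calibration, not create stratum imbalance).
    """
    n_lmm = 0
    n_reject = 0
    pair_total = 0
    flagged_total = 0
    strata_counts: dict[int, list[int]] = {}
    for c in range(n_cohorts):
        rng_c = np.random.default_rng(_child_seed(seed, 400 + c))
        # LMM type-I calibration on single-exon genes: exons of one gene share
        # family/zygosity draws, so multi-exon genes would correlate the tests
        lmm_cfg = _null_config(int(rng_c.integers(2 ** 31)),
                               lmm_tests_per_cohort, 4, (1, 1))
        lmm_cohort = simulate_cohort(lmm_cfg)
        assoc, _ = transcriptome_scan(int_transform_matrix(lmm_cohort.expression),
                                      lmm_cohort.metadata)
        n_lmm += len(assoc)
        n_reject += int((assoc["pvalue"] < alpha).sum())

        cfg = _null_config(int(rng_c.integers(2 ** 31)), n_genes, n_snps, (1, 20))
        cohort = simulate_cohort(cfg)
        expr = int_transform_matrix(cohort.expression)
        base = residualize_family_technical(expr, cohort.metadata)
        cis = cis_interaction_scan(base, cohort.genotypes, cohort.metadata, cohort.annotation)
        if cis.empty:
            continue
        annotated, _ = permutation_fdr(cis, base, cohort.genotypes, cohort.metadata,
                                       n_perm=n_perm, seed=seed + c)
        pair_total += len(annotated)
        flagged_total += int(annotated["significant"].sum())
        for s, grp in annotated.groupby("stratum"):
            cnt = strata_counts.setdefault(int(s), [0, 0])
            cnt[0] += int(grp["significant"].sum())
            cnt[1] += int(len(grp))

    # stratification check: flagged vs not, per stratum
    table = np.array([[c[0], c[1] - c[0]] for c in strata_counts.values()])
    if table[:, 0].sum() < 5:
        chi2_p = 1.0  # too few calls anywhere to distinguish strata
    else:
        chi2_p = float(stats.chi2_contingency(table)[1])
    return {
        "lmm_type1_rate": n_reject / n_lmm,
        "n_lmm_tests": n_lmm,
        "perm_fdr_flagged_fraction": flagged_total / pair_total,
        "n_pairs": pair_total,
        "stratification_chi2_p": chi2_p,
    }


# -- planted-interaction recovery --------------------------------------------

def interaction_recovery(seed: int = 0, n_reps: int = 200,
                         beta_range: tuple[float, float] = (0.02, 0.06)) -> dict:
    """Fraction of replicates (default 200, n = 700) in which the OLS
    interaction estimate falls within 2 SE of the planted coefficient."""
    rng = np.random.default_rng(_child_seed(seed, 500))
    hits = 0
    for r in range(n_reps):
        beta = float(rng.uniform(*beta_range)) * (1 if rng.random() < 0.5 else -1)
        cfg = SimulationConfig(
            n_mz_pairs=120, n_dz_pairs=170, n_unrelated=120,
            n_snps=6, n_genes=2, exons_per_gene_range=(1, 1),
            n_latent_factors=0, latent_phenotype_corr=(),
            effect_grid=[PlantedEffect("gxe_interaction", "", "",
                                       beta_snp=0.2, beta_interaction=beta)],
            seed=int(rng.integers(2 ** 31)),
        )
        cohort = simulate_cohort(cfg)
        eff = cohort.truth.effects[0]
        exon = cohort.expression.gene_ids[cohort.expression.gene_ids == eff.gene_id].index[0]
        st = fit_interaction_model(
            cohort.metadata.table["age"].to_numpy(dtype=float),
            cohort.metadata.table["bmi"].to_numpy(dtype=float),
            cohort.genotypes.dosages[eff.snp_id].to_numpy(dtype=float),
            cohort.expression.values.loc[exon].to_numpy(dtype=float),
        )
        if abs(st["beta_interaction"] - beta) <= 2 * st["se_interaction"]:
            hits += 1
    return {"within_2se_fraction": hits / n_reps, "n": n_reps}


# -- mediation recovery -------------------------------------------------------

def mediation_recovery(seed: int = 0, n_reps: int = 100,
                       fractions: tuple[float, ...] = (0.0, 0.5, 1.0)) -> dict:
    """Median Eq.-2 mediation score per planted fraction, plus the Sobel
    statistic under a pure null (target with no interaction at all) and its
    power at partial mediation."""
    rng = np.random.default_rng(_child_seed(seed, 600))
    scores: dict[float, list[float]] = {f: [] for f in fractions}
    null_abs_z: list[float] = []
    partial_sig = 0
    for r in range(n_reps):
        cfg = SimulationConfig(
            n_mz_pairs=120, n_dz_pairs=170, n_unrelated=120,
            n_snps=12, n_genes=6, exons_per_gene_range=(1, 1),
            n_latent_factors=0, latent_phenotype_corr=(),
            effect_grid=[PlantedEffect("gxe_interaction", "", "",
                                       beta_snp=0.2, beta_interaction=0.06)],
            seed=int(rng.integers(2 ** 31)),
        )
        cohort = simulate_cohort(cfg)
        med = cohort.truth.effects[0]
        free = [g for g in sorted(set(cohort.expression.gene_ids))
                if g != med.gene_id]
        for f, tg in zip(fractions, free):
            cohort = plant_trans_network(cohort, med.gene_id, 1, f,
                                         beta_interaction=0.06, target_genes=[tg])
        gene_ids = cohort.expression.gene_ids
        e_m = cohort.expression.values.loc[
            gene_ids[gene_ids == med.gene_id].index[0]].to_numpy(dtype=float)
        g = cohort.genotypes.dosages[med.snp_id].to_numpy(dtype=float)
        pheno = cohort.metadata.table["bmi"].to_numpy(dtype=float)
        age = cohort.metadata.table["age"].to_numpy(dtype=float)

        for f, tg in zip(fractions, free):
            y = cohort.expression.values.loc[
                gene_ids[gene_ids == tg].index[0]].to_numpy(dtype=float)
            res = mediation_test(y, e_m, g, pheno, age)
            scores[f].append(res.mediation_score)
            if f == 0.5 and res.sobel_p <= 0.001:
                partial_sig += 1
        # pure-null target: no planted dependence on mediator or SNP
        y0 = cohort.expression.values.loc[
            gene_ids[gene_ids == free[len(fractions)]].index[0]].to_numpy(dtype=float)
        null_abs_z.append(abs(mediation_test(y0, e_m, g, pheno, age).sobel_z))
    out = {f"median_score_f{f:g}": float(np.median(scores[f])) for f in fractions}
    out["null_median_abs_z"] = float(np.median(null_abs_z))
    out["sobel_power_partial"] = partial_sig / n_reps
    out["n"] = n_reps
    return out


# -- pi1 mixture recovery ------------------------------------------------------

def pi1_mixture_recovery(seed: int = 0, n_tests: int = 100_000,
                         fractions: tuple[float, ...] = (0.0, 0.3, 0.5, 0.9)) -> dict:
    """pi1 estimates on p-value mixtures with known alternative fractions.

    Alternatives are two-sided p-values of N(4, 1) z-scores (comfortably
    separated from the null), nulls are uniform.
    """
    rng = np.random.default_rng(_child_seed(seed, 700))
    out = {}
    for f in fractions:
        n_alt = int(round(f * n_tests))
        p_null = rng.uniform(size=n_tests - n_alt)
        z = rng.normal(4.0, 1.0, size=n_alt)
        p_alt = 2.0 * stats.norm.sf(np.abs(z))
        p = np.concatenate([p_null, p_alt])
        out[f"pi1_f{f:g}"] = estimate_pi0_qvalues(p).pi1
    out["n"] = n_tests
    return out


# -- RTC discrimination --------------------------------------------------------

def rtc_discrimination(seed: int = 0, n_reps: int = 50, n_snps: int = 250,
                       ld_rho: float = 0.9, min_r2: float = 0.9) -> dict:
    """Median RTC for colocalized vs independent GWAS signals.

    Each replicate simulates one window with an AR(1) LD block structure
    (local LD decaying over ~10-20 SNPs, unlinked background beyond), plants
    an interaction at one SNP, and scores (a) a colocalized GWAS proxy -- the
    causal dosages with ~3% of samples re-drawn, giving r^2 > ``min_r2`` --
    placed at the neighbouring position, and (b) an independent GWAS SNP
    drawn from the low-LD (r^2 < 0.1) remainder of the window.
    """
    from .datatypes import GenotypeMatrix

    rng = np.random.default_rng(_child_seed(seed, 800))
    coloc, indep = [], []
    attempts = 0
    while len(coloc) < n_reps and attempts < 3 * n_reps:
        attempts += 1
        cfg = SimulationConfig(
            n_mz_pairs=120, n_dz_pairs=170, n_unrelated=120,
            n_snps=n_snps, n_genes=1, exons_per_gene_range=(1, 1),
            n_latent_factors=0, latent_phenotype_corr=(), ld_rho=ld_rho,
            effect_grid=[PlantedEffect("gxe_interaction", "", "",
                                       beta_snp=0.0, beta_interaction=0.08)],
            seed=int(rng.integers(2 ** 31)),
        )
        cohort = simulate_cohort(cfg)
        geno = cohort.genotypes
        snp_ids = list(geno.snp_ids)
        causal = cohort.truth.effects[0].snp_id
        ci = snp_ids.index(causal)
        gc = geno.dosages[causal].to_numpy(dtype=float)

        # colocalized proxy: perturb a few samples' dosages, overwrite a neighbour
        proxy = gc.copy()
        n_samp = proxy.size
        flip = rng.random(n_samp) < 0.03
        maf = gc.mean() / 2.0
        proxy[flip] = rng.binomial(2, maf, size=int(flip.sum()))
        if np.corrcoef(gc, proxy)[0, 1] ** 2 < min_r2 or proxy.std() == 0:
            continue
        proxy_id = snp_ids[ci - 1 if ci > 0 else ci + 1]
        dosages = geno.dosages.copy()
        dosages[proxy_id] = proxy
        geno = GenotypeMatrix(dosages, geno.snp_info)

        dose = dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            r2 = np.array([np.corrcoef(gc, dose[:, j])[0, 1] ** 2
                           for j in range(n_snps)])
        low = np.flatnonzero(np.nan_to_num(r2, nan=1.0) < 0.1)
        if low.size == 0:
            continue
        gwas_indep = snp_ids[int(rng.choice(low))]

        exon = cohort.expression.meta_exon_ids[0]
        y = cohort.expression.values.loc[exon].to_numpy(dtype=float)
        pheno = cohort.metadata.table["bmi"].to_numpy(dtype=float)
        coloc.append(rtc_score(y, pheno, geno, causal, proxy_id).rtc)
        indep.append(rtc_score(y, pheno, geno, causal, gwas_indep).rtc)
    return {
        "median_rtc_colocalized": float(np.median(coloc)),
        "median_rtc_independent": float(np.median(indep)),
        "n": len(coloc),
    }
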