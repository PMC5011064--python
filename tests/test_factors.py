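"""Latent-factor estimation and residualization."""

import numpy as np
import pandas as pd
import pytest

from gxeqtl import (
    PlantedEffect,
    SimulationConfig,
    estimate_latent_factors,
    int_transform_matrix,
    residualize,
    residualize_family_technical,
    simulate_cohort,
)
from gxeqtl.datatypes import ExpressionMatrix
from gxeqtl.interaction import fit_interaction_model


def _noise_matrix(rng, n_feat=400, n_samp=150):
    df = pd.DataFrame(rng.normal(size=(n_feat, n_samp)),
                      index=[f"G{i}:chr1:1-10" for i in range(n_feat)],
                      columns=[f"s{i}" for i in range(n_samp)])
    return ExpressionMatrix(df, "residualized")


class TestEstimation:
    def test_planted_batch_factor_recovered(self, rng):
        n_feat, n_samp = 600, 200
        batch = rng.standard_normal(n_samp)
        arr = rng.normal(size=(n_feat, n_samp))
        hit = rng.random(n_feat) < 0.3
        arr[hit] += np.outer(rng.normal(0, 0.8, hit.sum()), batch)
        m = ExpressionMatrix(pd.DataFrame(
            arr, index=[f"G{i}:chr1:1-10" for i in range(n_feat)],
            columns=[f"s{i}" for i in range(n_samp)]), "residualized")
        model = estimate_latent_factors(m, k=5)
        r = np.corrcoef(model.scores["factor1"], batch)[0, 1]
        assert abs(r) > 0.9

    def test_factor_order_and_sign_convention(self, rng):
        model = estimate_latent_factors(_noise_matrix(rng), k=8)
        assert (np.diff(model.variance_explained) <= 1e-12).all()
        for c in model.loadings.columns:
            lo = model.loadings[c].to_numpy()
            assert lo[np.argmax(np.abs(lo))] > 0

    def test_scores_orthogonal(self, rng):
        model = estimate_latent_factors(_noise_matrix(rng), k=6)
        s = model.scores.to_numpy()
        gram = s.T @ s
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_null_top_factor_consistent_with_random_matrix(self, rng):
        """On pure noise the lead factor should explain roughly the
        Marchenko-Pastur edge share of variance, not a dominant chunk."""
        n_feat, n_samp = 1000, 200
        m = _noise_matrix(rng, n_feat, n_samp)
        model = estimate_latent_factors(m, k=3)
        # Monte-Carlo null: top singular-value share of an iid Gaussian matrix
        mc = []
        for s in range(5):
            z = np.random.default_rng(s).normal(size=(n_samp, n_feat))
            sv = np.linalg.svd(z, compute_uv=False)
            mc.append(sv[0] ** 2 / (sv ** 2).sum())
        assert model.variance_explained[0] == pytest.approx(np.mean(mc), rel=0.10)

    def test_phenotype_correlated_confounder_reported(self):
        cfg = SimulationConfig(n_mz_pairs=120, n_dz_pairs=170, n_unrelated=120,
                               n_snps=10, n_genes=300, exons_per_gene_range=(1, 1),
                               n_latent_factors=4, latent_phenotype_corr=(0.5,),
                               latent_affected_fraction=0.6, latent_loading_sd=0.4,
                               effect_grid=[], seed=31)
        cohort = simulate_cohort(cfg)
        expr = int_transform_matrix(cohort.expression)
        base = residualize_family_technical(expr, cohort.metadata)
        model = estimate_latent_factors(base, k=6,
                                        phenotype=cohort.metadata.phenotype("bmi"))
        assert model.phenotype_corr["r"].abs().max() == pytest.approx(0.5, abs=0.1)

    def test_k_bound_enforced(self, rng):
        with pytest.raises(ValueError, match="k"):
            estimate_latent_factors(_noise_matrix(rng, 50, 30), k=30)


class TestResidualize:
    def test_intercept_only_centers(self, rng):
        m = _noise_matrix(rng, 20, 50)
        out = residualize(m)
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-12)
        centered = m.values.sub(m.values.mean(axis=1), axis=0)
        np.testing.assert_allclose(out.values.to_numpy(), centered.to_numpy(), atol=1e-12)

    def test_residuals_orthogonal_to_design(self, rng):
        m = _noise_matrix(rng, 30, 80)
        cov = pd.DataFrame({"c1": rng.normal(size=80), "c2": rng.normal(size=80)},
                           index=m.sample_ids)
        out = residualize(m, covariates=cov)
        resid = out.values.to_numpy()
        for c in cov.columns:
            v = cov[c].to_numpy()
            v = (v - v.mean()) / v.std()
            dots = resid @ v / len(v)
            assert np.abs(dots).max() < 1e-6

    def test_idempotent(self, rng):
        m = _noise_matrix(rng, 25, 60)
        cov = pd.DataFrame({"c": rng.normal(size=60)}, index=m.sample_ids)
        once = residualize(m, covariates=cov)
        twice = residualize(once, covariates=cov)
        np.testing.assert_allclose(once.values.to_numpy(), twice.values.to_numpy(),
                                   atol=1e-10)

    def test_rank_deficient_design_names_columns(self, rng):
        m = _noise_matrix(rng, 10, 40)
        x = rng.normal(size=40)
        cov = pd.DataFrame({"a": x, "b": 2 * x}, index=m.sample_ids)
        with pytest.raises(ValueError, match="b"):
            residualize(m, covariates=cov)

    def test_exclude_phenotype_correlated_factors(self, rng):
        m = _noise_matrix(rng, 200, 100)
        pheno = pd.Series(rng.normal(25, 4, 100), index=m.sample_ids)
        model = estimate_latent_factors(m, k=5, phenotype=pheno)
        thr = model.phenotype_corr["r"].abs().sort_values().iloc[-2]
        kept = model.factors_below_corr(thr)
        assert len(kept) == 4
        out = residualize(m, factors=model, exclude_phenotype_correlated=thr)
        # residuals orthogonal to every kept factor
        for c in kept:
            s = model.scores[c].to_numpy()
            s = (s - s.mean()) / s.std()
            assert np.abs(out.values.to_numpy() @ s / len(s)).max() < 1e-6

    def test_factor_correction_improves_interaction_power(self):
        """With a phenotype-correlated confounder, the planted interaction is
        more significant after factor residualization (paired replicates)."""
        wins = 0
        for rep in range(8):
            cfg = SimulationConfig(
                n_mz_pairs=120, n_dz_pairs=170, n_unrelated=120,
                n_snps=40, n_genes=40, exons_per_gene_range=(1, 2),
                n_latent_factors=8, latent_phenotype_corr=(0.5, 0.35, 0.2),
                latent_affected_fraction=0.5, latent_loading_sd=0.35,
                effect_grid=[PlantedEffect("gxe_interaction", "", "",
                                           beta_snp=0.2, beta_interaction=0.04)],
                seed=1000 + rep)
            cohort = simulate_cohort(cfg)
            eff = cohort.truth.effects[0]
            expr = int_transform_matrix(cohort.expression)
            base = residualize_family_technical(expr, cohort.metadata)
            model = estimate_latent_factors(base, k=8,
                                            phenotype=cohort.metadata.phenotype("bmi"))
            corrected = residualize(base, factors=model,
                                    exclude_phenotype_correlated=0.25)
            age = cohort.metadata.table["age"].to_numpy(float)
            pheno = cohort.metadata.table["bmi"].to_numpy(float)
            g = cohort.genotypes.dosages[eff.snp_id].to_numpy(float)
            exon = base.gene_ids[base.gene_ids == eff.gene_id].index[0]
            p_raw = fit_interaction_model(age, pheno, g,
                                          base.values.loc[exon].to_numpy(float))["p_interaction"]
            p_fac = fit_interaction_model(age, pheno, g,
                                          corrected.values.loc[exon].to_numpy(float))["p_interaction"]
            wins += p_fac < p_raw
        assert wins >= 6
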