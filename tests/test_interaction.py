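"""cis/trans interaction scans and permutation FDR."""

import numpy as np
import pandas as pd
import pytest

from gxeqtl import (
    PlantedEffect,
    SimulationConfig,
    bonferroni_threshold,
    cis_interaction_scan,
    int_transform_matrix,
    permutation_fdr,
    residualize_family_technical,
    simulate_cohort,
    trans_interaction_scan,
)
from gxeqtl.datatypes import ExpressionMatrix, GenotypeMatrix, MetaExon
from gxeqtl.interaction import fit_interaction_model, interaction_design


@pytest.fixture(scope="module")
def scanned(small_cohort):
    expr = int_transform_matrix(small_cohort.expression)
    base = residualize_family_technical(expr, small_cohort.metadata)
    cis = cis_interaction_scan(base, small_cohort.genotypes, small_cohort.metadata,
                               small_cohort.annotation)
    return base, cis


class TestCisScan:
    def test_window_rule(self, small_cohort, scanned):
        base, cis = scanned
        exon_map = {ex.meta_exon_id: ex for ex in small_cohort.annotation}
        info = small_cohort.genotypes.snp_info
        for row in cis.sample(min(len(cis), 300), random_state=0).itertuples(index=False):
            ex = exon_map[row.meta_exon_id]
            snp = info.loc[row.snp_id]
            assert snp["chromosome"] == ex.chromosome
            assert abs(snp["position"] - ex.tss) <= 1_000_000

    def test_snp_outside_window_not_tested(self):
        """A SNP 1.5 Mb from the TSS is excluded under the 1 Mb rule."""
        rng = np.random.default_rng(0)
        n = 60
        ann = [MetaExon("G1", "chr1", 2_000_000, 2_000_500, "+")]
        snp_info = pd.DataFrame(
            {"chromosome": ["chr1", "chr1"], "position": [2_500_000, 3_500_000],
             "effect_allele": "A", "other_allele": "G"},
            index=pd.Index(["near", "far"], name="snp_id"))
        geno = GenotypeMatrix(pd.DataFrame(
            rng.binomial(2, 0.3, size=(n, 2)).astype(float),
            index=[f"s{i}" for i in range(n)], columns=snp_info.index), snp_info)
        from gxeqtl.datatypes import SampleMetadata
        meta = SampleMetadata(pd.DataFrame({
            "bmi": rng.normal(25, 4, n), "age": rng.uniform(38, 84, n),
            "family": [f"F{i}" for i in range(n)],
            "zygosity": [f"Z{i}" for i in range(n)]},
            index=geno.sample_ids), ("bmi",))
        expr = ExpressionMatrix(pd.DataFrame(
            rng.normal(size=(1, n)), index=[ann[0].meta_exon_id],
            columns=geno.sample_ids), "residualized",
            pd.Series(["G1"], index=[ann[0].meta_exon_id]))
        cis = cis_interaction_scan(expr, geno, meta, ann)
        assert set(cis["snp_id"]) == {"near"}

    def test_matches_ols_oracle(self, small_cohort, scanned):
        """Every (exon, SNP) coefficient/SE/p matches statsmodels OLS."""
        import statsmodels.api as sm

        base, cis = scanned
        meta = small_cohort.metadata
        age = meta.table["age"].to_numpy(float)
        pheno = meta.table["bmi"].to_numpy(float)
        for row in cis.sample(40, random_state=1).itertuples(index=False):
            y = base.values.loc[row.meta_exon_id].to_numpy(float)
            g = small_cohort.genotypes.dosages[row.snp_id].to_numpy(float)
            X = interaction_design(age, pheno, g)
            ref = sm.OLS(y, X).fit()
            assert row.beta_interaction == pytest.approx(ref.params[5], rel=1e-8)
            assert row.se_interaction == pytest.approx(ref.bse[5], rel=1e-8)
            assert row.p_interaction == pytest.approx(ref.pvalues[5], rel=1e-8, abs=1e-300)

    def test_sign_flip_interaction_detected(self):
        """Opposed expression-on-phenotype slopes across homozygote classes
        (+-0.05 per phenotype unit) reach p < 1e-6 at n = 700."""
        detected = 0
        for seed in range(10):
            cfg = SimulationConfig(
                n_mz_pairs=120, n_dz_pairs=170, n_unrelated=120,
                n_snps=6, n_genes=2, exons_per_gene_range=(1, 1),
                n_latent_factors=0, latent_phenotype_corr=(),
                effect_grid=[PlantedEffect("gxe_interaction", "", "",
                                           beta_snp=0.0, beta_interaction=0.05)],
                seed=600 + seed)
            cohort = simulate_cohort(cfg)
            eff = cohort.truth.effects[0]
            exon = cohort.expression.gene_ids[
                cohort.expression.gene_ids == eff.gene_id].index[0]
            st = fit_interaction_model(
                cohort.metadata.table["age"].to_numpy(float),
                cohort.metadata.table["bmi"].to_numpy(float),
                cohort.genotypes.dosages[eff.snp_id].to_numpy(float),
                cohort.expression.values.loc[exon].to_numpy(float))
            detected += st["p_interaction"] < 1e-6
        assert detected >= 8

    def test_invariant_to_sample_and_snp_order(self, small_cohort, scanned):
        base, cis = scanned
        rng = np.random.default_rng(3)
        perm = rng.permutation(base.n_samples)
        samples = base.sample_ids[perm]
        expr_p = ExpressionMatrix(base.values[samples], base.state, base.gene_ids)
        snp_perm = rng.permutation(small_cohort.genotypes.snp_ids)
        geno_p = GenotypeMatrix(
            small_cohort.genotypes.dosages.loc[samples, snp_perm],
            small_cohort.genotypes.snp_info.loc[snp_perm])
        cis_p = cis_interaction_scan(expr_p, geno_p,
                                     small_cohort.metadata.subset(samples),
                                     small_cohort.annotation)
        a = cis.sort_values(["meta_exon_id", "snp_id"]).reset_index(drop=True)
        b = cis_p.sort_values(["meta_exon_id", "snp_id"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, atol=1e-10)


class TestPermutationFDR:
    def test_nperm_floor(self, small_cohort, scanned):
        base, cis = scanned
        with pytest.raises(ValueError, match="n_perm"):
            permutation_fdr(cis, base, small_cohort.genotypes,
                            small_cohort.metadata, n_perm=10)

    def test_planted_interaction_flagged_and_fdr_monotone(self, small_cohort, scanned):
        base, cis = scanned
        annotated, summary = permutation_fdr(cis, base, small_cohort.genotypes,
                                             small_cohort.metadata, n_perm=50, seed=1)
        gxe = small_cohort.truth.effects[0]
        hit = annotated[(annotated["gene_id"] == gxe.gene_id)
                        & (annotated["snp_id"] == gxe.snp_id)]
        assert hit["significant"].any()
        # monotone non-decreasing FDR in p within each stratum
        for _, grp in annotated.groupby("stratum"):
            s = grp.sort_values("p_interaction")
            assert (np.diff(s["fdr"].to_numpy()) >= -1e-12).all()
        assert summary.n_permutations == 50

    def test_observed_beats_all_permutations_gives_zero(self, small_cohort, scanned):
        base, cis = scanned
        annotated, _ = permutation_fdr(cis, base, small_cohort.genotypes,
                                       small_cohort.metadata, n_perm=50, seed=1)
        best = annotated.sort_values("p_interaction").iloc[0]
        # the planted effect is orders of magnitude beyond any permuted
        # statistic: the empirical estimate hits its floor of exactly 0
        assert best["fdr"] == 0.0

    def test_deterministic_given_seed(self, small_cohort, scanned):
        base, cis = scanned
        a, _ = permutation_fdr(cis, base, small_cohort.genotypes,
                               small_cohort.metadata, n_perm=30, seed=9)
        b, _ = permutation_fdr(cis, base, small_cohort.genotypes,
                               small_cohort.metadata, n_perm=30, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestTransScan:
    def test_threshold_formula(self):
        thr = bonferroni_threshold(0.05, 4, 116_643)
        assert thr == pytest.approx(0.05 / 466_572)
        assert float(f"{thr:.1e}") == 1.1e-07  # two significant figures

    def test_exclusion_zone(self, small_cohort):
        expr = int_transform_matrix(small_cohort.expression)
        base = residualize_family_technical(expr, small_cohort.metadata)
        gxe = small_cohort.truth.effects[0]
        trans, thr = trans_interaction_scan([gxe.snp_id], base, small_cohort.genotypes,
                                            small_cohort.metadata, small_cohort.annotation)
        info = small_cohort.genotypes.snp_info.loc[gxe.snp_id]
        exon_map = {ex.meta_exon_id: ex for ex in small_cohort.annotation}
        for mid in trans["meta_exon_id"]:
            ex = exon_map[mid]
            assert (ex.chromosome != info["chromosome"]
                    or abs(ex.tss - info["position"]) > 5_000_000)
        assert thr == pytest.approx(0.05 / (1 * expr.values.shape[0]))

    def test_mediated_targets_recovered(self, small_cohort):
        expr = int_transform_matrix(small_cohort.expression)
        base = residualize_family_technical(expr, small_cohort.metadata)
        gxe = small_cohort.truth.effects[0]
        trans, _ = trans_interaction_scan([gxe.snp_id], base, small_cohort.genotypes,
                                          small_cohort.metadata, small_cohort.annotation)
        truth = {e.gene_id for e in small_cohort.truth.effects
                 if e.kind == "trans_mediated"}
        found = set(trans.loc[trans["significant"], "gene_id"])
        assert len(truth & found) >= len(truth) - 1

    def test_empty_seed_list_is_noop(self, small_cohort):
        expr = int_transform_matrix(small_cohort.expression)
        trans, thr = trans_interaction_scan([], expr, small_cohort.genotypes,
                                            small_cohort.metadata, small_cohort.annotation)
        assert trans.empty and np.isnan(thr)
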