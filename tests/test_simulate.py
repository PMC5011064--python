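"""Generator contracts: twin sharing, determinism, planted-effect recovery."""

import numpy as np
import pytest

from gxeqtl import PlantedEffect, SimulationConfig, plant_trans_network, simulate_cohort
from gxeqtl.interaction import fit_interaction_model
from gxeqtl.simulate import ConfigurationError, simulate_genotypes, simulate_metadata


def _pair_blocks(n_pairs):
    return [(2 * i, 2 * i + 1) for i in range(n_pairs)]


class TestGenotypes:
    def test_mz_twins_share_genotypes(self):
        cfg = SimulationConfig(n_mz_pairs=5, n_dz_pairs=0, n_unrelated=0,
                               n_snps=100, n_genes=5, seed=0)
        g = simulate_genotypes(cfg).dosages.to_numpy()
        for i, j in _pair_blocks(5):
            assert np.array_equal(g[i], g[j])

    def test_dz_within_pair_correlation_near_half(self):
        # expected IBD-based genotype correlation for DZ pairs is 1/2
        cfg = SimulationConfig(n_mz_pairs=0, n_dz_pairs=500, n_unrelated=0,
                               n_snps=400, n_genes=10, maf_range=(0.3, 0.3), seed=1)
        g = simulate_genotypes(cfg).dosages.to_numpy()
        cors = []
        for j in range(g.shape[1]):
            a, b = g[0::2, j], g[1::2, j]
            if a.std() > 0 and b.std() > 0:
                cors.append(np.corrcoef(a, b)[0, 1])
        assert abs(np.mean(cors) - 0.5) < 0.05

    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(n_mz_pairs=4, n_dz_pairs=4, n_unrelated=3,
                               n_snps=60, n_genes=6, seed=11)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        assert a.dosages.equals(b.dosages)
        assert a.snp_info.equals(b.snp_info)

    def test_dosage_bounds_and_maf_range(self):
        cfg = SimulationConfig(n_mz_pairs=50, n_dz_pairs=50, n_unrelated=50,
                               n_snps=300, n_genes=10, maf_range=(0.2, 0.4), seed=3)
        g = simulate_genotypes(cfg)
        arr = g.dosages.to_numpy()
        assert arr.min() >= 0 and arr.max() <= 2
        # realized MAF within range plus sampling error
        assert (g.maf > 0.12).all() and (g.maf < 0.48).all()

    def test_zero_samples_or_snps_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_genotypes(SimulationConfig(n_mz_pairs=0, n_dz_pairs=0, n_unrelated=0,
                                                n_snps=10, n_genes=2))
        with pytest.raises(ConfigurationError):
            simulate_genotypes(SimulationConfig(n_mz_pairs=1, n_dz_pairs=0, n_unrelated=0,
                                                n_snps=0, n_genes=2))

    def test_ld_mode_produces_local_correlation(self):
        cfg = SimulationConfig(n_mz_pairs=0, n_dz_pairs=0, n_unrelated=400,
                               n_snps=100, n_genes=1, ld_rho=0.95, seed=5)
        g = simulate_genotypes(cfg).dosages.to_numpy()
        r_adj = np.mean([abs(np.corrcoef(g[:, j], g[:, j + 1])[0, 1])
                         for j in range(40)])
        far = abs(np.corrcoef(g[:, 0], g[:, 80])[0, 1])
        assert r_adj > 0.6
        assert far < 0.3


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_mz_pairs": -1},
        {"maf_range": (0.01, 0.4)},
        {"maf_range": (0.3, 0.6)},
        {"ld_rho": 1.0},
        {"exons_per_gene_range": (0, 3)},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)

    def test_unknown_gene_or_snp_in_grid_rejected(self):
        cfg = SimulationConfig(n_mz_pairs=5, n_dz_pairs=5, n_unrelated=5,
                               n_snps=50, n_genes=5,
                               effect_grid=[PlantedEffect("main_eqtl", "NOPE", "",
                                                          beta_snp=0.3)])
        with pytest.raises(ConfigurationError):
            simulate_cohort(cfg)


class TestCohort:
    def test_determinism(self):
        cfg = SimulationConfig(n_mz_pairs=5, n_dz_pairs=5, n_unrelated=5,
                               n_snps=50, n_genes=5, seed=9)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert a.expression.values.equals(b.expression.values)
        assert a.metadata.table.equals(b.metadata.table)

    def test_metadata_twin_coding(self):
        cfg = SimulationConfig(n_mz_pairs=3, n_dz_pairs=3, n_unrelated=2,
                               n_snps=10, n_genes=2, seed=0)
        t = simulate_metadata(cfg).table
        mz = t.iloc[0:2]
        assert mz["family"].nunique() == 1 and mz["zygosity"].nunique() == 1
        dz = t.iloc[6:8]
        assert dz["family"].nunique() == 1 and dz["zygosity"].nunique() == 2

    def test_global_null_slope_calibration(self, big_null_cohort):
        """With no planted effects, per-exon regression on the phenotype has
        ~5% rejections at alpha = 0.05 (within a generous binomial band)."""
        cohort = big_null_cohort
        pheno = cohort.metadata.table["bmi"].to_numpy()
        age = cohort.metadata.table["age"].to_numpy()
        vals = cohort.expression.values.to_numpy()
        from scipy import stats
        rej = 0
        for i in range(vals.shape[0]):
            r, p = stats.pearsonr(vals[i], pheno)
            rej += p < 0.05
        frac = rej / vals.shape[0]
        assert frac < 0.15  # twin clustering inflates mildly; null, not signal

    def test_interaction_effect_recovered_by_ols(self):
        hits = 0
        reps = 25
        rng = np.random.default_rng(77)
        for r in range(reps):
            beta = 0.03
            cfg = SimulationConfig(n_mz_pairs=120, n_dz_pairs=170, n_unrelated=120,
                                   n_snps=6, n_genes=2, exons_per_gene_range=(1, 1),
                                   n_latent_factors=0, latent_phenotype_corr=(),
                                   effect_grid=[PlantedEffect("gxe_interaction", "", "",
                                                              beta_snp=0.2,
                                                              beta_interaction=beta)],
                                   seed=int(rng.integers(2 ** 31)))
            cohort = simulate_cohort(cfg)
            eff = cohort.truth.effects[0]
            exon = cohort.expression.gene_ids[
                cohort.expression.gene_ids == eff.gene_id].index[0]
            st = fit_interaction_model(
                cohort.metadata.table["age"].to_numpy(float),
                cohort.metadata.table["bmi"].to_numpy(float),
                cohort.genotypes.dosages[eff.snp_id].to_numpy(float),
                cohort.expression.values.loc[exon].to_numpy(float))
            hits += abs(st["beta_interaction"] - beta) <= 2 * st["se_interaction"]
        assert hits / reps >= 0.80

    def test_latent_factor_phenotype_correlation(self):
        cfg = SimulationConfig(n_mz_pairs=120, n_dz_pairs=170, n_unrelated=120,
                               n_snps=10, n_genes=5, n_latent_factors=3,
                               latent_phenotype_corr=(0.5,), seed=13)
        cohort = simulate_cohort(cfg)
        scores = cohort.truth.latent_scores
        r = np.corrcoef(scores["LF1"], cohort.metadata.table["bmi"])[0, 1]
        assert abs(r - 0.5) < 0.1
        r2 = np.corrcoef(scores["LF2"], cohort.metadata.table["bmi"])[0, 1]
        assert abs(r2) < 0.15

    def test_mz_expression_correlation_exceeds_dz(self):
        """Family + zygosity variance implies MZ > DZ within-pair correlation."""
        cfg = SimulationConfig(n_mz_pairs=200, n_dz_pairs=200, n_unrelated=0,
                               n_snps=10, n_genes=30, exons_per_gene_range=(1, 1),
                               n_latent_factors=0, latent_phenotype_corr=(),
                               age_effect_sd=0.0, age2_effect_sd=0.0,
                               technical_effect_sd=0.0, seed=21)
        cohort = simulate_cohort(cfg)
        vals = cohort.expression.values.to_numpy()
        mz_r, dz_r = [], []
        for i in range(vals.shape[0]):
            y = vals[i]
            mz_r.append(np.corrcoef(y[0:400:2], y[1:400:2])[0, 1])
            dz_r.append(np.corrcoef(y[400:800:2], y[401:800:2])[0, 1])
        assert np.mean(mz_r) > np.mean(dz_r) + 0.1


class TestTransNetwork:
    def _cohort(self, seed=0):
        cfg = SimulationConfig(n_mz_pairs=120, n_dz_pairs=170, n_unrelated=120,
                               n_snps=20, n_genes=8, exons_per_gene_range=(1, 1),
                               n_latent_factors=0, latent_phenotype_corr=(),
                               effect_grid=[PlantedEffect("gxe_interaction", "", "",
                                                          beta_snp=0.2,
                                                          beta_interaction=0.06)],
                               seed=seed)
        return simulate_cohort(cfg)

    def test_requires_gxe_mediator(self):
        cohort = self._cohort()
        with pytest.raises(ConfigurationError):
            plant_trans_network(cohort, "G0005", 1, 0.5)

    def test_fraction_bounds(self):
        cohort = self._cohort()
        med = cohort.truth.effects[0].gene_id
        with pytest.raises(ConfigurationError):
            plant_trans_network(cohort, med, 1, 1.5)

    @pytest.mark.parametrize("fraction", [0.0, 1.0])
    def test_mediation_endpoints(self, fraction):
        from gxeqtl import mediation_test
        scores = []
        for seed in range(6):
            cohort = self._cohort(seed)
            med = cohort.truth.effects[0]
            tg = [g for g in sorted(set(cohort.expression.gene_ids))
                  if g != med.gene_id][0]
            cohort = plant_trans_network(cohort, med.gene_id, 1, fraction,
                                         beta_interaction=0.06, target_genes=[tg])
            gi = cohort.expression.gene_ids
            y = cohort.expression.values.loc[gi[gi == tg].index[0]].to_numpy(float)
            e = cohort.expression.values.loc[gi[gi == med.gene_id].index[0]].to_numpy(float)
            res = mediation_test(
                y, e, cohort.genotypes.dosages[med.snp_id].to_numpy(float),
                cohort.metadata.table["bmi"].to_numpy(float),
                cohort.metadata.table["age"].to_numpy(float))
            scores.append(res.mediation_score)
        assert abs(np.median(scores) - fraction) < 0.2

    def test_truth_table_records_targets(self):
        cohort = self._cohort()
        med = cohort.truth.effects[0].gene_id
        cohort = plant_trans_network(cohort, med, 3, 0.8)
        trans = [e for e in cohort.truth.effects if e.kind == "trans_mediated"]
        assert len(trans) == 3
        assert all(e.mediator_gene_id == med and e.mediation_fraction == 0.8
                   for e in trans)

    def test_conflicting_cis_plants_rejected(self):
        from gxeqtl.datatypes import TruthTable
        tt = TruthTable()
        tt.add(PlantedEffect("main_eqtl", "G1", "snp1", beta_snp=0.3))
        with pytest.raises(ValueError):
            tt.add(PlantedEffect("gxe_interaction", "G1", "snp2", beta_interaction=0.05))
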