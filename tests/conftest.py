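import numpy as np
import pytest

from gxeqtl import PlantedEffect, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Compact cohort with one planted interaction, one main eQTL and a
    mediated trans network; shared across read-only tests."""
    cfg = SimulationConfig(
        n_mz_pairs=30, n_dz_pairs=40, n_unrelated=20,
        n_snps=300, n_genes=30, exons_per_gene_range=(1, 3),
        effect_grid=[
            # strong effects: at n = 180 this fixture checks mechanics, not power
            PlantedEffect("gxe_interaction", "", "", beta_snp=0.2, beta_interaction=0.3),
            PlantedEffect("main_eqtl", "", "", beta_snp=0.4),
            PlantedEffect("trans_mediated", "", "", beta_interaction=0.3,
                          mediator_gene_id="__first_gxe__", n_trans_targets=4,
                          mediation_fraction=0.8),
        ],
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def big_null_cohort():
    """700 samples, no planted effects, no latent confounders."""
    cfg = SimulationConfig(
        n_mz_pairs=120, n_dz_pairs=170, n_unrelated=120,
        n_snps=40, n_genes=40, exons_per_gene_range=(1, 2),
        n_latent_factors=0, latent_phenotype_corr=(),
        effect_grid=[], seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
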