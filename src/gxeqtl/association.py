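"""Transcriptome-wide phenotype association under the twin mixed model.

Each meta-exon's inverse-normal-transformed expression is regressed on the
phenotype (BMI or visceral fat), age, age squared and technical covariates,
with family and zygosity random intercepts capturing twin relatedness. The
phenotype is tested with a one-degree-of-freedom likelihood ratio comparing
the full model against the same model with the phenotype omitted, both
fitted by maximum likelihood. Per-scan q-values give a within-tissue FDR; a
gene is called associated when at least one of its exons passes the FDR
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, SampleMetadata
from .twinlmm import TwinLMM, lrt_pvalue
from .qvalues import estimate_pi0_qvalues, qvalues_from_pi0


@dataclass
class AssociationResult:
    meta_exon_id: str
    beta: float
    se: float
    lrt: float
    pvalue: float
    qvalue: float | None = None
    var_family: float = np.nan
    var_zygosity: float = np.nan
    converged: bool = True


def build_design(metadata: SampleMetadata, phenotype_name: str,
                 include_phenotype: bool = True,
                 categorical_covariates: tuple[str, ...] = ()) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design: intercept, phenotype, centered age and age^2,
    standardized continuous technical covariates, optional categorical
    covariates as dummy columns.

    Age squared is computed from centered age for numerical stability; the
    fit space is identical to using raw age and age^2.
    """
    t = metadata.table
    pheno = t[phenotype_name].to_numpy(dtype=float)
    if np.isnan(pheno).mean() > 0.10:
        raise ValueError(f"phenotype {phenotype_name!r} missing for more than 10% of samples")
    age_c = t["age"].to_numpy(dtype=float)
    age_c = age_c - age_c.mean()
    cols = [np.ones(len(t))]
    names = ["intercept"]
    if include_phenotype:
        cols.append(pheno)
        names.append(phenotype_name)
    cols += [age_c, age_c ** 2]
    names += ["age", "age2"]
    for c in metadata.technical_columns:
        v = t[c].to_numpy(dtype=float)
        sd = v.std()
        cols.append((v - v.mean()) / sd if sd > 0 else v - v.mean())
        names.append(c)
    for c in categorical_covariates:
        dummies = pd.get_dummies(t[c], prefix=c, drop_first=True)
        for col in dummies.columns:
            cols.append(dummies[col].to_numpy(dtype=float))
            names.append(col)
    return np.column_stack(cols), names


def fit_lmm_lrt(expression: np.ndarray | pd.Series, metadata: SampleMetadata,
                phenotype_name: str = "bmi",
                categorical_covariates: tuple[str, ...] = (),
                meta_exon_id: str = "") -> AssociationResult:
    """Twin-LMM likelihood-ratio test of the phenotype for one meta-exon."""
    y = np.asarray(expression, dtype=float)
    fam = metadata.table["family"].to_numpy()
    zyg = metadata.table["zygosity"].to_numpy()
    X_full, names_full = build_design(metadata, phenotype_name, True, categorical_covariates)
    X_null, _ = build_design(metadata, phenotype_name, False, categorical_covariates)
    full = TwinLMM(X_full, names_full, fam, zyg)
    null = TwinLMM(X_null, [n for n in names_full if n != phenotype_name], fam, zyg)
    return _test_one(full, null, y, metadata, phenotype_name, meta_exon_id)


def _test_one(full: TwinLMM, null: TwinLMM, y: np.ndarray, metadata: SampleMetadata,
              phenotype_name: str, meta_exon_id: str,
              reml_variances: bool = True) -> AssociationResult:
    fit_f = full.fit(y, reml=False)
    fit_n = null.fit(y, reml=False)
    lrt, p = lrt_pvalue(fit_f.loglik, fit_n.loglik)
    beta, se = fit_f.coef(phenotype_name)
    if reml_variances:  # variance components reported under REML
        vfit = full.fit(y, reml=True)
    else:
        vfit = fit_f
    return AssociationResult(
        meta_exon_id=meta_exon_id, beta=beta, se=se, lrt=lrt, pvalue=p,
        var_family=vfit.var_family, var_zygosity=vfit.var_zygosity,
        converged=fit_f.converged and fit_n.converged,
    )


def transcriptome_scan(matrix: ExpressionMatrix, metadata: SampleMetadata,
                       phenotype_name: str = "bmi", fdr: float = 0.05,
                       categorical_covariates: tuple[str, ...] = ()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phenotype association for every meta-exon plus a gene-level summary.

    Returns ``(exon_table, gene_table)``. q-values are computed within the
    scan; a gene is associated if any of its exons has q <= ``fdr``.
    """
    matrix.require_state("int_transformed", "filtered", "residualized")
    meta = metadata.subset(matrix.sample_ids)
    fam = meta.table["family"].to_numpy()
    zyg = meta.table["zygosity"].to_numpy()
    X_full, names_full = build_design(meta, phenotype_name, True, categorical_covariates)
    X_null, _ = build_design(meta, phenotype_name, False, categorical_covariates)
    full = TwinLMM(X_full, names_full, fam, zyg)
    null = TwinLMM(X_null, [n for n in names_full if n != phenotype_name], fam, zyg)

    vals = matrix.values.to_numpy(dtype=float)
    results = [
        _test_one(full, null, vals[i], meta, phenotype_name, str(mid), reml_variances=False)
        for i, mid in enumerate(matrix.meta_exon_ids)
    ]
    table = pd.DataFrame([r.__dict__ for r in results]).set_index("meta_exon_id")
    table["gene_id"] = matrix.gene_ids.to_numpy()
    if len(table) >= 100:
        table["qvalue"] = estimate_pi0_qvalues(table["pvalue"].to_numpy()).qvalues
    else:
        # small panels: pi0 is not estimable, fall back to pi0 = 1 (BH)
        table["qvalue"] = qvalues_from_pi0(table["pvalue"].to_numpy(), 1.0)

    gene = (
        table.groupby("gene_id")
        .agg(n_exons=("pvalue", "size"), min_qvalue=("qvalue", "min"),
             min_pvalue=("pvalue", "min"))
        .assign(associated=lambda d: d["min_qvalue"] <= fdr)
    )
    return table, gene


def residualize_family_technical(matrix: ExpressionMatrix, metadata: SampleMetadata,
                                 categorical_covariates: tuple[str, ...] = ()) -> ExpressionMatrix:
    """Expression residuals corrected for family structure and technical
    covariates (not for the phenotype or age).

    Fixed effects: intercept + technical covariates; family/zygosity enter as
    random intercepts whose BLUPs are subtracted. This is the input both to
    latent-factor estimation and to the non-factor-corrected scan branches.
    """
    meta = metadata.subset(matrix.sample_ids)
    t = meta.table
    cols = [np.ones(len(t))]
    names = ["intercept"]
    for c in meta.technical_columns:
        v = t[c].to_numpy(dtype=float)
        sd = v.std()
        cols.append((v - v.mean()) / sd if sd > 0 else v - v.mean())
        names.append(c)
    for c in categorical_covariates:
        dummies = pd.get_dummies(t[c], prefix=c, drop_first=True)
        for col in dummies.columns:
            cols.append(dummies[col].to_numpy(dtype=float))
            names.append(col)
    X = np.column_stack(cols)
    model = TwinLMM(X, names, t["family"].to_numpy(), t["zygosity"].to_numpy())
    vals = matrix.values.to_numpy(dtype=float)
    out = np.empty_like(vals)
    for i in range(vals.shape[0]):
        out[i] = model.residualize(vals[i])
    return matrix.advance(
        pd.DataFrame(out, index=matrix.meta_exon_ids, columns=matrix.sample_ids),
        "residualized",
    )
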