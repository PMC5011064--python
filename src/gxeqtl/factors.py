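"""Latent-factor estimation on corrected residuals, and residualization.

Hidden expression confounders (batch effects, cell-type composition and
other broad variance components) are estimated as latent factors of the
family/technical-corrected residual matrix: by default the truncated SVD of
per-feature-standardized residuals, optionally an EM factor analysis. Each
factor's correlation with the phenotype is reported so phenotype-correlated
factors can be excluded before residualization, which reduces collinearity
with the interaction term in downstream scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix


@dataclass
class LatentFactorModel:
    scores: pd.DataFrame       # sample x k, orthogonal columns
    loadings: pd.DataFrame     # meta-exon x k
    variance_explained: np.ndarray
    phenotype_corr: pd.DataFrame | None = None  # per-factor r and p

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def factors_below_corr(self, threshold: float) -> list[str]:
        """Factor names with |phenotype correlation| <= threshold."""
        if self.phenotype_corr is None:
            raise ValueError("model was estimated without a phenotype")
        keep = self.phenotype_corr["r"].abs() <= threshold
        return list(self.phenotype_corr.index[keep])


def estimate_latent_factors(matrix: ExpressionMatrix, k: int = 50, seed: int = 0,
                            phenotype: pd.Series | None = None,
                            method: str = "svd") -> LatentFactorModel:
    """Estimate k latent factors capturing broad expression variance.

    Rows (meta-exons) are standardized, then factors are the top-k left
    singular directions in sample space, ordered by variance explained
    (non-increasing). Sign convention: the largest-|loading| entry of each
    factor is positive. ``method='factor_analysis'`` substitutes an EM
    factor analysis (scikit-learn) seeded by ``seed``.
    """
    n_feat, n_samp = matrix.values.shape
    if k >= min(n_feat, n_samp):
        raise ValueError(f"k = {k} must be < min(n_features, n_samples) = {min(n_feat, n_samp)}")
    vals = matrix.values.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (vals - mu) / sd  # feature x sample

    if method == "svd":
        u, s, vt = np.linalg.svd(z.T, full_matrices=False)  # sample x feature
        scores = u[:, :k] * s[:k]
        loadings = vt[:k].T
        var_exp = (s[:k] ** 2) / (s ** 2).sum()
    elif method == "factor_analysis":
        from sklearn.decomposition import FactorAnalysis

        fa = FactorAnalysis(n_components=k, random_state=seed)
        scores = fa.fit_transform(z.T)
        loadings = fa.components_.T
        var_exp = (scores ** 2).sum(axis=0)
        order = np.argsort(-var_exp)
        scores, loadings, var_exp = scores[:, order], loadings[:, order], var_exp[order]
        var_exp = var_exp / (z ** 2).sum()
    else:
        raise ValueError(f"unknown factor method {method!r}")

    # fix signs: largest-|loading| entry positive
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    names = [f"factor{j + 1}" for j in range(k)]
    scores_df = pd.DataFrame(scores, index=matrix.sample_ids, columns=names)
    loadings_df = pd.DataFrame(loadings, index=matrix.meta_exon_ids, columns=names)

    pheno_corr = None
    if phenotype is not None:
        ph = phenotype.reindex(matrix.sample_ids).to_numpy(dtype=float)
        rows = []
        for j in range(k):
            r, p = stats.pearsonr(scores[:, j], ph)
            rows.append((names[j], r, p))
        pheno_corr = pd.DataFrame(rows, columns=["factor", "r", "p"]).set_index("factor")
    return LatentFactorModel(scores_df, loadings_df, np.asarray(var_exp), pheno_corr)


def residualize(matrix: ExpressionMatrix,
                covariates: pd.DataFrame | None = None,
                factors: LatentFactorModel | None = None,
                exclude_phenotype_correlated: float | None = None) -> ExpressionMatrix:
    """Per-feature OLS residuals against covariates and/or factor scores.

    Residuals are orthogonal to every regressor by construction. With
    ``exclude_phenotype_correlated`` set, factors whose |r| with the
    phenotype exceeds the threshold are dropped from the design first (the
    factor model must have been estimated with a phenotype).
    """
    cols = [pd.Series(1.0, index=matrix.sample_ids, name="intercept")]
    if covariates is not None:
        cov = covariates.reindex(matrix.sample_ids)
        if cov.isna().any().any():
            raise ValueError("covariate rows do not align with samples")
        for c in cov.columns:
            cols.append(cov[c].astype(float))
    if factors is not None:
        use = list(factors.scores.columns)
        if exclude_phenotype_correlated is not None:
            use = factors.factors_below_corr(exclude_phenotype_correlated)
        for c in use:
            cols.append(factors.scores[c].reindex(matrix.sample_ids))
    D = pd.concat(cols, axis=1)
    X = D.to_numpy(dtype=float)
    names = list(D.columns)

    # rank check with offender names
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps * 100
    bad = [names[i] for i in range(len(names)) if diag[i] < tol]
    if bad:
        raise ValueError(f"rank-deficient residualization design; dependent columns: {bad}")

    Y = matrix.values.to_numpy(dtype=float).T  # sample x feature
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ beta).T
    out = pd.DataFrame(resid, index=matrix.meta_exon_ids, columns=matrix.sample_ids)
    return ExpressionMatrix(out, "residualized", matrix.gene_ids)
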