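"""Exact maximum-likelihood linear mixed model for twin-pair cohorts.

The model is ``y = X beta + u_family + u_zygosity + e`` with independent
Gaussian random intercepts for family (shared by co-twins) and zygosity
(shared only by MZ co-twins; unique for each DZ twin and singleton). With
families of size at most two, the marginal covariance is block diagonal in
2x2 pair blocks, so rotating each pair onto its within-pair sum and
difference diagonalizes the model into five homoscedastic observation
classes:

====================  =========================================
class                 variance / sigma_e^2 (a = v_fam/sigma_e^2,
                      b = v_zyg/sigma_e^2)
====================  =========================================
MZ pair difference    1
MZ pair sum           1 + 2a + 2b
DZ pair difference    1 + b
DZ pair sum           1 + 2a + b
singleton             1 + a + b
====================  =========================================

Profiling out beta and sigma_e^2 leaves a two-parameter likelihood in
(a, b) that is maximized numerically; per-class Gram matrices make each
likelihood evaluation O(p^2). Both full and reduced models are fitted by ML
so that likelihood-ratio tests of fixed effects are valid; REML is available
for variance-component reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

CLASS_MZ_DIFF, CLASS_MZ_SUM, CLASS_DZ_DIFF, CLASS_DZ_SUM, CLASS_SINGLE = range(5)
_SQRT2 = np.sqrt(2.0)


class SingularDesignError(ValueError):
    """Fixed-effect design is rank deficient; names the collinear columns."""


@dataclass
class TwinTransform:
    """Orthogonal rotation onto within-pair sums/differences plus singletons."""

    first: np.ndarray     # index of first twin per pair
    second: np.ndarray    # index of second twin per pair
    is_mz: np.ndarray     # bool per pair
    singles: np.ndarray   # indices of unpaired samples
    n: int

    @classmethod
    def from_codes(cls, family: np.ndarray, zygosity: np.ndarray) -> "TwinTransform":
        fam = pd.Series(family)
        first, second, is_mz, singles = [], [], [], []
        for _, idx in fam.groupby(fam, sort=False).groups.items():
            idx = list(idx)
            if len(idx) == 1:
                singles.append(idx[0])
            elif len(idx) == 2:
                i, j = idx
                first.append(i)
                second.append(j)
                is_mz.append(zygosity[i] == zygosity[j])
            else:
                raise ValueError(
                    f"family with {len(idx)} members; only pairs and singletons are supported"
                )
        return cls(
            np.asarray(first, dtype=int),
            np.asarray(second, dtype=int),
            np.asarray(is_mz, dtype=bool),
            np.asarray(singles, dtype=int),
            n=len(family),
        )

    @property
    def class_labels(self) -> np.ndarray:
        """Variance-class label per transformed row ([pair sums, pair diffs, singles])."""
        sums = np.where(self.is_mz, CLASS_MZ_SUM, CLASS_DZ_SUM)
        diffs = np.where(self.is_mz, CLASS_MZ_DIFF, CLASS_DZ_DIFF)
        return np.concatenate([sums, diffs, np.full(len(self.singles), CLASS_SINGLE)])

    def forward(self, y: np.ndarray) -> np.ndarray:
        """Rotate sample-space vectors/matrices (first axis = samples)."""
        yi, yj = y[self.first], y[self.second]
        return np.concatenate(
            [(yi + yj) / _SQRT2, (yi - yj) / _SQRT2, y[self.singles]], axis=0
        )

    def backward(self, yt: np.ndarray) -> np.ndarray:
        """Inverse rotation (the transform is orthogonal)."""
        k = len(self.first)
        out_shape = (self.n,) + yt.shape[1:]
        out = np.empty(out_shape, dtype=yt.dtype)
        s, d = yt[:k], yt[k:2 * k]
        out[self.first] = (s + d) / _SQRT2
        out[self.second] = (s - d) / _SQRT2
        out[self.singles] = yt[2 * k:]
        return out


def _class_weights(a: float, b: float) -> np.ndarray:
    return np.array([1.0, 1.0 + 2 * a + 2 * b, 1.0 + b, 1.0 + 2 * a + b, 1.0 + a + b])


@dataclass
class TwinLMMFit:
    beta: np.ndarray
    se: np.ndarray
    sigma2_e: float
    var_family: float
    var_zygosity: float
    loglik: float
    converged: bool
    fallback: str | None
    column_names: list[str]

    def coef(self, name: str) -> tuple[float, float]:
        i = self.column_names.index(name)
        return float(self.beta[i]), float(self.se[i])


def check_design_rank(X: np.ndarray, names: list[str]) -> None:
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps * 100
    bad = [names[i] for i in range(len(names)) if diag[i] < tol]
    if bad:
        raise SingularDesignError(f"collinear fixed-effect columns: {bad}")


class TwinLMM:
    """ML/REML fitter for one fixed-effect design shared across outcomes.

    Build once per design; :meth:`fit` is then cheap per expression vector,
    which is what a transcriptome-wide scan needs.
    """

    def __init__(self, X: np.ndarray, column_names: list[str],
                 family: np.ndarray, zygosity: np.ndarray):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 20:
            raise ValueError("need at least 20 samples")
        check_design_rank(X, column_names)
        self.column_names = list(column_names)
        self.transform = TwinTransform.from_codes(np.asarray(family), np.asarray(zygosity))
        self.Xt = self.transform.forward(X)
        self.labels = self.transform.class_labels
        self.n, self.p = X.shape
        self._class_rows = [np.flatnonzero(self.labels == c) for c in range(5)]
        self._n_c = np.array([len(r) for r in self._class_rows], dtype=float)
        self._G = [self.Xt[r].T @ self.Xt[r] for r in self._class_rows]

    # -- profiled likelihood pieces -------------------------------------

    def _suffstats(self, yt: np.ndarray):
        h = [self.Xt[r].T @ yt[r] for r in self._class_rows]
        s = np.array([float(yt[r] @ yt[r]) for r in self._class_rows])
        return h, s

    def _profile(self, a: float, b: float, h, s, reml: bool):
        w = _class_weights(a, b)
        inv_w = 1.0 / w
        A = sum(iw * G for iw, G in zip(inv_w, self._G))
        rhs = sum(iw * hc for iw, hc in zip(inv_w, h))
        try:
            cho = np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            return None
        beta = np.linalg.solve(A, rhs)
        rss = float(inv_w @ s - rhs @ beta)
        rss = max(rss, 1e-300)
        logdet_w = float(self._n_c @ np.log(w))
        if reml:
            df = self.n - self.p
            sigma2 = rss / df
            logdet_A = 2.0 * float(np.log(np.diag(cho)).sum())
            ll = -0.5 * (df * np.log(2 * np.pi * sigma2) + df + logdet_w + logdet_A)
        else:
            sigma2 = rss / self.n
            ll = -0.5 * (self.n * np.log(2 * np.pi * sigma2) + self.n + logdet_w)
        return ll, beta, sigma2, A

    def fit(self, y: np.ndarray, reml: bool = False) -> TwinLMMFit:
        yt = self.transform.forward(np.asarray(y, dtype=float))
        h, s = self._suffstats(yt)

        def negll(theta):
            out = self._profile(theta[0], theta[1], h, s, reml)
            return np.inf if out is None else -out[0]

        best = None
        fallback = None
        for x0 in ((0.3, 0.3), (0.02, 0.02), (1.5, 1.5)):
            res = optimize.minimize(negll, x0=np.asarray(x0), method="L-BFGS-B",
                                    bounds=[(0.0, 200.0)] * 2)
            if best is None or res.fun < best.fun - 1e-10:
                best = res
            if res.success and best.fun < np.inf:
                break
        converged = bool(best.success and np.isfinite(best.fun))
        if not converged:
            # collapse to a family-only random intercept and flag
            res = optimize.minimize(lambda t: negll((t[0], 0.0)), x0=np.array([0.3]),
                                    method="L-BFGS-B", bounds=[(0.0, 200.0)])
            best_theta = np.array([res.x[0], 0.0])
            fallback = "family_only"
        else:
            best_theta = best.x
        ll, beta, sigma2, A = self._profile(best_theta[0], best_theta[1], h, s, reml)
        cov = sigma2 * np.linalg.inv(A)
        return TwinLMMFit(
            beta=beta,
            se=np.sqrt(np.diag(cov)),
            sigma2_e=sigma2,
            var_family=best_theta[0] * sigma2,
            var_zygosity=best_theta[1] * sigma2,
            loglik=float(ll),
            converged=converged,
            fallback=fallback,
            column_names=self.column_names,
        )

    def residualize(self, y: np.ndarray) -> np.ndarray:
        """GLS-whitened residuals: fixed effects and family/zygosity
        covariance removed.

        In the rotated space each coordinate's GLS residual is scaled by
        1/sqrt(w), so under the model the result is i.i.d. noise (scaled to
        the unit-weight class); rotating back gives decorrelated per-sample
        residuals, which keeps downstream per-pair OLS scans calibrated.
        Full BLUP subtraction (1/w) would over-shrink pair sums and induce
        negative within-pair correlation.
        """
        fit = self.fit(y, reml=True)
        a = fit.var_family / fit.sigma2_e
        b = fit.var_zygosity / fit.sigma2_e
        w = _class_weights(a, b)[self.labels]
        yt = self.transform.forward(np.asarray(y, dtype=float))
        rt = yt - self.Xt @ fit.beta
        return self.transform.backward(rt / np.sqrt(w))


def lrt_pvalue(ll_full: float, ll_null: float, df: int = 1) -> tuple[float, float]:
    """One-degree-of-freedom likelihood-ratio statistic (clipped at 0) and p."""
    lrt = max(0.0, 2.0 * (ll_full - ll_null))
    return lrt, float(stats.chi2.sf(lrt, df))
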