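"""Storey pi0 estimation, q-values, and pi1 sharing statistics.

pi0 estimates the proportion of true null hypotheses in a p-value set; its
complement pi1 = 1 - pi0 measures the proportion of true associations and is
used here to quantify sharing of effects between tissues or cohorts. pi0 is
estimated on the lambda grid 0.05, 0.10, ..., 0.95 with a cubic extrapolation
to lambda -> 1 (a bootstrap-minimization alternative is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


@dataclass
class QValueResult:
    pvalues: np.ndarray
    pi0: float
    qvalues: np.ndarray

    @property
    def pi1(self) -> float:
        return 1.0 - self.pi0


_DF3_LAM_CACHE: dict[bytes, float] = {}


def _df3_penalty(x: np.ndarray) -> float:
    """Smoothing-spline penalty giving ~3 effective df on grid ``x``.

    The smoother is linear in y, so its effective degrees of freedom are the
    trace of the hat matrix, obtained by smoothing unit vectors; the penalty
    is found by bisection and cached per grid.
    """
    from scipy.interpolate import make_smoothing_spline

    key = x.tobytes()
    if key in _DF3_LAM_CACHE:
        return _DF3_LAM_CACHE[key]

    def edf(lam: float) -> float:
        tr = 0.0
        for i in range(len(x)):
            e = np.zeros(len(x))
            e[i] = 1.0
            tr += make_smoothing_spline(x, e, lam=lam)(x[i])
        return tr

    lo, hi = 1e-8, 1e4
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        if edf(mid) > 3.0:
            lo = mid
        else:
            hi = mid
    _DF3_LAM_CACHE[key] = np.sqrt(lo * hi)
    return _DF3_LAM_CACHE[key]


def _smoothing_spline_df3(x: np.ndarray, y: np.ndarray):
    """Cubic smoothing spline with the penalty tuned to ~3 effective df."""
    from scipy.interpolate import make_smoothing_spline

    return make_smoothing_spline(x, y, lam=_df3_penalty(x))


def _pi0_smoother(pvalues: np.ndarray, method: str, rng: np.random.Generator | None) -> float:
    m = pvalues.size
    pi0_lambda = np.array([(pvalues > lam).sum() / (m * (1 - lam)) for lam in LAMBDA_GRID])
    if method == "smoother":
        # df-3 cubic smoothing spline over the lambda grid, evaluated at the
        # grid maximum
        spline = _smoothing_spline_df3(LAMBDA_GRID, pi0_lambda)
        pi0 = float(spline(LAMBDA_GRID[-1]))
    elif method == "bootstrap":
        if rng is None:
            rng = np.random.default_rng(0)
        min_pi0 = pi0_lambda.min()
        mse = np.zeros_like(pi0_lambda)
        for _ in range(100):
            pb = rng.choice(pvalues, size=m, replace=True)
            pi0_b = np.array([(pb > lam).sum() / (m * (1 - lam)) for lam in LAMBDA_GRID])
            mse += (pi0_b - min_pi0) ** 2
        pi0 = float(pi0_lambda[np.argmin(mse)])
    else:
        raise ValueError(f"unknown pi0 method {method!r}")
    return float(np.clip(pi0, 0.0, 1.0))


def qvalues_from_pi0(pvalues: np.ndarray, pi0: float) -> np.ndarray:
    """q(p_(i)) = min_{j >= i} pi0 * m * p_(j) / j over sorted p-values
    (monotone non-decreasing in p-value rank). pi0 = 1 gives Benjamini-
    Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    pi0_q = max(pi0, 1.0 / m)
    q_sorted = pi0_q * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def estimate_pi0_qvalues(pvalues: np.ndarray, method: str = "smoother",
                         rng: np.random.Generator | None = None) -> QValueResult:
    """Storey pi0 and q-values for a set of p-values.

    q(p_(i)) = min_{j >= i} pi0 * m * p_(j) / j over the sorted p-values, so
    q-values are monotone non-decreasing in p-value rank.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size < 100:
        raise ValueError("need at least 100 p-values for a stable pi0 estimate")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    pi0 = _pi0_smoother(p, method, rng)
    return QValueResult(pvalues=p, pi0=pi0, qvalues=qvalues_from_pi0(p, pi0))


def pi1_replication(discovery_pairs: list, replication_pvalues: dict | "np.ndarray",
                    min_pairs: int = 100) -> tuple[float, bool]:
    """pi1 of replication p-values matched to significant discovery pairs.

    ``replication_pvalues`` maps pair ID -> p-value (or is an array aligned
    with ``discovery_pairs``). Returns ``(pi1, stable)`` where ``stable`` is
    False when fewer than ``min_pairs`` pairs matched.
    """
    if isinstance(replication_pvalues, dict):
        matched = np.array([replication_pvalues[k] for k in discovery_pairs
                            if k in replication_pvalues], dtype=float)
    else:
        matched = np.asarray(replication_pvalues, dtype=float)
    if matched.size == 0:
        raise ValueError("no matched discovery/replication pairs")
    stable = matched.size >= min_pairs
    if matched.size < 100:
        # too few pairs for the smoother; fall back to the most lenient
        # lambda = 0.5 point estimate, flagged unstable
        pi0 = float(np.clip((matched > 0.5).sum() / (matched.size * 0.5), 0, 1))
        return 1.0 - pi0, False
    res = estimate_pi0_qvalues(matched)
    return res.pi1, stable
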