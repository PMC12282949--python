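"""Shared statistical helpers: q-value estimation and two-sample tests.

The false-discovery-rate machinery follows Storey's q-value construction with a
smoother-based estimate of pi0 (the proportion of true nulls) and a
Benjamini-Hochberg fallback (pi0 = 1) when the p-value collection is too small
or the smoother is unstable.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = ["estimate_qvalues", "bh_qvalues", "welch_ttest", "estimate_pi0"]


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values with pi0 = 1)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Smoother estimate of the null proportion pi0.

    Evaluates pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on a lambda grid
    and extrapolates with a cubic polynomial smoother to lambda -> max grid
    value. Returns a value in (0, 1]; NaN signals an unstable estimate.
    """
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = p.size
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if np.any(~np.isfinite(pi0_lambda)):
        return float("nan")
    coeffs = np.polyfit(lambdas, pi0_lambda, deg=3)
    pi0 = float(np.polyval(coeffs, lambdas.max()))
    if not np.isfinite(pi0) or pi0 <= 0:
        return float("nan")
    return min(pi0, 1.0)


def estimate_qvalues(p, min_for_storey: int = 100) -> np.ndarray:
    """q-values for a collection of p-values.

    Uses Storey's estimator (q_i = pi0 * m * p_(i) / i, monotonised) with the
    smoother pi0; falls back to Benjamini-Hochberg (pi0 = 1) for fewer than
    `min_for_storey` p-values or when the pi0 smoother is unstable.
    NaN p-values yield NaN q-values and are excluded from the calibration.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    pv = p[mask]
    if pv.size == 0:
        return out
    if np.any((pv <= 0) | (pv > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if pv.size < min_for_storey:
        pi0 = 1.0
    else:
        pi0 = estimate_pi0(pv)
        if not np.isfinite(pi0):
            warnings.warn("pi0 smoother unstable; falling back to BH (pi0=1)")
            pi0 = 1.0
    out[mask] = np.clip(bh_qvalues(pv) * pi0, 0.0, 1.0)
    return out


def welch_ttest(a, b, alternative: str = "two-sided", pooled: bool = False):
    """Two-sample t-test, unequal variance by default.

    Returns (delta, t, p) with delta = mean(a) - mean(b). With fewer than two
    observations in either group returns (delta-or-nan, nan, nan).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        delta = a.mean() - b.mean() if (a.size and b.size) else float("nan")
        return delta, float("nan"), float("nan")
    delta = float(a.mean() - b.mean())
    res = stats.ttest_ind(a, b, equal_var=pooled, alternative=alternative)
    p = float(res.pvalue)
    # q-value machinery requires p in (0, 1]
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return delta, float(res.statistic), p
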