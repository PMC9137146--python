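"""Multivariate-normality diagnostics.

Mardia's multivariate skewness and kurtosis are affine-invariant moment
summaries; for a bivariate Gaussian sample their population values are 0 and
8 whatever the covariance.  The associated tests compare the sample values
with those references (skewness: n*b1/6 ~ chi2 with p(p+1)(p+2)/6 degrees of
freedom; kurtosis: asymptotically normal around p(p+2) with variance
8p(p+2)/n).  ``normal_scores`` is the rank-based probability-integral
transform used to visualise the copula of two phenotypes free of their
margins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["MardiaResult", "mardia", "normal_scores"]


@dataclass(frozen=True)
class MardiaResult:
    """Mardia skewness/kurtosis of a multivariate sample with test p-values."""

    skewness: float
    kurtosis: float
    n: int
    p_skew: float
    p_kurt: float


def mardia(sample: np.ndarray) -> MardiaResult:
    """Mardia's multivariate skewness and kurtosis with normality tests.

    Parameters
    ----------
    sample : (n, p) array
        At least three observations with a nonsingular sample covariance.

    Notes
    -----
    With ``m_ij = (x_i - xbar)' S^{-1} (x_j - xbar)`` (S the maximum-likelihood
    covariance, divisor n), skewness is the mean of ``m_ij**3`` over all pairs
    and kurtosis the mean of ``m_ii**2``.
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("sample must be an (n, p) array with n >= 3")
    n, p = x.shape
    xc = x - x.mean(axis=0)
    S = xc.T @ xc / n
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0 or not np.isfinite(logdet) or np.linalg.cond(S) > 1e12:
        raise ValueError("degenerate sample: singular covariance matrix")
    # b1 = mean_ij (xc_i' S^-1 xc_j)^3 contracts the third central moment
    # tensor with S^-1 three times, avoiding the n x n Gram matrix:
    # b1 = sum_{abc,def} M_abc M_def (S^-1)_ad (S^-1)_be (S^-1)_cf.
    Si = np.linalg.inv(S)
    M3 = np.einsum("ia,ib,ic->abc", xc, xc, xc) / n
    b1 = float(np.einsum("abc,def,ad,be,cf->", M3, M3, Si, Si, Si))
    d = np.einsum("ia,ab,ib->i", xc, Si, xc)
    b2 = float(np.mean(d ** 2))
    df_skew = p * (p + 1) * (p + 2) // 6
    p_skew = float(stats.chi2.sf(n * b1 / 6.0, df_skew))
    z_kurt = (b2 - p * (p + 2)) / np.sqrt(8.0 * p * (p + 2) / n)
    p_kurt = float(2.0 * stats.norm.sf(abs(z_kurt)))
    return MardiaResult(skewness=b1, kurtosis=b2, n=n, p_skew=p_skew, p_kurt=p_kurt)


def normal_scores(values: np.ndarray) -> np.ndarray:
    """Gaussian quantiles of ranks: Phi^{-1}(rank_i / (n + 1)).

    Invariant under strictly monotone transforms of the input; ties receive
    average ranks.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise ValueError("values must be a non-empty 1-D array")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf(ranks / (v.size + 1))
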