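"""Shared statistical-test battery (two-sided defaults, alpha = 0.05)."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = [
    "two_proportion_ztest",
    "shuffle_percentile",
    "ranksum",
    "signed_rank",
]


def two_proportion_ztest(k1, n1, k2, n2, alternative="two-sided"):
    """Z-test for two proportions with a pooled variance estimate."""
    if n1 == 0 or n2 == 0:
        return float("nan"), float("nan")
    p1, p2 = k1 / n1, k2 / n2
    p = (k1 + k2) / (n1 + n2)
    se = np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    if alternative == "two-sided":
        p_val = 2 * sps.norm.sf(abs(z))
    elif alternative == "greater":
        p_val = sps.norm.sf(z)
    elif alternative == "less":
        p_val = sps.norm.cdf(z)
    else:
        raise ValueError(alternative)
    return float(z), float(p_val)


def shuffle_percentile(value: float, shuffles: np.ndarray) -> float:
    """Percentile of a value within its shuffle distribution, in [0, 1].

    Ties count half, so a value drawn from the same distribution is
    uniformly distributed on (0, 1).
    """
    s = np.asarray(shuffles, float)
    if s.size == 0:
        return float("nan")
    return float(((s < value).sum() + 0.5 * (s == value).sum()) / s.size)


def ranksum(x, y, alternative="two-sided"):
    """Wilcoxon rank-sum (Mann-Whitney) test p-value."""
    return float(sps.mannwhitneyu(x, y, alternative=alternative).pvalue)


def signed_rank(x, alternative="two-sided"):
    """Wilcoxon signed-rank test of paired differences against zero."""
    return float(sps.wilcoxon(x, alternative=alternative).pvalue)
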