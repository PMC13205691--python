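"""Shared nonparametric test helpers.

Wilcoxon rank-sum comparisons use the exact null distribution when both
sides have n <= 25 and the pooled data are tie-free; otherwise the normal
approximation with continuity correction is used.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import mannwhitneyu

EXACT_MAX_N = 25


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney U). Returns (U, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)
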