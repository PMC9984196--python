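"""Shared statistical primitives.

The Wilcoxon rank-sum (Mann-Whitney U) test is the workhorse comparison for
per-cell smFISH summaries and gene-class bias contrasts. The exact null
distribution is used for small samples without ties; otherwise the normal
approximation with tie and continuity corrections applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._exceptions import InputError

#: Combined sample size up to which the exact rank-sum null is enumerated
#: (when the pooled data contain no ties).
EXACT_MAX_N = 30


@dataclass(frozen=True)
class RankSumResult:
    u_stat: float
    p_value: float
    n_x: int
    n_y: int
    method: str  # "exact" or "asymptotic"


def rank_sum_test(x, y) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration when the combined sample size is at most
    :data:`EXACT_MAX_N` and there are no ties; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InputError("rank-sum test needs at least 2 observations per group")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and pooled.size <= EXACT_MAX_N:
        method = "exact"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return RankSumResult(
        u_stat=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_x=int(x.size),
        n_y=int(y.size),
        method=method,
    )


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment; NaNs pass through.

    Thin wrapper over statsmodels so the adjustment applies only to the
    non-missing entries (genes with undefined tests keep a missing FDR).
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
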