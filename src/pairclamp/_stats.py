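"""Shared statistical helpers (nonparametric tests, rounding conventions)."""

from __future__ import annotations

import numpy as np
from scipy import stats

#: per-group size at or below which the exact Mann-Whitney null is used
EXACT_MW_MAX_N = 8


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p-value for group sizes <= 8 without ties, normal approximation
    with tie correction otherwise (scipy switches internally when ties make
    the exact null invalid).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if max(len(x), len(y)) <= EXACT_MW_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def paired_location_test(before, after) -> tuple[str, float, bool]:
    """Paired comparison with normality gating.

    Shapiro-Wilk on the paired differences selects between a paired t-test
    (p >= 0.05) and the Wilcoxon signed-rank test.  All-zero differences are
    a degenerate case reported as p = 1 with a flag.

    Returns (test_name, p_value, zero_difference_flag).
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    diffs = after - before
    if np.allclose(diffs, 0.0):
        return "wilcoxon", 1.0, True
    if len(diffs) >= 3 and not np.isclose(np.std(diffs), 0.0):
        normal_p = stats.shapiro(diffs).pvalue
    else:
        normal_p = 0.0
    if normal_p >= 0.05:
        return "paired_t", float(stats.ttest_rel(after, before).pvalue), False
    res = stats.wilcoxon(after, before)
    return "wilcoxon", float(res.pvalue), False


def percent(count: int, total: int) -> tuple[float, int]:
    """Fraction of ``total`` as (exact percent, nearest-integer percent)."""
    if total == 0:
        return float("nan"), 0
    value = 100.0 * count / total
    return value, int(np.floor(value + 0.5))
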