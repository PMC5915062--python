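"""Proteome-vs-transcriptome comparison.

Tests whether the genes of differential proteins are higher expressed at
the RNA level than the background of all proteome-identified genes, using
a Wilcoxon rank-sum (Mann-Whitney) test on per-gene mean log2 FPKM across
tumor samples.  Exact enumeration is used for small tie-free samples,
otherwise the normal approximation with tie and continuity correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .model import ExpressionTable

EXACT_MAX_N = 8


def mean_expression(expr: ExpressionTable,
                    genes: list[str]) -> tuple[pd.Series, list[str]]:
    """Per-gene mean log2 expression across samples.

    Returns ``(means, dropped)`` where ``dropped`` lists requested genes
    absent from the table (reported, never silently ignored).
    """
    present = [g for g in genes if g in expr.values.index]
    dropped = [g for g in genes if g not in expr.values.index]
    means = expr.values.loc[present].mean(axis=1)
    means.name = "mean_log2_expression"
    return means, dropped


def wilcoxon_rank_sum(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when min(n_a, n_b) <= 8 and there are no ties;
    normal approximation with tie and continuity correction otherwise.
    Two identical constant samples give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if min(a.size, b.size) <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(res.pvalue, 1.0))


def compare_to_background(diff_genes: list[str],
                          background_genes: list[str],
                          expr: ExpressionTable,
                          p_threshold: float = 0.01) -> dict:
    """Differential genes vs proteome background at the RNA level.

    Both lists are intersected with the expression table; the two-sided
    rank-sum p compares per-gene mean expression, and the verdict is
    ``significant`` iff p < ``p_threshold``.  Direction is reported as the
    difference of medians (positive = differential genes higher).
    """
    diff_means, diff_dropped = mean_expression(expr, diff_genes)
    bg_means, bg_dropped = mean_expression(expr, background_genes)
    if len(diff_means) == 0:
        raise ValueError("no differential genes present in expression table")
    if len(bg_means) == 0:
        raise ValueError("no background genes present in expression table")
    p = wilcoxon_rank_sum(diff_means.to_numpy(), bg_means.to_numpy())
    med_diff = float(np.median(diff_means))
    med_bg = float(np.median(bg_means))
    return {
        "p_value": p,
        "median_diff_genes": med_diff,
        "median_background": med_bg,
        "median_difference": med_diff - med_bg,
        "significant": p < p_threshold,
        "n_diff": int(len(diff_means)),
        "n_background": int(len(bg_means)),
        "dropped_diff_genes": diff_dropped,
        "dropped_background_genes": bg_dropped,
    }
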