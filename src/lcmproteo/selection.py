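"""The three selection regimes for differential proteins.

* all-or-nothing — a presence/absence exclusivity rule: a protein must be
  completely undetected in every excluded group (healthy epithelium and
  stroma), detected in at least ``min_present_target`` samples of the
  target group (7 of 11 early-stage cancers by default), and carry a raw
  p-value below ``p_max``; detection in allowed groups (late-stage cancer)
  is permitted.
* Bonferroni — family-wise control at level alpha; a protein is called
  when p < alpha / m (strict).
* Benjamini-Hochberg — step-up FDR control at level q (p(i) <= i·q/m).

The family size m defaults to the number of proteins actually tested in
the contrast; an explicit override exists because published thresholds do
not always reveal the family they were computed from.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .model import (
    SampleAnnotation,
    SelectionParams,
    SpectralCountMatrix,
    samples_in_group,
)


def all_or_nothing(matrix: SpectralCountMatrix,
                   annotations: list[SampleAnnotation],
                   params: SelectionParams,
                   p_values: pd.Series) -> list[str]:
    """Proteins exclusively detected in the target group.

    Selects proteins with zero counts in every sample of every excluded
    group, presence (count >= 1) in at least ``params.min_present_target``
    samples of ``params.target_group`` and ``p < params.p_max``.  Presence
    in ``params.allow_groups`` is ignored.
    """
    overlap = set(params.exclude_groups) & ({params.target_group} | set(params.allow_groups))
    if overlap:
        raise ValueError(f"exclude groups overlap target/allow groups: {sorted(overlap)}")
    missing = [p for p in matrix.protein_ids if p not in p_values.index]
    if missing:
        raise ValueError(f"p_values missing for protein(s): {missing[:5]}")

    target_cols = samples_in_group(annotations, params.target_group)
    exclude_cols: list[str] = []
    for g in params.exclude_groups:
        exclude_cols.extend(samples_in_group(annotations, g))
    if not target_cols or not exclude_cols:
        raise ValueError("target and exclude groups must be nonempty")

    counts = matrix.counts
    absent_excluded = (counts[exclude_cols] == 0).all(axis=1)
    present_target = (counts[target_cols] >= 1).sum(axis=1) >= params.min_present_target
    significant = p_values.reindex(counts.index) < params.p_max
    mask = absent_excluded & present_target & significant
    return list(counts.index[mask])


def exclusive_in_group(matrix: SpectralCountMatrix,
                       annotations: list[SampleAnnotation],
                       group: str,
                       other_groups: tuple[str, ...],
                       min_present: int = 6) -> list[str]:
    """Proteins detected only in ``group`` (>= min_present samples there)."""
    group_cols = samples_in_group(annotations, group)
    other_cols: list[str] = []
    for g in other_groups:
        other_cols.extend(samples_in_group(annotations, g))
    if not group_cols or not other_cols:
        raise ValueError("group and other_groups must be nonempty")
    counts = matrix.counts
    mask = ((counts[other_cols] == 0).all(axis=1)
            & ((counts[group_cols] >= 1).sum(axis=1) >= min_present))
    return list(counts.index[mask])


def bonferroni(p_values: pd.Series | np.ndarray,
               alpha: float = 0.05,
               m: int | None = None) -> tuple[float, pd.Series]:
    """Bonferroni family-wise correction: flag p < alpha/m (strict).

    Returns ``(threshold, flags)``.  ``m`` defaults to the number of
    p-values supplied.
    """
    p = pd.Series(p_values)
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("family size m must be >= 1")
    threshold = alpha / m
    flags = p < threshold
    flags.name = "bonferroni"
    return threshold, flags


def benjamini_hochberg(p_values: pd.Series | np.ndarray,
                       q: float = 0.05) -> tuple[pd.Series, pd.Series]:
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(flags, adjusted_p)``; rejection uses ``p(i) <= i*q/m`` and
    adjusted p-values are the usual monotone step-up values capped at 1.
    """
    p = pd.Series(p_values, dtype=float)
    arr = p.to_numpy()
    if ((arr <= 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    reject, adj, _, _ = multipletests(arr, alpha=q, method="fdr_bh")
    flags = pd.Series(reject, index=p.index, name="bh")
    adjusted = pd.Series(adj, index=p.index, name="p_adjusted")
    return flags, adjusted


def selection_table(matrix: SpectralCountMatrix,
                    annotations: list[SampleAnnotation],
                    params: SelectionParams,
                    p_values: pd.Series,
                    log2_fc: pd.Series) -> pd.DataFrame:
    """Combined per-protein table with flags for all three regimes."""
    m = params.explicit_m if params.family_size_policy == "explicit_m" else len(p_values)
    threshold, bonf = bonferroni(p_values, params.alpha, m)
    bh_flags, p_adj = benjamini_hochberg(p_values, params.q)
    aon = set(all_or_nothing(matrix, annotations, params, p_values))
    df = pd.DataFrame(
        {
            "protein_id": p_values.index,
            "p_value": p_values.to_numpy(),
            "log2_fc": log2_fc.reindex(p_values.index).to_numpy(),
            "all_or_nothing": [pid in aon for pid in p_values.index],
            "bonferroni": bonf.to_numpy(),
            "bh": bh_flags.to_numpy(),
            "p_adjusted": p_adj.to_numpy(),
        }
    )
    df.attrs["bonferroni_threshold"] = threshold
    return df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
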