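"""Per-protein differential abundance from spectral counts.

Fold-changes are log2 ratios of group means after replacing zero counts
with a small pseudocount (0.125 by default) so that a protein completely
absent from the reference group maps to a finite, large fold-change (a
group mean of 4 against an all-zero reference gives a linear ratio of 32,
i.e. log2 FC = 5).  Two per-protein tests are offered:

``welch_log``
    two-sided unequal-variance t-test on log2 zero-replaced counts — the
    graded-abundance view;
``fisher_presence``
    two-sided exact test on the 2×2 presence/absence table (count >= 1 vs
    count = 0 per sample), the natural companion of the all-or-nothing
    exclusivity rule.  Two-sided p is twice the smaller hypergeometric
    tail, capped at 1.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    ContrastSpec,
    SampleAnnotation,
    SpectralCountMatrix,
    check_annotations,
    samples_in_group,
)

DEFAULT_PSEUDOCOUNT = 0.125

_TINY = np.finfo(float).tiny


def replace_zeros(counts: np.ndarray | pd.DataFrame,
                  pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """Replace zero counts with the pseudocount; positive counts unchanged."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    arr = np.asarray(counts, dtype=float) if not isinstance(counts, pd.DataFrame) else counts.astype(float)
    if (np.asarray(arr) < 0).any():
        raise ValueError("counts must be nonnegative")
    if isinstance(arr, pd.DataFrame):
        return arr.mask(arr == 0, pseudocount)
    out = arr.copy()
    out[out == 0] = pseudocount
    return out


def _group_columns(matrix: SpectralCountMatrix,
                   annotations: list[SampleAnnotation],
                   group: str) -> pd.DataFrame:
    ids = [s for s in samples_in_group(annotations, group) if s in matrix.counts.columns]
    if not ids:
        raise ValueError(f"no samples of group {group!r} in matrix")
    return matrix.counts[ids]


def log2_fold_change(matrix: SpectralCountMatrix,
                     annotations: list[SampleAnnotation],
                     contrast: ContrastSpec) -> pd.Series:
    """log2( mean of zero-replaced counts in group_a / same in group_b )."""
    check_annotations(matrix, annotations)
    a = replace_zeros(_group_columns(matrix, annotations, contrast.group_a),
                      contrast.pseudocount)
    b = replace_zeros(_group_columns(matrix, annotations, contrast.group_b),
                      contrast.pseudocount)
    # log difference rather than log of ratio: antisymmetry holds exactly
    fc = np.log2(a.mean(axis=1)) - np.log2(b.mean(axis=1))
    fc.name = "log2_fc"
    return fc


def presence_counts(matrix: SpectralCountMatrix,
                    annotations: list[SampleAnnotation],
                    group: str) -> pd.Series:
    """Per-protein number of samples in ``group`` with count >= 1."""
    return (_group_columns(matrix, annotations, group) >= 1).sum(axis=1)


def fisher_presence_p(present_a: int, n_a: int, present_b: int, n_b: int) -> float:
    """Two-sided exact presence/absence p: twice the smaller hypergeometric tail.

    The number of detections in group a, conditional on the total number of
    detections, is hypergeometric with population ``n_a + n_b``, successes
    ``present_a + present_b`` and draws ``n_a``.
    """
    if not (0 <= present_a <= n_a and 0 <= present_b <= n_b):
        raise ValueError("presence counts exceed group sizes")
    total = present_a + present_b
    rv = stats.hypergeom(n_a + n_b, total, n_a)
    lower = rv.cdf(present_a)
    upper = rv.sf(present_a - 1)
    return float(min(1.0, 2.0 * min(lower, upper)))


def _welch_log_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    import warnings

    with warnings.catch_warnings():
        # near-constant rows trigger a precision warning; they resolve to p=1
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups with equal means -> no evidence, p = 1
    p = np.where(np.isnan(p), 1.0, p)
    return np.clip(p, _TINY, 1.0)


def differential_test(matrix: SpectralCountMatrix,
                      annotations: list[SampleAnnotation],
                      contrast: ContrastSpec) -> pd.Series:
    """Per-protein two-sided p-value for the configured test method."""
    check_annotations(matrix, annotations)
    ca = _group_columns(matrix, annotations, contrast.group_a)
    cb = _group_columns(matrix, annotations, contrast.group_b)
    if contrast.test_method == "welch_log":
        if ca.shape[1] < 2 or cb.shape[1] < 2:
            raise ValueError("welch_log requires >= 2 samples per group")
        a = np.log2(replace_zeros(ca, contrast.pseudocount).to_numpy())
        b = np.log2(replace_zeros(cb, contrast.pseudocount).to_numpy())
        p = _welch_log_p(a, b)
    else:  # fisher_presence
        pa = (ca >= 1).sum(axis=1).to_numpy()
        pb = (cb >= 1).sum(axis=1).to_numpy()
        p = np.array([
            fisher_presence_p(int(x), ca.shape[1], int(y), cb.shape[1])
            for x, y in zip(pa, pb)
        ])
    return pd.Series(p, index=matrix.counts.index, name="p_value")


def volcano_table(matrix: SpectralCountMatrix,
                  annotations: list[SampleAnnotation],
                  contrast: ContrastSpec) -> pd.DataFrame:
    """Volcano-plot table: (protein_id, log2_fc, neg_log10_p), ascending p."""
    fc = log2_fold_change(matrix, annotations, contrast)
    p = differential_test(matrix, annotations, contrast)
    df = pd.DataFrame(
        {
            "protein_id": matrix.counts.index,
            "log2_fc": fc.to_numpy(),
            "neg_log10_p": -np.log10(p.to_numpy()),
            "p_value": p.to_numpy(),
        }
    )
    return df.sort_values("p_value", kind="mergesort").reset_index(drop=True)[
        ["protein_id", "log2_fc", "neg_log10_p", "p_value"]
    ]


CELL_LINES = ("HeLa", "U87", "HEK293")


def classify_fold_changes(fc: pd.DataFrame, fc_min: float = 2.5) -> pd.Series:
    """Classify proteins by their fold-change pattern across tumor and cell lines.

    ``fc`` has columns ``early_cancer``, ``late_cancer``, ``HeLa``, ``U87``,
    ``HEK293`` of log2 fold-changes versus healthy epithelium.  A protein is

    * ``tumor_and_HeLa`` when both cancer stages and HeLa reach ``fc_min``
      while the non-cervical lines (U87, HEK293) stay below it;
    * ``tumor_only`` when both cancer stages reach ``fc_min`` but HeLa does
      not;
    * ``unclassified`` otherwise.
    """
    needed = {"early_cancer", "late_cancer", *CELL_LINES}
    missing = needed - set(fc.columns)
    if missing:
        raise ValueError(f"fold-change table lacks columns: {sorted(missing)}")
    tumor = (fc["early_cancer"] >= fc_min) & (fc["late_cancer"] >= fc_min)
    hela = fc["HeLa"] >= fc_min
    other = (fc["U87"] >= fc_min) | (fc["HEK293"] >= fc_min)
    label = pd.Series("unclassified", index=fc.index, name="classification")
    label[tumor & hela & ~other] = "tumor_and_HeLa"
    label[tumor & ~hela] = "tumor_only"
    return label


def cell_line_contrast(matrix: SpectralCountMatrix,
                       annotations: list[SampleAnnotation],
                       fc_min: float = 2.5,
                       reference: str = "healthy_epithelium",
                       pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Fold-changes of cancer groups and cell lines vs healthy epithelium.

    Returns one row per protein with the five log2 fold-change columns and a
    ``classification`` column (see :func:`classify_fold_changes`).
    """
    check_annotations(matrix, annotations)
    groups = {"early_cancer": "early_cancer", "late_cancer": "late_cancer"}
    for line in CELL_LINES:
        groups[line] = f"cell_line:{line}"
    present = {a.group for a in annotations}
    missing = [g for g in groups.values() if g not in present]
    if missing:
        raise ValueError(f"matrix lacks group(s): {missing}")
    fc = {}
    for col, group in groups.items():
        contrast = ContrastSpec(group_a=group, group_b=reference,
                                pseudocount=pseudocount)
        fc[col] = log2_fold_change(matrix, annotations, contrast)
    df = pd.DataFrame(fc)
    df["classification"] = classify_fold_changes(df, fc_min)
    return df


def replicate_overlap(protein_sets: list[set[str]]) -> dict:
    """Overlap of identified-protein sets across replicates, in percent.

    ``overall`` is 100 · |intersection| / |union| over all sets; ``pairwise``
    maps each pair of replicate indices to the same statistic for that pair.
    An overlap above 50% is the conventional reproducibility bar.
    """
    if len(protein_sets) < 2:
        raise ValueError("need at least two protein sets")
    if any(len(s) == 0 for s in protein_sets):
        raise ValueError("protein sets must be nonempty")
    union = set().union(*protein_sets)
    inter = set(protein_sets[0]).intersection(*protein_sets[1:])
    pairwise = {}
    for i, j in combinations(range(len(protein_sets)), 2):
        u = protein_sets[i] | protein_sets[j]
        pairwise[(i, j)] = 100.0 * len(protein_sets[i] & protein_sets[j]) / len(u)
    return {
        "overall": 100.0 * len(inter) / len(union),
        "pairwise": pairwise,
        "acceptable": 100.0 * len(inter) / len(union) > 50.0,
    }
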