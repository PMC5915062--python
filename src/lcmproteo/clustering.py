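"""Agglomerative Ward clustering of abundance profiles.

Ward's minimum-variance criterion with Euclidean distance, computed via
the Lance-Williams recurrence on squared distances, with deterministic
tie-breaking by lowest cluster index.  Merge heights follow the common
convention h = sqrt(2 · ΔESS), so that the first merge of two singletons
sits at their Euclidean distance.  The result is a merge list in the same
layout as a SciPy linkage matrix plus the dendrogram leaf order, which is
what a heat map needs to order its rows and columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def ward_cluster(values: np.ndarray | pd.DataFrame) -> tuple[np.ndarray, list[int]]:
    """Cluster the rows of ``values`` under Ward's criterion.

    Returns ``(merges, leaf_order)``.  ``merges`` is an (n−1) × 4 array;
    row t holds (cluster_i, cluster_j, height, size) where original rows
    are clusters 0..n−1 and the cluster formed at step t gets index n+t.
    ``leaf_order`` is the left-to-right dendrogram leaf sequence (left
    child traversed first).
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.isfinite(X).all():
        raise ValueError("values must be finite")
    n = X.shape[0]

    # squared Euclidean distances; for singletons d2 = 2 * ΔESS
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    d2: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = sq[i, j]

    size = {i: 1 for i in range(n)}
    active = list(range(n))
    merges = np.zeros((n - 1, 4))
    for t in range(n - 1):
        # lowest-index pair wins ties (pairs scanned in lexicographic order)
        best = None
        best_d = np.inf
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                d = d2[(min(i, j), max(i, j))]
                if best is None or d < best_d - 1e-12 * max(1.0, best_d):
                    best_d, best = d, (i, j)
        i, j = best
        new = n + t
        merges[t] = (i, j, np.sqrt(max(best_d, 0.0)), size[i] + size[j])
        # Lance-Williams update (Ward) on squared distances
        for k in active:
            if k in (i, j):
                continue
            dki = d2[(min(k, i), max(k, i))]
            dkj = d2[(min(k, j), max(k, j))]
            dij = best_d
            ni, nj, nk = size[i], size[j], size[k]
            d2[(k, new)] = ((ni + nk) * dki + (nj + nk) * dkj - nk * dij) / (ni + nj + nk)
        size[new] = size[i] + size[j]
        active = [k for k in active if k not in (i, j)] + [new]

    def _leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        i, j = int(merges[node - n, 0]), int(merges[node - n, 1])
        return _leaves(i) + _leaves(j)

    return merges, _leaves(2 * n - 2)


def cut_clusters(merges: np.ndarray, n_clusters: int) -> list[set[int]]:
    """Cut the dendrogram into ``n_clusters`` flat clusters of leaf indices."""
    n = merges.shape[0] + 1
    if not (1 <= n_clusters <= n):
        raise ValueError("n_clusters out of range")

    def leaves(node: int) -> set[int]:
        if node < n:
            return {node}
        i, j = int(merges[node - n, 0]), int(merges[node - n, 1])
        return leaves(i) | leaves(j)

    # undo the last (n_clusters - 1) merges
    roots = {2 * n - 2}
    for t in range(n - 2, n - 1 - n_clusters, -1):
        roots.discard(n + t)
        roots.add(int(merges[t, 0]))
        roots.add(int(merges[t, 1]))
    return [leaves(r) for r in sorted(roots)]


def to_newick(merges: np.ndarray, labels: list[str]) -> str:
    """Render the dendrogram as a Newick string with branch lengths."""
    n = merges.shape[0] + 1
    if len(labels) != n:
        raise ValueError("labels length must equal number of leaves")

    def height(node: int) -> float:
        return 0.0 if node < n else float(merges[node - n, 2])

    def render(node: int) -> str:
        if node < n:
            return labels[node]
        i, j = int(merges[node - n, 0]), int(merges[node - n, 1])
        h = height(node)
        return "({}:{:g},{}:{:g})".format(
            render(i), h - height(i), render(j), h - height(j)
        )

    return render(2 * n - 2) + ";"


def cluster_matrix(values: pd.DataFrame) -> dict:
    """Cluster rows and columns independently; return trees and reordered data.

    ``values`` is typically log2 zero-replaced spectral counts of the
    selected proteins.  Returns a dict with row/column merge lists, leaf
    orders and the matrix reordered by both.
    """
    row_merges, row_order = ward_cluster(values.to_numpy())
    col_merges, col_order = ward_cluster(values.to_numpy().T)
    ordered = values.iloc[row_order, col_order]
    return {
        "row_merges": row_merges,
        "row_order": row_order,
        "col_merges": col_merges,
        "col_order": col_order,
        "ordered": ordered,
    }
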