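"""Gene-set over-representation with a permutation-derived score threshold.

Each set is scored by the right-tail hypergeometric (one-sided Fisher
exact) probability of its overlap with the input protein list, reported as
``score = -log10(p)``.  Significance is not judged against a fixed alpha:
instead random input lists of the same size are drawn from the background,
each repeat's best set score is recorded, and the threshold is the upper
95% confidence limit of the mean of those per-repeat maxima (Student t
quantile with repeats − 1 degrees of freedom by default).  A set is called
only when its score strictly exceeds that threshold.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .model import EnrichmentScore, GeneSetCollection, PermutationNull


def fisher_enrichment(input_list: list[str],
                      gene_set: tuple[str, ...] | list[str],
                      background: list[str]) -> float:
    """Right-tail hypergeometric p-value P(X >= overlap).

    Population N = |background|, successes K = |gene_set ∩ background|,
    draws n = |input_list| (which must be a subset of the background).
    """
    if not background:
        raise ValueError("background is empty")
    bg = set(background)
    inp = set(input_list)
    outside = inp - bg
    if outside:
        raise ValueError(f"input list not contained in background: {sorted(outside)[:5]}")
    members = set(gene_set) & bg
    overlap = len(inp & members)
    N, K, n = len(bg), len(members), len(inp)
    return float(stats.hypergeom.sf(overlap - 1, N, K, n))


def score_networks(input_list: list[str],
                   collection: GeneSetCollection) -> list[EnrichmentScore]:
    """Score every set in the collection; sorted by descending score."""
    bg = set(collection.background)
    inp = set(input_list)
    out = []
    for set_id, gs in collection.sets.items():
        p = fisher_enrichment(input_list, gs.members, collection.background)
        out.append(
            EnrichmentScore(
                set_id=set_id,
                overlap=len(inp & set(gs.members) & bg),
                p_value=p,
                score=max(0.0, float(-np.log10(p))) if p > 0
                else float(-np.log10(np.finfo(float).tiny)),
            )
        )
    return sorted(out, key=lambda s: (-s.score, s.set_id))


def mean_confidence_halfwidth(scores: list[float],
                              ci_method: str = "t") -> tuple[float, float]:
    """Mean of the scores and the half-width of its 95% confidence interval."""
    n = len(scores)
    if n < 2:
        raise ValueError("need at least 2 scores")
    mean = float(np.mean(scores))
    sd = float(np.std(scores, ddof=1))
    if ci_method == "t":
        quant = float(stats.t.ppf(0.975, n - 1))
    elif ci_method == "normal":
        quant = float(stats.norm.ppf(0.975))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return mean, quant * sd / np.sqrt(n)


def permutation_threshold(collection: GeneSetCollection,
                          background: list[str],
                          list_size: int,
                          repeats: int = 10,
                          seed: int = 0,
                          ci_method: str = "t") -> PermutationNull:
    """Null threshold from random input lists of size ``list_size``.

    Per repeat, ``list_size`` genes are drawn uniformly without replacement
    from the background, all sets are scored, and the maximum score is
    recorded.  The threshold is the upper 95% confidence limit of the mean
    of the per-repeat maxima: mean + q · sd / sqrt(repeats) with q the
    Student t 0.975 quantile at repeats − 1 df (``ci_method="t"``) or the
    normal 0.975 quantile (``ci_method="normal"``).
    """
    if repeats < 2:
        raise ValueError("repeats must be >= 2 (confidence interval undefined)")
    if list_size > len(background):
        raise ValueError("list_size exceeds background size")
    rng = np.random.default_rng(seed)
    bg = np.asarray(background, dtype=object)
    max_scores = []
    for _ in range(repeats):
        draw = list(rng.choice(bg, size=list_size, replace=False))
        scores = score_networks(draw, collection)
        max_scores.append(scores[0].score if scores else 0.0)
    mean, half = mean_confidence_halfwidth(max_scores, ci_method)
    return PermutationNull(
        repeats=repeats,
        max_scores=[float(s) for s in max_scores],
        mean=mean,
        ci_lower=mean - half,
        ci_upper=mean + half,
        seed=seed,
    )


def significant_networks(scores: list[EnrichmentScore],
                         null: PermutationNull) -> list[dict]:
    """Judge every set against the permutation threshold (strict exceedance).

    Returns one record per set with its margin over the threshold, passing
    sets first.
    """
    out = []
    for s in scores:
        out.append(
            {
                "set_id": s.set_id,
                "overlap": s.overlap,
                "score": s.score,
                "threshold": null.threshold,
                "margin": float(s.score - null.threshold),
                "significant": bool(s.score > null.threshold),
            }
        )
    return sorted(out, key=lambda r: (not r["significant"], -r["score"], r["set_id"]))
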