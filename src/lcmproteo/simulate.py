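"""Synthetic studies with the statistical structure the pipeline assumes.

The generator emulates a four-group LCM spectral-counting study — early
cancer (n=11), late cancer (n=11), healthy epithelium (n=13) and stroma
(n=13) — over a few thousand proteins.  Baseline counts are negative
binomial (overdispersion is the norm in spectral counting) thinned by an
independent per-cell detection dropout, which reproduces the missingness
the all-or-nothing rule exploits.  Planted classes provide ground truth:

* ``fc_up`` / ``fc_down`` — counts in both cancer groups scaled by
  2**(±log2_effect);
* ``tumor_exclusive`` — zero in every healthy-epithelium and stroma
  sample, detected in a fixed number of early-cancer samples (late-cancer
  counts are left at baseline: presence there is permitted);
* ``healthy_exclusive`` — the mirror image, detected only in healthy
  epithelium.

All randomness flows from the single mandatory seed; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    GeneSet,
    GeneSetCollection,
    SampleAnnotation,
    SpectralCountMatrix,
    TruthTable,
)

EARLY_STAGES = ("Ib1", "Ib2", "IIb")
LATE_STAGES = ("IIIa", "IIIb", "IVa", "IVb")


@dataclass
class SimulationConfig:
    """Study-level parameters of the synthetic generator.

    Defaults mirror the emulated study design: group sizes 11/11/13/13 and
    per-sample protein detection in the 1,300–2,200 range (negative
    binomial mean 5, dispersion 1, 15% dropout over 2,000 proteins).
    """

    n_proteins: int = 2000
    n_early: int = 11
    n_late: int = 11
    n_healthy: int = 13
    n_stroma: int = 13
    nb_mean: float = 5.0          # baseline negative binomial mean µ
    nb_dispersion: float = 1.0    # NB size k; k -> inf recovers Poisson
    dropout: float = 0.15         # independent per-cell detection dropout
    prop_fc_up: float = 0.05
    prop_fc_down: float = 0.05
    prop_tumor_exclusive: float = 0.0155   # ~31 proteins of 2,000
    prop_healthy_exclusive: float = 0.005
    log2_effect: float = 2.0
    tumor_exclusive_presence: int = 8      # early-cancer samples detected
    healthy_exclusive_presence: int = 6    # healthy samples detected
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        props = (self.prop_fc_up + self.prop_fc_down
                 + self.prop_tumor_exclusive + self.prop_healthy_exclusive)
        if props > 1:
            raise ValueError("planted-class proportions sum above 1")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("nb_mean and nb_dispersion must be > 0")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if self.tumor_exclusive_presence > self.n_early:
            raise ValueError("tumor_exclusive_presence exceeds early group size")
        if self.healthy_exclusive_presence > self.n_healthy:
            raise ValueError("healthy_exclusive_presence exceeds healthy group size")


def _nb_draw(rng: np.random.Generator, mean: float, k: float, size) -> np.ndarray:
    return rng.negative_binomial(k, k / (k + mean), size=size)


def simulate_study(config: SimulationConfig
                   ) -> tuple[SpectralCountMatrix, list[SampleAnnotation], TruthTable]:
    """Generate a spectral-count study with planted ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    proteins = [f"G{i:05d}" for i in range(n)]

    groups = (
        [("EC%02d" % (i + 1), "early_cancer") for i in range(config.n_early)]
        + [("LC%02d" % (i + 1), "late_cancer") for i in range(config.n_late)]
        + [("HE%02d" % (i + 1), "healthy_epithelium") for i in range(config.n_healthy)]
        + [("ST%02d" % (i + 1), "stroma") for i in range(config.n_stroma)]
    )
    sample_ids = [s for s, _ in groups]
    group_of = dict(groups)
    cols = {g: [s for s, gg in groups if gg == g]
            for g in ("early_cancer", "late_cancer", "healthy_epithelium", "stroma")}

    # class assignment
    n_up = round(config.prop_fc_up * n)
    n_down = round(config.prop_fc_down * n)
    n_tex = round(config.prop_tumor_exclusive * n)
    n_hex = round(config.prop_healthy_exclusive * n)
    order = rng.permutation(n)
    classes = np.array(["null"] * n, dtype=object)
    pos = 0
    for cls, cnt in (("fc_up", n_up), ("fc_down", n_down),
                     ("tumor_exclusive", n_tex), ("healthy_exclusive", n_hex)):
        classes[order[pos:pos + cnt]] = cls
        pos += cnt

    mu, k = config.nb_mean, config.nb_dispersion
    counts = pd.DataFrame(
        _nb_draw(rng, mu, k, (n, len(sample_ids))),
        index=proteins, columns=sample_ids,
    )

    cancer_cols = cols["early_cancer"] + cols["late_cancer"]
    up_rows = classes == "fc_up"
    down_rows = classes == "fc_down"
    if up_rows.any():
        counts.loc[up_rows, cancer_cols] = _nb_draw(
            rng, mu * 2**config.log2_effect, k, (up_rows.sum(), len(cancer_cols)))
    if down_rows.any():
        counts.loc[down_rows, cancer_cols] = _nb_draw(
            rng, mu / 2**config.log2_effect, k, (down_rows.sum(), len(cancer_cols)))

    # detection dropout, independent per cell
    if config.dropout > 0:
        keep = rng.random(counts.shape) >= config.dropout
        counts = counts.where(keep, 0)

    # exclusivity patterns are imposed after dropout so they hold exactly
    def _plant_exclusive(rows: np.ndarray, present_cols: list[str],
                         zero_cols: list[str], n_present: int) -> None:
        for ridx in np.flatnonzero(rows):
            pid = proteins[ridx]
            counts.loc[pid, zero_cols] = 0
            chosen = rng.choice(len(present_cols), size=n_present, replace=False)
            present = [present_cols[c] for c in chosen]
            absent = [c for c in present_cols if c not in present]
            draw = np.maximum(1, _nb_draw(rng, mu, k, n_present))
            counts.loc[pid, present] = draw
            counts.loc[pid, absent] = 0

    _plant_exclusive(
        classes == "tumor_exclusive",
        cols["early_cancer"],
        cols["healthy_epithelium"] + cols["stroma"],
        config.tumor_exclusive_presence,
    )
    _plant_exclusive(
        classes == "healthy_exclusive",
        cols["healthy_epithelium"],
        cols["early_cancer"] + cols["late_cancer"] + cols["stroma"],
        config.healthy_exclusive_presence,
    )

    annotations = []
    for sid in sample_ids:
        g = group_of[sid]
        age = float(rng.integers(30, 81))
        figo = None
        if g == "early_cancer":
            figo = str(rng.choice(EARLY_STAGES))
        elif g == "late_cancer":
            figo = str(rng.choice(LATE_STAGES))
        annotations.append(SampleAnnotation(sample_id=sid, group=g, age=age,
                                            figo_stage=figo))

    truth = TruthTable(classes=dict(zip(proteins, classes)))
    return SpectralCountMatrix(counts), annotations, truth


def simulate_gene_sets(n_sets: int,
                       set_size: int,
                       background: list[str],
                       planted_members: list[str] | tuple[str, ...] = (),
                       seed: int = 0,
                       planted_set_id: str = "NET01") -> GeneSetCollection:
    """Gene-set collection with one designated set holding planted members.

    The designated set contains all ``planted_members`` topped up to
    ``set_size`` with random background genes; the remaining sets are
    uniform draws from the background.  ``set_size`` defaults in callers to
    35, the typical curated-network size.
    """
    rng = np.random.default_rng(seed)
    bg = list(background)
    planted = list(dict.fromkeys(planted_members))
    if len(planted) > set_size:
        raise ValueError("more planted members than set_size")
    outside = [g for g in planted if g not in set(bg)]
    if outside:
        raise ValueError(f"planted members not in background: {outside[:5]}")
    sets: dict[str, GeneSet] = {}
    fill_pool = [g for g in bg if g not in set(planted)]
    fill = list(rng.choice(np.asarray(fill_pool, dtype=object),
                           size=set_size - len(planted), replace=False))
    sets[planted_set_id] = GeneSet("planted enriched set",
                                   tuple(planted + fill))
    for i in range(1, n_sets):
        members = list(rng.choice(np.asarray(bg, dtype=object),
                                  size=set_size, replace=False))
        sets[f"NET{i + 1:02d}"] = GeneSet("random set", tuple(members))
    return GeneSetCollection(sets=sets, background=bg)


DEFAULT_PRM_LEVELS = (0.0, 0.625, 1.25, 2.5, 5.0, 10.0, 20.0)


def simulate_prm_series(slope: float,
                        intercept: float = 0.0,
                        cv: float = 0.05,
                        levels: tuple[float, ...] = DEFAULT_PRM_LEVELS,
                        replicates: int = 3,
                        seed: int = 0,
                        peptide_id: str = "PEP1") -> pd.DataFrame:
    """Triplicate dilution series: area = slope·level + intercept, times
    multiplicative lognormal noise of the given fractional CV (mean 1)."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    sigma = np.sqrt(np.log1p(cv**2))
    for level in levels:
        expected = slope * level + intercept
        for rep in range(1, replicates + 1):
            noise = np.exp(rng.normal(-sigma**2 / 2, sigma)) if cv > 0 else 1.0
            rows.append(
                {"peptide": peptide_id, "level": level, "replicate": rep,
                 "area": expected * noise}
            )
    return pd.DataFrame(rows)


def simulate_expression(genes: list[str],
                        n_samples: int = 50,
                        high_set: list[str] | tuple[str, ...] = (),
                        low_set: list[str] | tuple[str, ...] = (),
                        seed: int = 0,
                        high_mean: float = 5.0,
                        mid_mean: float = 2.0,
                        low_mean: float = -5.0,
                        sd: float = 1.5):
    """log2 FPKM table over tumor samples with planted expression strata.

    Genes in ``high_set`` center around log2 FPKM ≈ 5 (strongly expressed),
    ``low_set`` around −5 (undetectable), all others intermediate.
    """
    from .model import ExpressionTable

    rng = np.random.default_rng(seed)
    high, low = set(high_set), set(low_set)
    centers = np.array([
        high_mean if g in high else low_mean if g in low else mid_mean
        for g in genes
    ])
    values = rng.normal(centers[:, None], sd, size=(len(genes), n_samples))
    df = pd.DataFrame(values, index=genes,
                      columns=[f"T{i + 1:03d}" for i in range(n_samples)])
    return ExpressionTable(df)


def write_study(outdir, config: SimulationConfig,
                n_sets: int = 10, set_size: int = 35,
                prm_slope: float = 1000.0, prm_cv: float = 0.05) -> dict:
    """Emit a full synthetic study (matrix, annotations, truth, gene sets,
    PRM series, expression) as TSV/GMT files into ``outdir``."""
    from pathlib import Path

    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, annotations, truth = simulate_study(config)
    rng = np.random.default_rng(config.seed)
    planted = truth.proteins_of_class("fc_up")[:14]
    collection = simulate_gene_sets(
        n_sets, set_size, matrix.protein_ids, planted_members=planted,
        seed=int(rng.integers(2**31)),
    )
    truth.planted_set_id = "NET01"
    prm = simulate_prm_series(prm_slope, cv=prm_cv,
                              seed=int(rng.integers(2**31)))
    expr = simulate_expression(
        matrix.protein_ids,
        high_set=truth.proteins_of_class("fc_up"),
        low_set=truth.proteins_of_class("fc_down"),
        seed=int(rng.integers(2**31)),
    )
    io.write_count_matrix(matrix, outdir / "matrix.tsv")
    io.write_annotations(annotations, outdir / "annotations.tsv")
    pd.DataFrame(
        {"protein_id": list(truth.classes), "class": list(truth.classes.values())}
    ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    io.write_gmt(collection, outdir / "sets.gmt")
    io.write_table(prm, outdir / "prm.tsv")
    io.write_expression(expr, outdir / "expression.tsv")
    return {
        "matrix": outdir / "matrix.tsv",
        "annotations": outdir / "annotations.tsv",
        "truth": outdir / "truth.tsv",
        "sets": outdir / "sets.gmt",
        "prm": outdir / "prm.tsv",
        "expression": outdir / "expression.tsv",
    }
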