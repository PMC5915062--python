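"""Core domain types for the spectral-count proteomics pipeline.

The central object is a :class:`SpectralCountMatrix` — a proteins × samples
grid of nonnegative integer spectral counts — together with per-sample
annotations (group label, age, FIGO stage).  Downstream stages add gene-set
collections, expression tables and per-protein differential records.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Closed vocabulary of tissue groups.  Cell lines use ``cell_line:<name>``.
CANCER_GROUPS = ("early_cancer", "late_cancer")
TISSUE_GROUPS = ("early_cancer", "late_cancer", "healthy_epithelium", "stroma")
CELL_LINE_PREFIX = "cell_line:"


def is_valid_group(group: str) -> bool:
    return group in TISSUE_GROUPS or (
        group.startswith(CELL_LINE_PREFIX) and len(group) > len(CELL_LINE_PREFIX)
    )


@dataclass
class SpectralCountMatrix:
    """Proteins × samples grid of spectral counts.

    Parameters
    ----------
    counts
        DataFrame with protein identifiers (gene symbols) as the index and
        sample identifiers as columns; every cell a nonnegative integer.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate protein id: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        values = self.counts.to_numpy()
        if values.size == 0:
            raise ValueError("empty count matrix")
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("count matrix contains non-numeric cells")
        if np.isnan(values.astype(float)).any():
            raise ValueError("count matrix contains missing cells")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at protein {idx[r]!r}, sample {cols[c]!r}"
            )
        if np.any(values.astype(float) % 1 != 0):
            r, c = np.argwhere(values.astype(float) % 1 != 0)[0]
            raise ValueError(
                f"non-integer count at protein {idx[r]!r}, sample {cols[c]!r}"
            )
        self.counts = self.counts.astype(np.int64)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    def subset_samples(self, sample_ids: list[str]) -> "SpectralCountMatrix":
        return SpectralCountMatrix(self.counts[sample_ids])

    def presence(self) -> pd.DataFrame:
        """Boolean grid: protein detected (count >= 1) in sample."""
        return self.counts >= 1


@dataclass
class SampleAnnotation:
    """Group label plus optional clinical covariates for one sample."""

    sample_id: str
    group: str
    age: float | None = None
    figo_stage: str | None = None

    def __post_init__(self) -> None:
        if not is_valid_group(self.group):
            raise ValueError(f"unknown group {self.group!r} for sample {self.sample_id!r}")
        if self.figo_stage is not None and self.group not in CANCER_GROUPS:
            raise ValueError(
                f"figo_stage given for non-cancer sample {self.sample_id!r} ({self.group})"
            )


def annotation_frame(annotations: list[SampleAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(a) for a in annotations]
    ).set_index("sample_id")


def samples_in_group(annotations: list[SampleAnnotation], group: str) -> list[str]:
    return [a.sample_id for a in annotations if a.group == group]


def check_annotations(matrix: SpectralCountMatrix,
                      annotations: list[SampleAnnotation]) -> None:
    """Every matrix sample must carry exactly one annotation (hard error)."""
    seen: dict[str, int] = {}
    for a in annotations:
        seen[a.sample_id] = seen.get(a.sample_id, 0) + 1
    multi = [s for s, n in seen.items() if n > 1]
    if multi:
        raise ValueError(f"multiple annotations for sample(s): {multi}")
    missing = [s for s in matrix.sample_ids if s not in seen]
    if missing:
        raise ValueError(f"missing annotation for sample(s): {missing}")


@dataclass
class GeneSet:
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError("gene set members must be unique")


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background gene universe they are scored against."""

    sets: dict[str, GeneSet]
    background: list[str]

    def __post_init__(self) -> None:
        if len(set(self.background)) != len(self.background):
            raise ValueError("background contains duplicate gene symbols")


@dataclass
class ExpressionTable:
    """Genes × samples table of log2-scale expression (log2 FPKM)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene id in expression table")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample id in expression table")
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValueError("expression table contains infinite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DifferentialRecord:
    """One volcano-table row: fold-change, p-value, presence, selection flags."""

    protein_id: str
    log2_fc: float
    p_value: float
    presence_a: int = 0
    presence_b: int = 0
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p_value must lie in (0, 1], got {self.p_value}")


@dataclass
class EnrichmentScore:
    """Right-tail over-representation of an input list in one gene set."""

    set_id: str
    overlap: int
    p_value: float
    score: float  # -log10(p_value)

    def __post_init__(self) -> None:
        if self.overlap < 0:
            raise ValueError("overlap must be >= 0")
        if self.score < 0:
            raise ValueError("score must be >= 0")


@dataclass
class PermutationNull:
    """Null distribution of the best per-repeat set score for random input lists.

    ``threshold`` is the upper 95% confidence limit of the mean of the
    per-repeat maximum scores; sets must exceed it strictly to be called.
    """

    repeats: int
    max_scores: list[float]
    mean: float
    ci_lower: float
    ci_upper: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.max_scores) != self.repeats:
            raise ValueError("max_scores length must equal repeats")
        if not (self.ci_lower <= self.mean <= self.ci_upper):
            raise ValueError("confidence limits must bracket the mean")

    @property
    def threshold(self) -> float:
        return self.ci_upper


#: Planted ground-truth classes for simulated proteins.
TRUTH_CLASSES = ("null", "fc_up", "fc_down", "tumor_exclusive", "healthy_exclusive")


@dataclass
class TruthTable:
    """Ground truth of a simulated study: per-protein class and the planted set."""

    classes: dict[str, str]
    planted_set_id: str | None = None

    def __post_init__(self) -> None:
        bad = {c for c in self.classes.values() if c not in TRUTH_CLASSES}
        if bad:
            raise ValueError(f"unknown truth class(es): {sorted(bad)}")

    def proteins_of_class(self, cls: str) -> list[str]:
        return [p for p, c in self.classes.items() if c == cls]


@dataclass
class ContrastSpec:
    """Two-group contrast: test group vs reference group."""

    group_a: str
    group_b: str
    pseudocount: float = 0.125
    test_method: str = "welch_log"

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("contrast groups must be disjoint")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.test_method not in ("welch_log", "fisher_presence"):
            raise ValueError(f"unknown test_method {self.test_method!r}")


@dataclass
class SelectionParams:
    """Parameters of the three selection regimes."""

    target_group: str = "early_cancer"
    min_present_target: int = 7
    exclude_groups: tuple[str, ...] = ("healthy_epithelium", "stroma")
    allow_groups: tuple[str, ...] = ("late_cancer",)
    p_max: float = 0.05
    alpha: float = 0.05
    q: float = 0.05
    family_size_policy: str = "tested_proteins"
    explicit_m: int | None = None

    def __post_init__(self) -> None:
        for name in ("p_max", "alpha", "q"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.target_group in self.exclude_groups:
            raise ValueError("target group overlaps exclude groups")
        if self.family_size_policy not in ("tested_proteins", "explicit_m"):
            raise ValueError(f"unknown family_size_policy {self.family_size_policy!r}")
        if self.family_size_policy == "explicit_m" and not self.explicit_m:
            raise ValueError("explicit_m policy requires explicit_m")


_STAGE_RE = re.compile(r"^(IV|III|II|I)([A-D]?\d*)$", re.IGNORECASE)


def stage_class(figo_stage: str) -> str:
    """Map a FIGO stage string to ``early`` (I/II) or ``late`` (III/IV).

    The Roman numeral is matched longest-first so that e.g. ``IIb`` parses as
    stage II (early), not as a prefix of III.
    """
    m = _STAGE_RE.match(figo_stage.strip())
    if not m:
        raise ValueError(f"unparseable FIGO stage {figo_stage!r}")
    numeral = m.group(1).upper()
    return "late" if numeral in ("III", "IV") else "early"


def estimate_cell_count(area_mm2: float, section_thickness_um: float,
                        cell_edge_um: float) -> int:
    """Number of cells in a microdissected area, assuming cubic cells.

    ``area_mm2`` is converted to µm² (× 10⁶), multiplied by the section
    thickness and divided by the cell volume ``cell_edge_um ** 3``.
    """
    if area_mm2 <= 0 or section_thickness_um <= 0 or cell_edge_um <= 0:
        raise ValueError("all arguments must be > 0")
    return round(area_mm2 * 1e6 * section_thickness_um / cell_edge_um**3)
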