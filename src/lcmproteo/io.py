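"""Readers and writers for the pipeline's tabular formats.

Everything tabular is TSV (UTF-8, tab-separated, ``.`` decimal); gene sets
use the standard GMT dialect.  Writers emit a header line and format floats
with 6 significant digits.  Readers validate hard: duplicate identifiers,
non-integer counts and malformed lines are errors, not warnings.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    ExpressionTable,
    GeneSet,
    GeneSetCollection,
    SampleAnnotation,
    SpectralCountMatrix,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


def read_count_matrix(path: str | Path) -> SpectralCountMatrix:
    """Read a proteins × samples spectral-count TSV.

    First column holds protein identifiers, the header row sample
    identifiers.  Cells must be nonnegative integers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty count matrix file: {path}") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty count matrix file: {path}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate protein id {dup!r} in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric count {df.iat[r, c]!r} at protein "
            f"{df.index[r]!r}, sample {df.columns[c]!r} in {path}"
        )
    frac = numeric.to_numpy(dtype=float) % 1 != 0
    if frac.any():
        r, c = np.argwhere(frac)[0]
        raise ValueError(
            f"non-integer count {df.iat[r, c]!r} at protein "
            f"{df.index[r]!r}, sample {df.columns[c]!r} in {path}"
        )
    numeric.index.name = None
    return SpectralCountMatrix(numeric.astype(np.int64))


def write_count_matrix(matrix: SpectralCountMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="protein_id")


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read per-sample annotations: sample_id, group, age, figo_stage."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation file {path} lacks columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        age = row.get("age")
        figo = row.get("figo_stage")
        out.append(
            SampleAnnotation(
                sample_id=row["sample_id"],
                group=row["group"],
                age=float(age) if isinstance(age, str) and age != "" else None,
                figo_stage=figo if isinstance(figo, str) and figo != "" else None,
            )
        )
    ids = [a.sample_id for a in out]
    if len(set(ids)) != len(ids):
        dup = next(s for s in ids if ids.count(s) > 1)
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    return out


def write_annotations(annotations: list[SampleAnnotation], path: str | Path) -> None:
    rows = []
    for a in annotations:
        rows.append(
            {
                "sample_id": a.sample_id,
                "group": a.group,
                "age": "" if a.age is None else (
                    "%d" % a.age if float(a.age).is_integer() else FLOAT_FORMAT % a.age
                ),
                "figo_stage": a.figo_stage or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: ``set_id TAB description TAB member ...``.

    Members duplicated within one set are dropped with a logged warning; the
    background is the union of all members (replace via
    :func:`read_gene_list` for an explicit universe).
    """
    sets: dict[str, GeneSet] = {}
    background: list[str] = []
    seen_bg: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue  # tolerate blank lines (common at EOF)
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            set_id, description = fields[0], fields[1]
            if set_id in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            members: list[str] = []
            for g in fields[2:]:
                if not g:
                    continue
                if g in members:
                    logger.warning(
                        "%s:%d: duplicated member %r in set %r dropped",
                        path, lineno, g, set_id,
                    )
                    continue
                members.append(g)
            sets[set_id] = GeneSet(description, tuple(members))
            for g in members:
                if g not in seen_bg:
                    seen_bg.add(g)
                    background.append(g)
    return GeneSetCollection(sets=sets, background=background)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id, gs in collection.sets.items():
            fh.write("\t".join([set_id, gs.description, *gs.members]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list (duplicates are an error)."""
    with open(path, encoding="utf-8") as fh:
        genes = [line.strip() for line in fh if line.strip()]
    if len(set(genes)) != len(genes):
        dup = next(g for g in genes if genes.count(g) > 1)
        raise ValueError(f"duplicate gene {dup!r} in {path}")
    return genes


def write_gene_list(genes: list[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(g + "\n")


def read_expression(path: str | Path) -> ExpressionTable:
    """Read a genes × samples table of log2 expression values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return ExpressionTable(df.astype(float))


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="gene_id",
                        float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    """Generic TSV reader for result/PRM tables."""
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
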