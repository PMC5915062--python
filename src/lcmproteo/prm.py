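"""Targeted (PRM) absolute quantification with stable-isotope-labeled spikes.

A known amount of SIL peptide (10 fmol by default) is spiked into a
digested aliquot; the endogenous amount follows from the endogenous/SIL
peak-area ratio scaled back to the whole lysate.  Calibration quality of
the dilution series (levels in fmol/µL, triplicate areas) is summarised by
an ordinary least-squares fit on replicate means, with

* LOD = 3.3 · σ_blank / slope and LOQ = 10 · σ_blank / slope, where
  σ_blank is the standard deviation of the level-0 replicate areas
  (falling back to the residual standard deviation of the fit when no
  blank replicates exist), and
* per-level CV% = 100 · sd / mean of the replicate areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PRMMeasurement:
    """One peptide's peak areas in one sample."""

    peptide_id: str
    protein_id: str
    endogenous_area: float
    sil_area: float
    spike_fmol: float = 10.0
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.endogenous_area < 0 or self.sil_area < 0:
            raise ValueError("peak areas must be >= 0")
        if self.spike_fmol <= 0:
            raise ValueError("spike_fmol must be > 0")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be > 0")


def peptide_amount_fmol(m: PRMMeasurement) -> float | None:
    """Whole-lysate endogenous amount: (endo/SIL) · spike · scale.

    Returns ``None`` (not quantifiable) when the SIL area is zero — a
    missing internal standard gives no ratio, not an infinite amount.
    """
    if m.sil_area == 0:
        return None
    return (m.endogenous_area / m.sil_area) * m.spike_fmol * m.scale_factor


def protein_amount_ng(peptide_amounts_fmol: list[float],
                      molecular_weight_da: float,
                      aggregate: str = "median") -> float:
    """Protein amount in ng from its peptides' fmol estimates.

    Peptide amounts are aggregated (median by default, robust to a single
    interfered transition; ``mean`` optional) and converted by
    ng = fmol · MW(Da) · 10⁻⁶.
    """
    if molecular_weight_da <= 0:
        raise ValueError("molecular weight must be > 0")
    amounts = [a for a in peptide_amounts_fmol if a is not None]
    if not amounts:
        raise ValueError("no quantifiable peptide amounts")
    if aggregate == "median":
        fmol = float(np.median(amounts))
    elif aggregate == "mean":
        fmol = float(np.mean(amounts))
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return fmol * molecular_weight_da * 1e-6


@dataclass
class CalibrationCurve:
    """Dilution-series fit summary for one peptide."""

    peptide_id: str
    levels: list[float]
    slope: float
    intercept: float
    r_squared: float
    lod_fmol_per_ul: float
    loq_fmol_per_ul: float
    cv_percent: dict[float, float] = field(default_factory=dict)
    sigma_blank: float = float("nan")
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and not (self.lod_fmol_per_ul <= self.loq_fmol_per_ul + 1e-12):
            raise ValueError("LOD must not exceed LOQ")


def fit_calibration(series: pd.DataFrame,
                    peptide_id: str = "") -> CalibrationCurve:
    """Fit one peptide's dilution series.

    ``series`` needs columns ``level`` (fmol/µL) and ``area``; a
    ``replicate`` column is optional.  Requires >= 3 distinct levels.
    """
    if not {"level", "area"}.issubset(series.columns):
        raise ValueError("series needs 'level' and 'area' columns")
    levels = np.sort(series["level"].unique())
    if len(levels) < 3:
        raise ValueError("need at least 3 distinct levels")
    means = series.groupby("level")["area"].mean()
    fit = stats.linregress(means.index.to_numpy(dtype=float), means.to_numpy())
    slope, intercept = float(fit.slope), float(fit.intercept)
    r_squared = float(fit.rvalue**2)

    blank = series.loc[series["level"] == 0, "area"]
    if len(blank) >= 2:
        sigma_blank = float(blank.std(ddof=1))
    else:
        resid = means.to_numpy() - (slope * means.index.to_numpy() + intercept)
        sigma_blank = float(np.sqrt((resid**2).sum() / max(len(resid) - 2, 1)))

    cv = {}
    for lv, grp in series.groupby("level"):
        mean = grp["area"].mean()
        cv[float(lv)] = float(100.0 * grp["area"].std(ddof=1) / mean) if (
            len(grp) >= 2 and mean != 0
        ) else float("nan")

    valid = slope > 0
    lod = 3.3 * sigma_blank / slope if valid else float("nan")
    loq = 10.0 * sigma_blank / slope if valid else float("nan")
    return CalibrationCurve(
        peptide_id=peptide_id,
        levels=[float(v) for v in levels],
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        lod_fmol_per_ul=lod,
        loq_fmol_per_ul=loq,
        cv_percent=cv,
        sigma_blank=sigma_blank,
        valid=valid,
    )


def fit_calibration_table(table: pd.DataFrame) -> dict[str, CalibrationCurve]:
    """Fit every peptide in a dilution table with a ``peptide`` column."""
    if "peptide" not in table.columns:
        raise ValueError("table needs a 'peptide' column")
    return {
        pep: fit_calibration(grp, peptide_id=pep)
        for pep, grp in table.groupby("peptide")
    }


def quantify_samples(measurements: pd.DataFrame,
                     molecular_weights: dict[str, float],
                     aggregate: str = "median") -> pd.DataFrame:
    """Per-sample, per-protein amounts from a PRM measurement table.

    ``measurements`` columns: sample, peptide, protein, endo_area,
    sil_area, spike_fmol, scale.  Returns rows (sample, protein,
    amount_fmol, amount_ng, n_peptides); proteins with no quantifiable
    peptide in a sample are reported with NaN amounts.
    """
    needed = {"sample", "peptide", "protein", "endo_area", "sil_area"}
    missing = needed - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns: {sorted(missing)}")
    rows = []
    for (sample, protein), grp in measurements.groupby(["sample", "protein"]):
        amounts = []
        for _, r in grp.iterrows():
            m = PRMMeasurement(
                peptide_id=r["peptide"],
                protein_id=protein,
                endogenous_area=float(r["endo_area"]),
                sil_area=float(r["sil_area"]),
                spike_fmol=float(r.get("spike_fmol", 10.0)),
                scale_factor=float(r.get("scale", 1.0)),
            )
            a = peptide_amount_fmol(m)
            if a is not None:
                amounts.append(a)
        if amounts:
            if aggregate == "median":
                fmol = float(np.median(amounts))
            else:
                fmol = float(np.mean(amounts))
            mw = molecular_weights.get(protein)
            ng = fmol * mw * 1e-6 if mw else float("nan")
        else:
            fmol, ng = float("nan"), float("nan")
        rows.append(
            {
                "sample": sample,
                "protein": protein,
                "amount_fmol": fmol,
                "amount_ng": ng,
                "n_peptides": len(amounts),
            }
        )
    return pd.DataFrame(rows)
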