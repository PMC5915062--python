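"""Bundled reference tables from the cervical-cancer LCM study.

Two small published tables ship with the package so that the cohort
summaries and the cell-line contrast filter can be exercised on real
numbers without any download:

* the clinical cohort — 22 squamous cervical cancer patients (11 early
  stage FIGO I/II, 11 late stage FIGO III/IV) and 13 healthy controls,
  with age and FIGO stage;
* the cell-line fold-change table — per-protein log2 fold-changes versus
  healthy epithelium for early-stage cancer (EC), late-stage cancer (LC)
  and the HeLa, U87 and HEK293 cell lines.
"""

from __future__ import annotations

import pandas as pd

from .model import SampleAnnotation

# (sample_id, age, figo_stage or None, group)
_COHORT = [
    ("1218", 50, "Ib2", "early_cancer"),
    ("1230", 44, "IIb", "early_cancer"),
    ("1239", 43, "Ib1", "early_cancer"),
    ("1291", 34, "Ib2", "early_cancer"),
    ("1298", 80, "Ib2", "early_cancer"),
    ("2110", 77, "IIb", "early_cancer"),
    ("2146", 46, "Ib2", "early_cancer"),
    ("2163", 39, "Ib1", "early_cancer"),
    ("2180", 74, "IIb", "early_cancer"),
    ("2246", 73, "Ib1", "early_cancer"),
    ("2252", 44, "Ib2", "early_cancer"),
    ("1225", 58, "IIIb", "late_cancer"),
    ("1348", 71, "IIIa", "late_cancer"),
    ("1685", 26, "IIIb", "late_cancer"),
    ("1966", 75, "IVb", "late_cancer"),
    ("1981", 68, "IIIb", "late_cancer"),
    ("1998", 72, "IIIb", "late_cancer"),
    ("2008", 84, "IIIa", "late_cancer"),
    ("2087", 49, "IIIb", "late_cancer"),
    ("2247", 76, "IIIb", "late_cancer"),
    ("2265", 83, "IVb", "late_cancer"),
    ("2297", 52, "IVa", "late_cancer"),
    ("1247", 43, None, "healthy_epithelium"),
    ("1262", 51, None, "healthy_epithelium"),
    ("1315", 36, None, "healthy_epithelium"),
    ("1477", 41, None, "healthy_epithelium"),
    ("1516", 39, None, "healthy_epithelium"),
    ("1525", 41, None, "healthy_epithelium"),
    ("1542", 46, None, "healthy_epithelium"),
    ("1826", 45, None, "healthy_epithelium"),
    ("1849", 51, None, "healthy_epithelium"),
    ("1936", 41, None, "healthy_epithelium"),
    ("1948", 60, None, "healthy_epithelium"),
    ("2000", 41, None, "healthy_epithelium"),
    ("2001", 49, None, "healthy_epithelium"),
]


def cohort_annotations() -> list[SampleAnnotation]:
    """The study cohort as a list of :class:`SampleAnnotation`."""
    return [
        SampleAnnotation(sample_id=s, group=g, age=float(a), figo_stage=f)
        for s, a, f, g in _COHORT
    ]


# Published log2 fold-changes versus healthy epithelium.  Part A lists the
# proteins up-regulated (>= 2.5) in both cancer stages and HeLa but not in
# the non-cervical U87/HEK293 lines; part B those up-regulated in the
# microdissected tumor cells only.  protein: full protein name, gene: symbol.
_CELL_LINE_FC = [
    # part A
    ("A-kinase anchor protein 13", "AKAP13", 3.1, 3.2, 4.3, 0.0, 0.0),
    ("Antigen peptide transporter 2", "TAP2", 2.8, 2.8, 3.0, -0.6, -0.6),
    ("DBIRD complex subunit ZNF326", "ZNF326", 2.9, 3.2, 5.0, 0.0, 0.0),
    ("E3 ubiquitin-protein ligase UBR4", "UBR4", 2.8, 3.0, 6.5, 0.0, 0.0),
    ("G patch domain and KOW motifs-containing protein", "GPKOW", 2.7, 2.7, 5.2, 0.0, 0.0),
    ("Intercellular adhesion molecule 1", "ICAM1", 3.6, 3.6, 4.4, 0.0, 0.0),
    ("Leucine-rich repeat-containing protein 16A", "LRRC16A", 2.7, 2.6, 4.0, 0.0, 0.0),
    ("Melanoma-associated antigen D2", "MAGED2", 2.8, 2.5, 4.4, 0.0, 0.0),
    ("Periostin", "POSTN", 3.2, 2.6, 2.6, -1.4, -1.4),
    ("Phospholipase A-2-activating protein", "PLAA", 3.2, 2.8, 5.1, -1.1, -1.1),
    ("Protein RCC2", "RCC2", 2.8, 2.7, 3.8, -2.1, -2.1),
    ("Protein S100-P", "S100P", 2.9, 2.6, 3.9, 0.0, 0.0),
    ("Receptor-type tyrosine-protein phosphatase F", "PTPRF", 3.3, 3.0, 2.7, -2.3, -2.3),
    ("RNA-binding protein 10", "RBM10", 3.0, 2.5, 4.2, -0.6, -0.6),
    ("Shootin-1", "KIAA1598", 2.6, 2.6, 4.5, -0.6, -0.6),
    ("Sterile alpha motif domain-containing protein 9", "SAMD9", 3.8, 3.9, 2.8, 0.0, 0.0),
    ("Thrombospondin-1", "THBS1", 3.5, 3.1, 6.1, 0.0, 0.0),
    ("Ubiquitin-like protein ISG15", "ISG15", 2.5, 3.4, 3.4, 0.0, 0.0),
    ("Zinc finger RNA-binding protein", "ZFR", 2.7, 3.7, 5.8, 0.0, 0.0),
    # part B
    ("Calcium-activated chloride channel regulator 4", "CLCA4", 2.8, 3.3, 0.0, 0.0, 0.0),
    ("Carcinoembryonic antigen-related cell adhesion molecule 5", "CEACAM5", 3.8, 2.8, 0.0, 0.0, 0.0),
    ("Cathelicidin antimicrobial peptide", "CAMP", 3.8, 2.7, 0.0, 0.0, 0.0),
    ("Collagen alpha-1(XII) chain", "COL12A1", 4.0, 3.5, -2.1, -2.1, -2.1),
    ("Dimethylaniline monooxygenase [N-oxide-forming] 3", "FMO3", 3.5, 2.6, 0.0, 0.0, 0.0),
    ("E3 ubiquitin-protein ligase DTX3L", "DTX3L", 3.7, 3.2, 0.0, 0.0, 0.0),
    ("Epithelial cell adhesion molecule", "EPCAM", 3.2, 3.2, 0.0, 0.0, 0.0),
    ("Fibulin-2", "FBLN2", 3.1, 3.0, 0.0, 0.0, 0.0),
    ("HLA class II histocompatibility antigen, DRB1-16 beta chain", "HLA-DRB1", 3.7, 3.3, -0.6, -0.6, -0.6),
    ("HLA class II histocompatibility antigen, DRB1-7 beta chain", "HLA-DRB1", 3.8, 3.0, 0.0, 0.0, 0.0),
    ("Myeloperoxidase", "MPO", 5.0, 3.6, 0.0, 0.0, 0.0),
    ("Poly [ADP-ribose] polymerase 9", "PARP9", 3.7, 2.6, 0.0, 0.0, 0.0),
    ("Stimulator of interferon genes protein", "TMEM173", 3.0, 2.8, 0.0, 0.0, 0.0),
    ("Transgelin", "TAGLN", 3.5, 2.9, -1.7, -1.7, -1.7),
]


def cell_line_fold_changes() -> pd.DataFrame:
    """Published log2 fold-changes vs healthy epithelium, one row per protein.

    Columns: ``protein``, ``gene``, ``early_cancer``, ``late_cancer``,
    ``HeLa``, ``U87``, ``HEK293``.
    """
    return pd.DataFrame(
        _CELL_LINE_FC,
        columns=["protein", "gene", "early_cancer", "late_cancer",
                 "HeLa", "U87", "HEK293"],
    )
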