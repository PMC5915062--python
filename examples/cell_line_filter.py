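"""Cell-line contrast filter on the bundled published fold-change table.

Each row holds log2 fold-changes versus healthy epithelium for early
(EC) and late (LC) stage cancer and three cell lines.  At a cutoff of
2.5 log2 units the filter separates proteins shared with the cervical
HeLa line from those seen in microdissected tumor cells only.
"""

from lcmproteo.datasets import cell_line_fold_changes
from lcmproteo.differential import classify_fold_changes

fc = cell_line_fold_changes()
labels = classify_fold_changes(fc, fc_min=2.5)
fc = fc.assign(classification=labels)

for label in ("tumor_and_HeLa", "tumor_only"):
    genes = fc.loc[fc.classification == label, "gene"]
    print(f"{label} ({len(genes)} proteins): {', '.join(genes)}")
print("\nProteins up-regulated in tumor and HeLa but not in the "
      "non-cervical U87/HEK293 lines are candidate cervical-cancer markers.")
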