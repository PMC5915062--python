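"""Are differential-protein genes higher expressed at the RNA level?

Simulates a log2 FPKM table over tumor samples with a planted
highly-expressed stratum, then compares the mean expression of a
differential gene list against the proteome-identified background with a
two-sided Wilcoxon rank-sum test (called at p < 0.01).
"""

from lcmproteo.simulate import simulate_expression
from lcmproteo.transcriptome import compare_to_background

genes = [f"G{i:04d}" for i in range(3000)]
diff_genes = genes[:30]          # planted around log2 FPKM 5
silent = genes[2700:]            # planted around log2 FPKM -5
expr = simulate_expression(genes, n_samples=50, high_set=diff_genes,
                           low_set=silent, seed=5)

result = compare_to_background(diff_genes, genes, expr)
print(f"differential genes: {result['n_diff']}, "
      f"background genes: {result['n_background']}")
print(f"median log2 FPKM: {result['median_diff_genes']:.2f} (differential) "
      f"vs {result['median_background']:.2f} (background)")
print(f"Wilcoxon rank-sum p = {result['p_value']:.2e} -> "
      f"{'significantly higher expressed' if result['significant'] else 'no call'}")
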