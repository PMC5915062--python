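"""Ward clustering of selected proteins for a heat-map ordering.

Clusters the planted up-regulated proteins (rows) and the cancer/healthy
samples (columns) of a simulated study on log2 zero-replaced counts and
prints the merge heights and leaf orders a heat map would use.
"""

import numpy as np

from lcmproteo.clustering import cut_clusters, ward_cluster
from lcmproteo.differential import replace_zeros
from lcmproteo.model import samples_in_group
from lcmproteo.simulate import SimulationConfig, simulate_study

matrix, annotations, truth = simulate_study(SimulationConfig(seed=6))
up = truth.proteins_of_class("fc_up")[:20]
ec = samples_in_group(annotations, "early_cancer")
he = samples_in_group(annotations, "healthy_epithelium")
values = np.log2(replace_zeros(matrix.counts.loc[up, ec + he]))

merges, order = ward_cluster(values.to_numpy().T)  # cluster samples
samples = ec + he
print("sample leaf order:", " ".join(samples[i] for i in order))
clusters = cut_clusters(merges, 2)
for k, members in enumerate(clusters, 1):
    print(f"cluster {k}: {sorted(samples[i] for i in members)}")
print("\nWith a planted 2-log2-unit effect the two flat clusters are the "
      "cancer and healthy sample groups; merge heights are Ward distances.")
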