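"""Hierarchical clustering for heat-map ordering.

Distance 1 - Pearson correlation, average linkage — the parameters of the
published gene trees.  Sample-axis clustering should group the three
replicates of each condition, with the two 9-dpp populations (which share
the mitotic program block) closer to each other than to 22 dpp.
"""

import stageset as ss
from stageset.cluster import cluster, heatmap_order, to_newick

matrix, _, _ = ss.generate(ss.default_spec(seed=1))
signals = ss.summarize_signal(matrix)

sample_tree = cluster(signals, axis="samples")
print("sample order:", heatmap_order(sample_tree))
print(to_newick(sample_tree))

# leaf order is the left-to-right dendrogram order used to arrange the
# heat-map columns; replicates of one condition form contiguous runs, and
# the first split separates {G9, S9} from {G22, S22}.
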