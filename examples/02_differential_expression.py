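"""Concordance differential expression for one ordered comparison.

Each of the 3 experimental replicates is compared with each of the 3
reference replicates (9 pairwise signed-rank tests on matched probes);
a gene is selected when >= 7 of 9 calls agree in direction and the
condition-mean fold change is >= 2.
"""

import stageset as ss

matrix, truth, _ = ss.generate(ss.default_spec(seed=1))
records = ss.differential_expression(matrix, "G9", "G22")

sel = records[records["selected"]]
print(f"{len(sel)} of {len(records)} genes selected (G9 vs G22)")
print(sel.sort_values("combined_p").head(5)[
    ["feature_id", "concordance", "fold_change", "direction", "combined_p"]
].to_string(index=False))

up = ss.pairwise_up_list(records)
planted = truth.selective_genes("G9") | truth.block_genes("mitotic_shared")
print(f"up-regulated: {len(up)}, of which planted (G9-selective or shared "
      f"9-dpp program): {len(up & planted)}")

# concordance is the fraction of the 9 comparisons agreeing in direction;
# combined_p (Fisher's method over the 9 p-values) is a ranking aid only.
# G9 vs G22 recovers both the G9-selective block and the shared mitotic
# block, since the latter is elevated at 9 dpp in both cell types.
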