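"""Ligand-receptor complementarity between stem-cell and niche sets.

Ligands up-regulated in the 9-dpp germ cells (G9, the stem cell side)
whose cognate receptors are up-regulated in the 9-dpp Sertoli cells (S9,
the niche) indicate directed stem-cell-to-niche signalling.
"""

import stageset as ss
from stageset.crosstalk import demo_pair_table, find_crosstalk

matrix, truth, _ = ss.generate(ss.default_spec(seed=1))
g9 = truth.selective_genes("G9")
s9 = truth.selective_genes("S9")

res = find_crosstalk(g9, "G9", s9, "S9", demo_pair_table(),
                     universe=frozenset(matrix.gene_ids))
print(res.hits.to_string(index=False))
print(res.stats.to_string(index=False))

# the generator plants the ligands vegfc, edn1, bdnf in the G9 block and
# their receptors kdr, ednrb, ntrk1 in the S9 block, so exactly those
# three axes appear, all in the G9->S9 orientation; p_complete is the
# upper hypergeometric tail of that many complete pairs landing in the
# receiving set by chance.
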