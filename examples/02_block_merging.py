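"""Two-stage adaptive block merging on data with known correlation structure.

Builds 12 sites in four groups: two tightly correlated triples (r ~ 0.95,
the fragment-coverage scale), cross-linked at r ~ 0.7 (the biological
scale), plus six independent sites.  Stage 1 (t1 = 0.9) finds the triples;
stage 2 (t1 = 0.6) merges the cross-correlated pair of level-1 blocks.
"""

import numpy as np

from mwaspca import BlockParams, two_stage_blocks
from mwaspca.containers import MethylationMatrix

rng = np.random.default_rng(5)
n = 500
shared = rng.standard_normal(n)  # the "biological" signal linking both triples
cols = []
for _ in range(2):
    g = np.sqrt(0.25) * rng.standard_normal(n) + np.sqrt(0.7) * shared
    cols += [g + np.sqrt(0.05) * rng.standard_normal(n) for _ in range(3)]
cols += [rng.standard_normal(n) for _ in range(6)]

data = MethylationMatrix(
    subject_ids=[f"s{i}" for i in range(n)],
    chromosomes=np.full(12, "1", dtype=object),
    positions=np.arange(1, 13) * 100,
    values=np.column_stack(cols),
)

map1, map2, block_matrix = two_stage_blocks(
    data, BlockParams(t1=0.9, t2=0.9, nt=2), BlockParams(t1=0.6, t2=0.6, nt=2)
)

print(f"{data.n_sites} sites -> {len(map1)} level-1 blocks -> {len(map2)} level-2 blocks")
for b in map2:
    corr = "singleton" if b.mean_corr is None else f"mean r = {b.mean_corr:.3f}"
    print(f"  chr{b.chromosome}:{b.start}-{b.end}  {b.n_sites} site(s)  {corr}")

# The first level-2 block spans all six correlated sites (positions 100-600);
# the six noise sites survive as singleton blocks, so nothing is discarded.
# The block matrix (one mean column per block) is what PCA and association
# testing consume.
print("block matrix shape:", block_matrix.values.shape)
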