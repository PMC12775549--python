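"""Partition observed richness into N- and SAD-components by rarefaction.

A trap with many individuals sees more taxa by passive sampling alone.
Rarefying every trap to a common subsample size isolates that effect:
SAD = expected richness at n_ref; N = observed richness - SAD.
"""

import pandas as pd

from trapdiv import filter_traps, partition_diversity, reference_subsample_size

counts = pd.DataFrame(
    {"Nematocera": [5, 20, 2], "Ephemeroptera": [1, 6, 1],
     "Coleoptera": [1, 4, 1], "Hemiptera": [1, 2, 0]},
    index=pd.Index(["poor", "rich", "sparse"], name="trap_id"),
)
included = filter_traps(counts)          # keep traps with N > S (strictly)
n_ref = reference_subsample_size(counts.loc[included], prefilter=False)
parts = partition_diversity(counts.loc[included], n_ref=n_ref)
print(f"included traps: {list(included)}; reference subsample size: {n_ref}")
print(parts.round(3).to_string())
# 'rich' holds 32 individuals vs 8 at 'poor': its higher observed richness is
# mostly N-component (more individuals), while the SAD-components (expected
# richness at the same n_ref individuals) are directly comparable.
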