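"""K2P distances, the 0.050 substitutions/site species rule, and an NJ tree.

Simulates partial-gene sequences for a focal isolate and four relatives at
known divergences, estimates Kimura two-parameter distances, applies the
baculovirus species-demarcation rule and builds a bootstrapped
neighbor-joining tree.
"""

import numpy as np

from baculokit.distances_trees import (
    AlignedSeqSet,
    bootstrap_support,
    demarcation_table,
    pairwise_matrix,
)
from baculokit.synthetic_data import evolve_k2p

rng = np.random.default_rng(11)
focal = "".join(rng.choice(list("ACGT"), size=530))  # a partial polh-like locus
planted = {"relative1": 0.244, "relative2": 0.27, "relative3": 0.30, "relative4": 0.332}
seqs = {"focal": focal}
for i, (name, d) in enumerate(planted.items()):
    seqs[name] = evolve_k2p(focal, d, kappa=2.0, seed=100 + i)

aln = AlignedSeqSet(list(seqs), list(seqs.values()))
dm = pairwise_matrix(aln)
print("K2P distances from the focal isolate (planted in 0.244..0.332):")
print(demarcation_table(dm, "focal").to_string(index=False))
print("\nevery distance exceeds the 0.050 substitutions/site demarcation "
      "limit: each relative is a different species from the focal isolate")

tree = bootstrap_support(aln, B=200, seed=42)
print("\nNJ tree with bootstrap support (% of 200 replicates):")
print(tree.as_string(schema="newick").strip())
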