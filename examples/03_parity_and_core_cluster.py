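"""Gene parity plots and the conserved core-gene cluster.

A parity plot places each homologous ORF pair at (rank in genome A, rank in
genome B): collinear genomes fall on the diagonal and an inversion shows as
an anti-diagonal run.  Across several genomes, the largest set of core genes
with a shared relative circular order is found exactly.
"""

from baculokit.comparative import (
    CORE_GENES,
    conserved_core_cluster,
    map_homologs,
    parity_data,
)
from baculokit.synthetic_data import shuffle_gene_order, simulate_core_order_profiles


class Orf:
    def __init__(self, orf_id, gene):
        self.orf_id, self.gene = orf_id, gene


# genome B = genome A with one 12-gene inversion and one transposition
genes = [f"gene{i:03d}" for i in range(120)]
permuted, record = shuffle_gene_order(genes, n_inversions=1, n_transpositions=1, seed=5)
a = [Orf(f"A{i}", g) for i, g in enumerate(genes)]
b = [Orf(f"B{i}", g) for i, g in enumerate(permuted)]
hmap = map_homologs(a, b, mode="labels")
parity = parity_data(hmap, [o.orf_id for o in a], [o.orf_id for o in b])
off_diag = sum(1 for x, y, _ in parity.points if x != y)
print(f"parity: {len(parity.points)} homolog pairs, {off_diag} off the diagonal "
      f"(planted operations: {[op['op'] for op in record.operations]})")

# five genome profiles sharing a conserved 17-gene core cluster
profiles, _ = simulate_core_order_profiles(seed=3, n_genomes=5)
cluster = conserved_core_cluster(profiles)
names = {g: CORE_GENES[g] for g in sorted(cluster) if CORE_GENES[g]}
print(f"\nconserved core-gene cluster across {len(profiles)} genomes: "
      f"{len(cluster)} genes")
print("  " + ", ".join(f"{g} ({n})" for g, n in list(names.items())[:6]) + ", ...")
print("the cluster keeps its relative order in every genome even though each "
      "map has its own origin and orientation")
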