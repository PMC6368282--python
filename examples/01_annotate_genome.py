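"""Annotate a circular genome: ORFs, orientation split, promoter motifs.

Builds a synthetic genome emulating a full-size alphabaculovirus record,
reads its curated CDS table, and scans promoter motifs upstream of a few
ORFs of interest.
"""

from baculokit.genome_io import gc_content, translate_cds
from baculokit.orf_annotator import orfs_from_features, orientation_summary, scan_promoter_motifs
from baculokit.synthetic_data import simulate_reference_like_genome

genome, truth = simulate_reference_like_genome(seed=1)
print(f"genome: {genome.id}, {genome.length:,} bp, {gc_content(genome.sequence)}% G+C")

orfs = orfs_from_features(genome)
counts = orientation_summary(orfs, "polh")
print(f"{len(orfs)} annotated ORFs: {counts['polh_sense']} in the polyhedrin sense, "
      f"{counts['anti']} opposite")

orf6 = orfs[5]
hits = scan_promoter_motifs(genome, orf6)
print(f"{orf6.orf_id}: {orf6.length_codons} codons; promoter motifs: "
      + ", ".join(f"{h.motif_class} {h.motif_seq} at {h.offset}" for h in hits))

# the ie-1-like ORF is unusually long because an upstream in-frame ATG
# extends it; translating its printed extent gives the protein length
protein = translate_cds(genome, 120978, 123473, "+")
print(f"ie-1-like ORF at 120,978..123,473 (+): {len(protein)} aa")
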