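# baculokit

Annotation and comparative analysis of circular baculovirus genomes.

Baculoviruses are insect pathogens with large (80–180 kb) circular dsDNA
genomes; new isolates are characterized by a standard battery of analyses:
ORF annotation with promoter-motif scanning, detection of *homologous
regions* (*hr*s — arrays of imperfect palindromic repeats that act as
replication origins and enhancers), gene parity plots and conserved
core-gene-order analysis against reference genomes, and Kimura-2-parameter
(K2P) nucleotide distances on partial *polh*/*lef-8*/*lef-9* sequences for
species demarcation. `baculokit` implements that battery as a tested,
reusable Python library with a synthetic-genome generator, so every stage is
verifiable against known truth without any external downloads.

## What it computes

- **ORF scanning** (`orf_annotator`): every maximal ATG-initiated ORF of
  ≥ 50 codons on both strands of a circular genome, including frames running
  through the origin; baculovirus promoter motifs upstream of each start
  codon (late (A/G/T)TAAG; early CAGT initiator with a TATA box 20–40 bp
  further upstream); orientation relative to *polyhedrin*; overlap/containment
  relations between ORFs on circular coordinates.
- **hr detection** (`hr_finder`): windows whose Hamming distance to their own
  reverse complement is small (default ≤ 8 of 28 bp), clustered along the
  genome into *hr* loci; per-locus majority consensus with the conservation
  classes 100% / >85% / >60%; global-alignment identity between consensus
  sequences.
- **Comparative genomics** (`comparative`): one-to-one homolog maps (curated
  labels or built-in reciprocal-best k-mer matching), gene parity plot
  coordinates with axis points for genome-exclusive ORFs, and the exact
  maximum set of the 38 family-wide core genes whose relative circular order
  is conserved across all compared genomes (each genome allowed one global
  rotation and/or reversal).
- **Distances and trees** (`distances_trees`): K2P distances
  d = −½ ln(1−2P−Q) − ¼ ln(1−2Q) with pairwise deletion, the
  0.050 substitutions/site species-demarcation rule, canonical
  neighbor-joining with deterministic tie-breaking, and nonparametric
  bootstrap support.
- **Synthetic data** (`synthetic_data`): genomes with planted ORFs, promoter
  motifs and *hr* arrays; sequence evolution under the two-parameter
  (transition/transversion) substitution process; gene-order rearrangements —
  all emitting machine-readable ground truth.

## Worked example

```python
from baculokit.genome_io import gc_content, translate_cds
from baculokit.orf_annotator import orfs_from_features, orientation_summary
from baculokit.hr_finder import cluster_hrs, find_palindromic_repeats
from baculokit.synthetic_data import simulate_reference_like_genome

genome, truth = simulate_reference_like_genome(seed=1)
print(genome.length, gc_content(genome.sequence))   # 129528 41.23
orfs = orfs_from_features(genome)
print(len(orfs), orientation_summary(orfs, "polh")) # 139 {'polh_sense': 75, 'anti': 64}
print(len(translate_cds(genome, 120978, 123473, "+")))  # 831
loci = cluster_hrs(find_palindromic_repeats(genome))
print([hr.n_repeats for hr in loci])                # [17, 9, 5, 8, 12]
```

The synthetic reference-like genome plants the characteristics of a full-size
alphabaculovirus record — 129,528 bp at 41.23% G+C with 139 annotated ORFs
(75 in the *polyhedrin* sense), five *hr* loci of 5–16 imperfect 28-bp
palindromic repeats, and an unusually long *ie-1*-type ORF whose printed
coordinates translate to an 831-aa product — and the analysis stack recovers
each of them from the sequence and feature table alone.  The `examples/`
directory holds one short narrative script per capability (annotation, *hr*
detection, parity/core-cluster, distances and trees, simulate-and-recover);
each prints the numbers it computes and a line on what they mean.

A thin command line mirrors the library:

```bash
baculokit simulate --seed 1 --length 20000 --orf 60,+,late --hr 8
baculokit annotate synthetic.fasta --min-codons 50
baculokit hrs synthetic.fasta --unit-len 28 --max-mismatch 8
baculokit k2p alignment.fasta --threshold 0.050
baculokit nj alignment.fasta --bootstrap 500 --seed 1
baculokit run --genome genome.gb --outdir out
```

## Layout

```
src/baculokit/      genome_io, orf_annotator, hr_finder, comparative,
                    distances_trees, synthetic_data, pipeline, cli
tests/              unit + property tests, acceptance suite
examples/           one narrative script per capability
docs/methods.md     models, parameters, design choices, limitations
```
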