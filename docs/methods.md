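# Methods

This note documents the models and procedures `baculokit` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design choices made where the conventions of the field leave
the design open.

## Coordinates and circular genomes

All external coordinates are 1-based inclusive, the GenBank convention, so
printed feature extents can be reproduced verbatim.  A feature that runs
through the replication origin of a circular genome is represented as
`start > end`; internally, extraction and scanning linearize the circle by
doubling the sequence, and results are deduplicated modulo the genome length.
Sequences are restricted to uppercase A/C/G/T/N; lowercase and other IUPAC
ambiguity codes are rejected rather than silently normalized, so downstream
scans are deterministic.  GC content is 100·(G+C)/(A+C+G+T) with N excluded
from the denominator, rounded half-up to two decimals.  In GFF3 output an
origin-spanning feature becomes two part-lines sharing one `ID`, which the
reader reassembles; this keeps the files valid for standard consumers.

## ORF model

An ORF is a maximal ATG-initiated, stop-terminated reading frame: for each
stop codon the 5'-most in-frame ATG since the previous in-frame stop defines
the start.  This matters in practice — an upstream in-frame ATG with no
intervening stop extends an ORF, the mechanism behind unusually long *ie-1*
annotations — and internal-ATG alternatives are available behind a flag.  The
default emission threshold is 50 codons (excluding the stop) with a required
methionine start, the criteria customary for baculovirus genome reports.  On
circular genomes, maximality is per genome stop position: the doubled-sequence
scan can see a shorter variant of an origin-spanning ORF, and only the longest
ORF per stop is kept.

The raw scanner deliberately does **not** claim to reproduce a curated ORF
count from first principles: published annotations resolve overlaps and make
curation choices the raw criteria cannot recover.  Deposited-record analyses
therefore run off the record's CDS feature table (`orfs_from_features`), and
the scanner is validated by the superset property (it must find every curated
ORF, plus chance background ORFs).

Reported ORF extents include the stop codon; `length_codons` and the protein
exclude it.  Translation uses the standard genetic code; an internal stop is
an error in strict mode and a reported `*` in lenient mode (used when
translating curated tables, where sequencing or annotation artifacts occur).

## Promoter motifs

Late transcription in baculoviruses initiates at (A/G/T)TAAG; early promoters
combine an arthropod initiator CAGT with an upstream TATA box.  The scanner
reports, within a 120 bp window upstream of the ATG (offsets relative to the
A): every DTAAG on the ORF's strand as a late hit; every CAGT whose start
lies 20–40 bp downstream of a TATAW box start as a strict early hit; and in
relaxed mode, CAGT or TATAWTW alone.  These explicit motif rules stand in for
interactive promoter-prediction tools whose parameters are not published; the
window and both early modes are exposed so sensitivity can be probed.

## Homologous regions

An *hr* locus is modelled as an array of fixed-length (default 28 bp)
imperfect palindromic units with no internal indels, matching the gap-free
repeat alignments shown in genome reports.  Detection is window-based: a unit
qualifies when the Hamming distance to its own reverse complement is at most
`max_self_mismatch` (default 8 of 28; each substitution in one arm of a
perfect palindrome breaks two symmetric positions, so 8 corresponds to about
four arm substitutions).  A consensus-driven mode additionally requires
Hamming distance ≤ 9 to a supplied consensus (strand-neutral: the unit or its
reverse complement, whichever is closer).  Overlapping qualifying windows are
greedily deduplicated — fewest self-mismatches first, ties to the leftmost —
so accepted hits overlap by at most half a unit.  Hits are clustered by
single linkage along the genome (start-to-start gap ≤ 200 bp), and clusters
of ≥ 5 units (the smallest array size reported for natural loci; relaxable
to 3) become *hr* records.  The published tandem-repeat tools these thresholds
replace do not document comparable settings, so the thresholds here are the
package's own stated, CLI-exposed operating point; planted arrays at the
generator's default noise are recovered at it.

Per-locus consensus is the per-column majority base over the stacked units
(ties in the fixed order A<C<G<T), with columns classified by majority
fraction: 100%, ≥85% (">85%" class), ≥60% (">60%"), else "<60%" — the
shading classes used in repeat-alignment figures; a 6/10 column falls in the
>60% class.  Consensus-to-consensus identity uses Needleman–Wunsch global
alignment (match +1, mismatch −1, gap −2, configurable) with identity =
100 × matched columns / alignment length; because co-optimal alignments can
place gaps differently, the argument pair is canonicalized to keep the value
symmetric.  Published cross-virus consensus identities depend on unstated
alignment and consensus-derivation details, so this quantity is reported but
treated as fragile.

## Parity plots and the conserved core-gene cluster

Homolog maps are one-to-one.  The default route pairs ORFs by curated
gene-name labels; a built-in reciprocal-best-hit mode scores protein pairs by
shared distinct amino-acid 4-mers (floor 5) so synthetic comparisons need no
external search tool.  Parity coordinates are ordinal ranks along each
genome's published order, *polyhedrin* first by convention; genome-exclusive
ORFs become axis points.

"Conserved order" for core genes is formalized as an order-conserved
subsequence on the circle: a gene set is conserved across profiles when its
relative circular order is identical in every genome, allowing each genome
one global rotation and/or one global reversal (genome maps have arbitrary
origins and printed orientations), with intervening non-member genes ignored
— the weakest reading consistent with how such clusters are drawn.  The
maximum such set is computed exactly: anchoring the circle at each candidate
gene and fixing a reversal assignment turns the problem into a longest common
chain over per-profile position vectors (permutations over a shared alphabet,
so common subsequences are exactly chains in the coordinatewise dominance
order); the maximum over anchors and the ≤ 2^(k−1) reversal assignments is
the answer.  At the 38-gene scale this is instantaneous.  Among
maximum-cardinality sets, the one with the lexicographically smallest sorted
name list is returned, by greedy completion against an exact feasibility test
(forced genes must form a chain; gap segments are filled by chain DP).  The
result size can exceed a published cluster because a reported gene list may
be a strict subset of the true maximum.

The 38-gene controlled vocabulary is keyed by AcMNPV ORF numbers with common
names attached where in wide use.  The 17-gene lineage-conserved cluster
(ac77–ac103 block including *helicase*, *pif-4*, *38k*, *lef-5*) is carried
as a constant for simulation truth.

## K2P distances, demarcation, trees

For aligned sequences, sites with a gap or ambiguous base in either member
are excluded per pair (pairwise deletion, the common practice for the
demarcation protocol; complete deletion is a flag).  With transition
proportion P and transversion proportion Q over the n retained sites,
d = −½ ln(1−2P−Q) − ¼ ln(1−2Q).  When an argument of a log is ≤ 0 the
distance is undefined (saturation): single-pair calls raise a typed error,
matrix construction records the pair and returns NaN in that cell, and tree
construction refuses matrices with undefined entries, naming the pairs.  The
delta-method variance c₁²P + c₃²Q − (c₁P + c₃Q)² over n (c₁ = 1/(1−2P−Q),
c₃ = ½(c₁ + 1/(1−2Q))) is provided for recovery checks.

Species demarcation follows the nucleotide-distance rule for partial
*polh*/*lef-8*/*lef-9* sequences: strictly above 0.050 substitutions/site is
`different_species`; strictly below a configurable 0.015 is `same_species`;
anything between, including the threshold itself, is `undetermined` (the
boundary is deliberately exclusive).

Trees are built by canonical neighbor joining, which recovers additive
matrices exactly.  Ties in the Q-matrix argmin are broken by the sorted pair
of cluster representative names (the smallest leaf name in each cluster), so
output is independent of input order.  A negative branch length is clamped to
zero with the deficit moved to its sister edge, preserving the pairwise path
length.  Bootstrap support resamples alignment columns with replacement; each
replicate's RNG stream is indexed by (seed, replicate) so results do not
depend on iteration order, replicates with a saturated pair are skipped and
counted, and support is the percentage of successful replicates containing
each full-data bipartition.  NJ with bootstrap is this package's distance-
based inference; maximum-likelihood and minimum-evolution search are out of
scope, as is multiple-alignment construction (alignments are inputs).

## The synthetic-data generator

`simulate_genome` writes i.i.d. background at a target GC and plants: ORFs
(ATG + random sense codons + TAA, with an in-frame TAA guard immediately
upstream so the planted start is maximal; promoter motifs written at fixed
offsets −30 for DTAAG, −65/−35 for TATAA/CAGT), and *hr* arrays (a random
perfect palindrome consensus, units with i.i.d. substitutions at an 8%
default noise rate, 30 bp apart).  Noisy units are resampled within a bounded
number of tries to stay inside the default detection envelope, modelling
repeats that are imperfect but — as in the genomes this emulates —
detectable.  For small test genomes an option breaks every unplanted chance
ORF by inserting a stop outside protected intervals, so scanner output equals
planted truth exactly; the 129.5-kb reference-like genome instead keeps its
curated planted feature table as the analogue of a deposited record's CDS
annotation, and an exact-GC calibration flips free background bases so the
genome-wide G+C count hits the target composition precisely.

Sequence evolution uses the two-parameter rate matrix (transition rate α =
κ/(κ+2), transversion rate β = 1/(κ+2), normalized to one expected
substitution per site per unit time) exponentiated once per call, with exact
per-site sampling — no discretization bias, so the expected K2P estimate
between input and output equals the requested distance.  Gene-order
simulation applies stated numbers of random segmental inversions and
transpositions and returns the exact permutation.

The generator emulates the statistical structure the analyses assume and no
more: no codon usage, no indels, no recombination, no rate heterogeneity
across sites.  Passing tests therefore demonstrate correctness of the
algorithms under their stated models, not robustness to every property of
real sequence data.

## Problem sizes and reproducibility

The test and acceptance workloads run at the sizes the analyses are specified
at: the reference-like genome at full 129,528 bp scale; ORF- and
palindrome-scanner equivalence against exhaustive oracles on ≤ 5 kb random
sequences; core-cluster equivalence against exhaustive subset search on ≤ 8
genes; NJ additive-recovery on random trees of ≤ 10 taxa; substitution-
parameter recovery at 10,000 sites over 200 replicates against the analytic
standard error; consensus recovery over 100 seeds; bootstrap at 500
replicates.  Every stochastic component takes an explicit seed, replicate
streams are counter-indexed, and identical seed + configuration reproduce
outputs byte-for-byte.

## Known limitations

- The ORF scanner's raw output on a real genome is a superset of any curated
  annotation; reproducing a curated count requires the record's feature table.
- hr detection thresholds are an explicit operating point, not a reimplementation
  of published tandem-repeat tools; sensitivity near the thresholds differs.
- Consensus-identity values depend on alignment scoring; cross-study
  comparability of such percentages is limited.
- K2P assumes equal base frequencies and no rate variation; saturated pairs
  are refused rather than extrapolated.
- The core-cluster search is exact for permutation profiles (no paralogs);
  duplicated gene names are rejected.
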