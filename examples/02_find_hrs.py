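"""Detect homologous regions: imperfect 28-bp palindromes clustered into hr loci.

Alphabaculovirus hr loci are arrays of imperfect palindromic repeats that act
as replication origins and transcriptional enhancers.  The scanner accepts
every window close enough to its own reverse complement, clusters nearby hits
and derives a per-locus majority consensus with conservation classes.
"""

from baculokit.hr_finder import cluster_hrs, consensus_identity, find_palindromic_repeats
from baculokit.synthetic_data import simulate_reference_like_genome

genome, truth = simulate_reference_like_genome(seed=1)
hits = find_palindromic_repeats(genome, unit_len=28, max_self_mismatch=8)
loci = cluster_hrs(hits, min_repeats=5, max_gap=200)

print(f"{len(hits)} palindromic repeat units, {len(loci)} hr loci")
for hr in loci:
    print(f"  {hr.hr_id}: {hr.n_repeats:2d} repeats at {hr.span[0]:,}..{hr.span[1]:,}  "
          f"consensus {hr.consensus}")

# how similar are the hr consensus sequences of two loci?
ident = consensus_identity(loci[0].consensus, loci[1].consensus)
print(f"\nglobal-alignment identity between {loci[0].hr_id} and {loci[1].hr_id} "
      f"consensus sequences: {ident:.1f}%")
print("(each locus was planted from an independent random palindrome, so "
      "identity between loci reflects chance similarity only)")
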