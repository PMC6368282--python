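"""Detection of homologous regions (*hr*s): clustered imperfect palindromes.

Alphabaculovirus genomes carry several *hr* loci, each an array of short
imperfect palindromic repeat units (28 bp in the genomes modelled here) that
act as origins of DNA replication and transcriptional enhancers.  Detection
here is window-based: a unit is accepted when its Hamming distance to its own
reverse complement is small enough (de novo mode), optionally also requiring
similarity to a supplied consensus (consensus-driven mode).  Accepted units
are clustered along the genome into *hr* loci, and a per-column majority
consensus with conservation classes is derived for each locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import GenomeRecord, reverse_complement

__all__ = [
    "PalindromeHit",
    "Hr",
    "find_palindromic_repeats",
    "cluster_hrs",
    "derive_consensus",
    "consensus_identity",
    "self_palindrome_mismatches",
]

# conservation shading classes, highest first; a column qualifies for the
# highest class whose floor its majority fraction reaches (a 6/10 column is
# in the >60% class)
_CONSERVATION_CLASSES = [(1.0, "100%"), (0.85, ">85%"), (0.60, ">60%")]


@dataclass(frozen=True)
class PalindromeHit:
    start: int  # 1-based inclusive
    unit_len: int
    mismatches: int  # Hamming distance of the unit to its own reverse complement
    sequence: str

    @property
    def end(self) -> int:
        return self.start + self.unit_len - 1


@dataclass
class Hr:
    hr_id: str
    repeats: list[PalindromeHit]
    span: tuple[int, int]
    consensus: str = ""
    conservation_profile: list[str] = field(default_factory=list)

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)


def self_palindrome_mismatches(unit: str) -> int:
    """Hamming distance between a unit and its own reverse complement."""
    rc = reverse_complement(unit)
    return sum(1 for a, b in zip(unit, rc) if a != b)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


_CODE = np.frombuffer(b"\x00" * 256, dtype=np.uint8).copy()
for _i, _b in enumerate(b"ACGTN"):
    _CODE[_b] = _i
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N


def find_palindromic_repeats(
    genome: GenomeRecord,
    unit_len: int = 28,
    max_self_mismatch: int = 8,
    consensus: str | None = None,
    max_consensus_mismatch: int = 9,
) -> list[PalindromeHit]:
    """Scan every window of ``unit_len`` bp for imperfect palindromes.

    A window qualifies when its Hamming distance to its own reverse complement
    is <= ``max_self_mismatch``; with a ``consensus`` supplied, the window (or
    its reverse complement, whichever is closer) must additionally lie within
    ``max_consensus_mismatch`` of it.  Overlapping qualifying windows are
    greedily deduplicated, keeping the lower-mismatch hit (ties to the
    leftmost), so that accepted hits overlap by at most ``unit_len // 2``.
    On circular genomes windows running through the origin are scanned too.
    """
    L = genome.length
    if unit_len > L:
        raise ValueError(f"unit_len {unit_len} exceeds genome length {L}")
    if max_self_mismatch < 0 or max_consensus_mismatch < 0:
        raise ValueError("mismatch thresholds must be >= 0")
    seq = genome.sequence + (genome.sequence[: unit_len - 1] if genome.circular else "")
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    win = np.lib.stride_tricks.sliding_window_view(codes, unit_len)  # (n, unit_len)
    rc = _COMP[win][:, ::-1]
    self_mm = (win != rc).sum(axis=1)
    # windows containing N never qualify (N is not self-complementary evidence)
    has_n = (win == 4).any(axis=1)
    ok = (self_mm <= max_self_mismatch) & ~has_n
    if consensus is not None:
        if len(consensus) != unit_len:
            raise ValueError("consensus length must equal unit_len")
        cons = _CODE[np.frombuffer(consensus.encode(), dtype=np.uint8)]
        d_fwd = (win != cons).sum(axis=1)
        d_rev = (rc != cons).sum(axis=1)
        ok &= np.minimum(d_fwd, d_rev) <= max_consensus_mismatch
    idx = np.nonzero(ok)[0]
    candidates = [
        PalindromeHit(start=int(i) + 1, unit_len=unit_len, mismatches=int(self_mm[i]), sequence=seq[i : i + unit_len])
        for i in idx
    ]
    # greedy dedup: best (fewest self-mismatches, then leftmost) first
    max_overlap = unit_len // 2
    accepted: list[PalindromeHit] = []
    occupied: list[tuple[int, int]] = []
    for hit in sorted(candidates, key=lambda h: (h.mismatches, h.start)):
        s, e = hit.start, hit.start + unit_len - 1
        conflict = False
        for (s2, e2) in occupied:
            ov = min(e, e2) - max(s, s2) + 1
            if ov > max_overlap:
                conflict = True
                break
        if not conflict:
            accepted.append(hit)
            occupied.append((s, e))
    return sorted(accepted, key=lambda h: h.start)


def cluster_hrs(
    hits: list[PalindromeHit],
    min_repeats: int = 5,
    max_gap: int = 200,
) -> list[Hr]:
    """Single-linkage clustering of palindrome hits along the genome.

    Consecutive hits whose start-to-start gap is <= ``max_gap`` join one
    cluster; clusters with >= ``min_repeats`` members become *hr* records,
    numbered hr1, hr2, ... in genome order, each with a derived consensus.
    """
    hits = sorted(hits, key=lambda h: h.start)
    clusters: list[list[PalindromeHit]] = []
    for hit in hits:
        if clusters and hit.start - clusters[-1][-1].start <= max_gap:
            clusters[-1].append(hit)
        else:
            clusters.append([hit])
    out: list[Hr] = []
    for members in clusters:
        if len(members) < min_repeats:
            continue
        hr = Hr(
            hr_id=f"hr{len(out) + 1}",
            repeats=members,
            span=(members[0].start, members[-1].end),
        )
        if len(members) >= 2:
            hr.consensus, hr.conservation_profile = derive_consensus(hr)
        out.append(hr)
    return out


_BASE_ORDER = "ACGT"


def derive_consensus(hr: Hr | list[str]) -> tuple[str, list[str]]:
    """Per-column majority consensus over the stacked fixed-length repeats.

    Units are gap-free, so columns align positionally.  Each column is
    classified by the majority fraction: 100%, >85%, >60%, else <60% (the
    shading classes used in repeat-alignment figures).  Ties between bases are
    broken in the fixed order A < C < G < T.
    """
    units = [r.sequence for r in hr.repeats] if isinstance(hr, Hr) else list(hr)
    if len(units) < 2:
        raise ValueError("consensus requires at least 2 repeat units")
    width = len(units[0])
    if any(len(u) != width for u in units):
        raise ValueError("all repeat units must have equal length")
    consensus = []
    profile = []
    n = len(units)
    for col in range(width):
        counts = {b: 0 for b in _BASE_ORDER}
        for u in units:
            if u[col] in counts:
                counts[u[col]] += 1
        best = max(_BASE_ORDER, key=lambda b: counts[b])  # ties: A<C<G<T order
        frac = counts[best] / n
        consensus.append(best)
        for floor, label in _CONSERVATION_CLASSES:
            if frac >= floor:
                profile.append(label)
                break
        else:
            profile.append("<60%")
    return "".join(consensus), profile


def consensus_identity(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> float:
    """Percent identity between two consensus sequences under global alignment.

    Needleman-Wunsch with the given scores; identity is 100 x matched columns
    over the full alignment length (gap columns included in the denominator).
    Co-optimal alignments can differ in gap placement, so the argument pair
    is canonicalized (sorted) to keep the value symmetric.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = sorted((a, b))
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    total = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / total
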