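"""ORF enumeration, promoter-motif scanning and overlap analysis.

The scanner enumerates maximal ATG-initiated open reading frames on both
strands of a (usually circular) genome.  "Maximal" means that for each stop
codon the 5'-most in-frame ATG since the previous in-frame stop is taken as
the start; baculovirus annotation practice keeps ORFs of >= 50 codons started
by a methionine codon, which are the defaults here.

Promoter motifs follow baculovirus convention: late transcription initiates
at (A/G/T)TAAG; early transcription uses an arthropod initiator CAGT with a
TATA box 20-40 bp further upstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .genome_io import (
    GenomeRecord,
    extract_region,
    region_length,
    reverse_complement,
    translate_cds,
)

__all__ = [
    "OrfAnnotation",
    "PromoterHit",
    "OverlapRelation",
    "scan_orfs",
    "orfs_from_features",
    "scan_promoter_motifs",
    "orientation_summary",
    "orf_overlaps",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class OrfAnnotation:
    """One ORF: 1-based inclusive extent including the stop codon."""

    orf_id: str
    start: int
    end: int
    strand: str
    length_codons: int  # excluding the stop codon
    protein: str = ""
    promoter_hits: list["PromoterHit"] = field(default_factory=list)
    orientation: str | None = None  # polh_sense / anti_polh_sense
    gene: str | None = None  # curated gene-name qualifier, if any


@dataclass(frozen=True)
class PromoterHit:
    motif_class: str  # 'early' or 'late'
    motif_seq: str
    offset: int  # bp of motif start relative to the A of ATG (negative)
    box_offset: int | None = None  # TATA-box offset for strict early hits


@dataclass(frozen=True)
class OverlapRelation:
    orf_a: str  # container when relation == contained_within
    orf_b: str
    relation: str  # 'contained_within' or 'partial_overlap'
    same_strand: bool


def _scan_linear(seq: str, min_codons: int, require_atg: bool, include_internal_starts: bool):
    """Yield (start0, end0_exclusive) maximal ORFs in a linear string, all frames.

    Coordinates are 0-based on `seq`; the extent includes the stop codon.
    """
    n = len(seq)
    for frame in range(3):
        prev_stop_codon = -1  # codon index of previous stop in this frame
        starts: list[int] = []  # candidate start codon indices since previous stop
        ncodons = (n - frame) // 3
        for ci in range(ncodons):
            pos = frame + 3 * ci
            codon = seq[pos : pos + 3]
            if codon in _STOPS:
                if starts:
                    emit = starts if include_internal_starts else starts[:1]
                    for s in emit:
                        length_codons = ci - s  # codons before the stop
                        if length_codons >= min_codons:
                            yield (frame + 3 * s, pos + 3)
                starts = []
                prev_stop_codon = ci
            elif codon == "ATG" or (not require_atg and not starts and prev_stop_codon == ci - 1):
                if not starts or include_internal_starts:
                    starts.append(ci)


def scan_orfs(
    genome: GenomeRecord,
    min_codons: int = 50,
    require_atg: bool = True,
    circular: bool | None = None,
    include_internal_starts: bool = False,
) -> list[OrfAnnotation]:
    """Enumerate maximal ORFs of >= ``min_codons`` codons on both strands.

    On circular genomes, frames running through the origin are scanned by
    doubling the sequence; each ORF is reported exactly once, and an
    origin-spanning ORF carries ``start > end``.  Output is sorted by start,
    then strand ('+' first), then end.
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    if circular is None:
        circular = genome.circular
    L = genome.length
    results: dict[tuple[int, int, str], OrfAnnotation] = {}
    # On a circular genome, maximality is per stop codon: keep the longest ORF
    # seen for each (stop position, strand).  The doubled-sequence scan can
    # emit a shorter non-maximal variant for a stop near the origin when the
    # true maximal ATG lies across it.
    best_per_stop: dict[tuple[int, str], tuple[int, tuple[int, int, str]]] = {}
    for strand in "+-":
        s = genome.sequence if strand == "+" else reverse_complement(genome.sequence)
        scan_seq = s + s if circular else s
        for a, b in _scan_linear(scan_seq, min_codons, require_atg, include_internal_starts):
            if circular:
                if a >= L:  # duplicate of an ORF already seen in the first copy
                    continue
                if b - a > L:  # longer than the genome: artefact of doubling
                    continue
            # map strand-local 0-based [a, b) to genome 1-based inclusive extent
            if strand == "+":
                g_start, g_end = a + 1, b
            else:
                g_start, g_end = L - b + 1, L - a
            if circular:
                g_start = (g_start - 1) % L + 1
                g_end = (g_end - 1) % L + 1
            key = (g_start, g_end, strand)
            if key in results:
                continue
            nt_len = b - a
            results[key] = OrfAnnotation(
                orf_id="",
                start=g_start,
                end=g_end,
                strand=strand,
                length_codons=nt_len // 3 - 1,
                protein=translate_cds(genome, g_start, g_end, strand),
            )
            if circular and not include_internal_starts:
                stop_key = (g_end if strand == "+" else g_start, strand)
                prev = best_per_stop.get(stop_key)
                if prev is None or nt_len > prev[0]:
                    if prev is not None:
                        del results[prev[1]]
                    best_per_stop[stop_key] = (nt_len, key)
                else:
                    del results[key]
    order = sorted(results.values(), key=lambda o: (o.start, 0 if o.strand == "+" else 1, o.end))
    for i, orf in enumerate(order, start=1):
        orf.orf_id = f"ORF{i}"
    return order


def orfs_from_features(genome: GenomeRecord, translate: bool = False) -> list[OrfAnnotation]:
    """Build ORF annotations from a record's curated CDS feature table.

    This is how deposited genomes are analysed: the annotation of record, not
    the raw scanner, defines the ORF set (curation resolves overlaps in ways
    raw criteria cannot reproduce).
    """
    orfs = []
    for i, f in enumerate((f for f in genome.features if f.kind == "CDS"), start=1):
        nt_len = region_length(f.start, f.end, genome.length)
        gene = f.qualifiers.get("gene") or f.qualifiers.get("label")
        orfs.append(
            OrfAnnotation(
                orf_id=f.qualifiers.get("ID", f"ORF{i}"),
                start=f.start,
                end=f.end,
                strand=f.strand,
                length_codons=nt_len // 3 - 1,
                protein=translate_cds(genome, f.start, f.end, f.strand, strict=False) if translate else "",
                gene=gene,
            )
        )
    return orfs


_LATE_RE = re.compile(r"[AGT]TAAG")
_TATA_RE = re.compile(r"TATA[AT]")
_TATAWTW_RE = re.compile(r"TATA[AT]T[AT]")


def scan_promoter_motifs(
    genome: GenomeRecord,
    orf: OrfAnnotation,
    window: int = 120,
    early_mode: str = "strict",
) -> list[PromoterHit]:
    """Scan the window upstream of an ORF's ATG for promoter motifs.

    Late: every (A/G/T)TAAG on the ORF's strand.  Early (strict): every CAGT
    initiator with a TATAW box whose start lies 20-40 bp further upstream;
    early (relaxed): every CAGT or TATAWTW on its own.  Offsets are bp of the
    motif start relative to the A of the start codon (negative upstream).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    L = genome.length
    if window > L:
        raise ValueError(f"window of {window} bp exceeds genome length {L}")
    # the upstream window is [atg-window, atg-1] on '+' and [atg+1, atg+window]
    # read on '-'; wrap on circular genomes, clip at the ends on linear ones
    if orf.strand == "+":
        atg = orf.start
        if genome.circular:
            up_start = (atg - window - 1) % L + 1
            up_end = (atg - 2) % L + 1
            upstream = extract_region(genome, up_start, up_end, "+")
        elif atg == 1:
            upstream = ""
        else:
            upstream = extract_region(genome, max(1, atg - window), atg - 1, "+")
    else:
        atg = orf.end
        if genome.circular:
            up_start = atg % L + 1
            up_end = (atg + window - 1) % L + 1
            upstream = extract_region(genome, up_start, up_end, "-")
        elif atg == L:
            upstream = ""
        else:
            upstream = extract_region(genome, atg + 1, min(L, atg + window), "-")
    w = len(upstream)
    # position i in `upstream` has offset i - w relative to the A of ATG
    hits: list[PromoterHit] = []
    for m in _LATE_RE.finditer(upstream):
        hits.append(PromoterHit("late", m.group(), m.start() - w))
    if early_mode == "strict":
        tata_starts = [m.start() for m in _TATA_RE.finditer(upstream)]
        for m in re.finditer("CAGT", upstream):
            for t in tata_starts:
                gap = m.start() - t
                if 20 <= gap <= 40:
                    hits.append(
                        PromoterHit("early", m.group(), m.start() - w, box_offset=t - w)
                    )
                    break
    elif early_mode == "relaxed":
        for m in re.finditer("CAGT", upstream):
            hits.append(PromoterHit("early", m.group(), m.start() - w))
        for m in _TATAWTW_RE.finditer(upstream):
            hits.append(PromoterHit("early", m.group(), m.start() - w))
    else:
        raise ValueError(f"unknown early_mode {early_mode!r}")
    return sorted(hits, key=lambda h: (h.offset, h.motif_class))


def orientation_summary(orfs: list[OrfAnnotation], reference: str) -> dict[str, int]:
    """Count ORFs transcribed in the same sense as the reference (polyhedrin) ORF."""
    ref = next((o for o in orfs if o.orf_id == reference or o.gene == reference), None)
    if ref is None:
        raise ValueError(f"reference ORF {reference!r} not found")
    n_sense = sum(1 for o in orfs if o.strand == ref.strand)
    for o in orfs:
        o.orientation = "polh_sense" if o.strand == ref.strand else "anti_polh_sense"
    return {"polh_sense": n_sense, "anti": len(orfs) - n_sense}


def _unwrapped(orf: OrfAnnotation, L: int) -> tuple[int, int]:
    """Extent as a linear interval [s, e] with e possibly > L for origin-spanners."""
    if orf.start <= orf.end:
        return orf.start, orf.end
    return orf.start, orf.end + L


def orf_overlaps(orfs: list[OrfAnnotation], genome_length: int, circular: bool = True) -> list[OverlapRelation]:
    """Report every pair of ORFs whose extents intersect on the (circular) genome.

    Containment is classified as ``contained_within`` with the container
    reported as ``orf_a``; any other intersection is ``partial_overlap``.
    """
    rels: list[OverlapRelation] = []
    L = genome_length
    shifts = (-L, 0, L) if circular else (0,)
    for i in range(len(orfs)):
        for j in range(i + 1, len(orfs)):
            a, b = orfs[i], orfs[j]
            s1, e1 = _unwrapped(a, L)
            best = None  # (priority, relation, container, contained)
            for k in shifts:
                s2, e2 = (x + k for x in _unwrapped(b, L))
                if e2 < s1 or e1 < s2:
                    continue
                if s1 <= s2 and e2 <= e1:
                    cand = (0, "contained_within", a, b)
                elif s2 <= s1 and e1 <= e2:
                    cand = (0, "contained_within", b, a)
                else:
                    cand = (1, "partial_overlap", a, b)
                if best is None or cand[0] < best[0]:
                    best = cand
            if best is not None:
                _, rel, x, y = best
                rels.append(OverlapRelation(x.orf_id, y.orf_id, rel, a.strand == b.strand))
    return rels
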