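"""Synthetic genomes, alignments and gene orders with known ground truth.

Every analysis stage in this package is testable offline: this module plants
ORFs (ATG-initiated, stop-terminated, with upstream promoter motifs), *hr*
arrays of imperfect 28-bp palindromic repeats, gene-order rearrangements and
pairwise divergence under a two-parameter (transition/transversion)
substitution process, and emits the exact truth next to every artifact.

Background sequence is i.i.d. at a target GC; no codon-usage or indel model
is attempted, because the analyses exercised here assume none.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.linalg import expm

from .genome_io import FeatureRecord, GenomeRecord, reverse_complement
from .orf_annotator import scan_orfs

__all__ = [
    "OrfPlan",
    "HrPlan",
    "SimSpec",
    "SimTruth",
    "simulate_genome",
    "random_palindrome",
    "evolve_k2p",
    "expected_pq",
    "simulate_divergent_pair",
    "simulate_star_alignment",
    "shuffle_gene_order",
    "RearrangementRecord",
    "simulate_reference_like_genome",
    "simulate_core_order_profiles",
    "CONSERVED_CLUSTER_17",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = ["".join(c) for c in itertools.product(_BASES, repeat=3) if "".join(c) not in _STOPS]


@dataclass
class OrfPlan:
    length_codons: int  # excluding the stop codon
    strand: str = "+"
    promoters: tuple[str, ...] = ()  # subset of {'early', 'late'}
    start: int | None = None  # 1-based start of the ORF extent; None = auto-pack
    gene: str | None = None


@dataclass
class HrPlan:
    n_repeats: int
    consensus: str | None = None  # perfect palindrome; None = drawn at random
    noise: float = 0.08  # per-base substitution probability in each repeat unit
    gap: int = 30  # bp between consecutive repeat units
    unit_len: int = 28
    start: int | None = None


@dataclass
class SimSpec:
    genome_length: int
    orfs: list[OrfPlan] = field(default_factory=list)
    hrs: list[HrPlan] = field(default_factory=list)
    gc: float = 0.5
    seed: int = 0
    circular: bool = True
    # break every unplanted ORF of >= this many codons by inserting a stop,
    # so scanner output equals the planted truth (small test genomes only)
    suppress_orfs_above: int | None = None
    exact_gc_count: bool = False  # calibrate genome-wide G+C count exactly


@dataclass
class SimTruth:
    genome_length: int
    seed: int
    gc: float
    orfs: list[dict] = field(default_factory=list)
    hrs: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _rand_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def _rand_codon(rng: np.random.Generator, gc: float, forbid_stop: bool = True) -> str:
    while True:
        codon = _codes_to_str(_rand_bases(rng, 3, gc))
        if not forbid_stop or codon not in _STOPS:
            return codon


def random_palindrome(rng: np.random.Generator, unit_len: int = 28) -> str:
    """A perfect palindrome: random arm + its reverse complement."""
    if unit_len % 2:
        raise ValueError("a perfect nucleotide palindrome needs even length")
    arm = _codes_to_str(_rand_bases(rng, unit_len // 2, 0.5))
    return arm + reverse_complement(arm)


def _noisy_unit(rng: np.random.Generator, consensus: str, noise: float,
                max_self_mm: int = 8, max_cons_mm: int = 9, max_tries: int = 50) -> str:
    """One repeat unit: the consensus with i.i.d. substitutions.

    Units are resampled (bounded tries) until they stay within the detection
    envelope of the default scanner thresholds — the planted arrays model
    repeats that were, by construction of the study design, detectable.
    """
    for _ in range(max_tries):
        chars = list(consensus)
        for i in range(len(chars)):
            if rng.random() < noise:
                chars[i] = rng.choice([b for b in _BASES if b != chars[i]])
        unit = "".join(chars)
        rc = reverse_complement(unit)
        self_mm = sum(1 for a, b in zip(unit, rc) if a != b)
        cons_mm = sum(1 for a, b in zip(unit, consensus) if a != b)
        if self_mm <= max_self_mm and cons_mm <= max_cons_mm:
            return unit
    return consensus


def _orf_nt(rng: np.random.Generator, length_codons: int, gc: float) -> str:
    codons = ["ATG"]
    codons += [_rand_codon(rng, gc) for _ in range(length_codons - 1)]
    codons.append("TAA")
    return "".join(codons)


def _write_at(arr: np.ndarray, pos0: int, s: str) -> None:
    L = arr.shape[0]
    codes = np.frombuffer(s.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    codes = lut[codes]
    idx = (np.arange(pos0, pos0 + len(s))) % L
    arr[idx] = codes


def simulate_genome(spec: SimSpec) -> tuple[GenomeRecord, SimTruth]:
    """Generate a genome with planted ORFs and *hr* arrays, plus its truth.

    Planted ORFs begin with ATG, end with TAA and contain no internal stop;
    an in-frame TAA guard is written immediately upstream of each planted ATG
    so the planted start is the maximal one.  Promoter motifs are written at
    fixed offsets upstream: late (A)TAAG at -30; early TATAA at -65 with the
    CAGT initiator at -35.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.genome_length
    arr = _rand_bases(rng, L, spec.gc)
    protected: list[tuple[int, int]] = []  # 0-based [s, e) intervals (may exceed L; mod)
    truth = SimTruth(genome_length=L, seed=spec.seed, gc=spec.gc)

    def reserve(s: int, e: int) -> None:
        protected.append((s, e))

    def collides(s: int, e: int) -> bool:
        for (s2, e2) in protected:
            if s < e2 and s2 < e:
                return True
        return False

    # lay out: explicit positions first, then auto-packed with random gaps
    planned: list[tuple[str, object, int]] = []  # (kind, plan, block_start0)
    autos: list[tuple[str, object]] = []
    for plan in spec.orfs:
        blen = 3 * (plan.length_codons + 1) + 3 + 3  # guard + ORF incl. stop
        if plan.start is not None:
            if plan.strand == "+":
                block0 = plan.start - 1 - 3
            else:
                block0 = plan.start - 1
            planned.append(("orf", plan, block0))
            reserve(block0, block0 + blen)
        else:
            autos.append(("orf", plan))
    for plan in spec.hrs:
        blen = plan.n_repeats * plan.unit_len + (plan.n_repeats - 1) * plan.gap
        if plan.start is not None:
            planned.append(("hr", plan, plan.start - 1))
            reserve(plan.start - 1, plan.start - 1 + blen)
        else:
            autos.append(("hr", plan))
    cursor = 0
    for kind, plan in autos:
        if kind == "orf":
            blen = 3 * (plan.length_codons + 1) + 3 + 3
            lead = 80 if plan.promoters else 0  # room for upstream motifs
        else:
            blen = plan.n_repeats * plan.unit_len + (plan.n_repeats - 1) * plan.gap
            lead = 0
        gap = int(rng.integers(90, 200))
        pos = cursor + gap + lead
        while collides(pos - lead, pos + blen):
            pos += 50
        if pos + blen > L:
            raise ValueError("infeasible packing: planned features exceed genome length")
        planned.append((kind, plan, pos))
        reserve(pos - lead, pos + blen)
        cursor = pos + blen

    genes: list[FeatureRecord] = []
    for kind, plan, block0 in sorted(planned, key=lambda t: t[2]):
        if kind == "orf":
            orf_nt = _orf_nt(rng, plan.length_codons, spec.gc)
            nt_len = len(orf_nt)
            if plan.strand == "+":
                _write_at(arr, block0, "TAA" + orf_nt)
                g_start0 = block0 + 3
                start = g_start0 % L + 1
                end = (g_start0 + nt_len - 1) % L + 1
                atg0 = g_start0
                up_dir = -1
            else:
                _write_at(arr, block0, reverse_complement("TAA" + orf_nt))
                start = block0 % L + 1
                end = (block0 + nt_len - 1) % L + 1
                atg0 = block0 + nt_len - 1
                up_dir = +1
            for prom in plan.promoters:
                if prom == "late":
                    # motif start sits 30 bp upstream of the A of ATG
                    _plant_motif(arr, L, atg0, up_dir, "ATAAG", -30)
                    reserve_motif(protected, L, atg0, up_dir, -30, 5)
                elif prom == "early":
                    _plant_motif(arr, L, atg0, up_dir, "TATAA", -65)
                    _plant_motif(arr, L, atg0, up_dir, "CAGT", -35)
                    reserve_motif(protected, L, atg0, up_dir, -65, 5)
                    reserve_motif(protected, L, atg0, up_dir, -35, 4)
                else:
                    raise ValueError(f"unknown promoter class {prom!r}")
            quals = {}
            if plan.gene:
                quals["gene"] = plan.gene
            genes.append(FeatureRecord("CDS", start, end, plan.strand, quals))
            truth.orfs.append(
                {
                    "start": start,
                    "end": end,
                    "strand": plan.strand,
                    "length_codons": plan.length_codons,
                    "gene": plan.gene,
                    "promoters": list(plan.promoters),
                }
            )
        else:
            consensus = plan.consensus or random_palindrome(rng, plan.unit_len)
            starts = []
            pos = block0
            for _ in range(plan.n_repeats):
                unit = _noisy_unit(rng, consensus, plan.noise)
                _write_at(arr, pos, unit)
                starts.append(pos % L + 1)
                pos += plan.unit_len + plan.gap
            span_end = (block0 + plan.n_repeats * plan.unit_len + (plan.n_repeats - 1) * plan.gap - 1) % L + 1
            genes.append(
                FeatureRecord("hr", block0 % L + 1, span_end, "+", {"n_repeats": str(plan.n_repeats)})
            )
            truth.hrs.append(
                {"repeat_starts": starts, "consensus": consensus, "n_repeats": plan.n_repeats}
            )

    genome = GenomeRecord(
        id=f"synthetic_seed{spec.seed}",
        sequence=_codes_to_str(arr),
        circular=spec.circular,
        features=genes,
    )
    if spec.suppress_orfs_above is not None:
        genome = _suppress_background_orfs(genome, truth, protected, spec.suppress_orfs_above, rng)
    if spec.exact_gc_count:
        genome = _calibrate_gc(genome, spec.gc, protected, rng)
    return genome, truth


def _plant_motif(arr: np.ndarray, L: int, atg0: int, up_dir: int, motif: str, offset: int) -> None:
    """Write a motif on the ORF's strand at the given offset upstream of ATG."""
    if up_dir == -1:  # '+' strand ORF: upstream is genome-left, motif as-is
        _write_at(arr, (atg0 + offset) % L, motif)
    else:  # '-' strand ORF: upstream is genome-right, motif reverse-complemented
        end0 = atg0 - offset  # genome position of the motif start on the minus strand
        _write_at(arr, (end0 - len(motif) + 1) % L, reverse_complement(motif))


def reserve_motif(protected: list, L: int, atg0: int, up_dir: int, offset: int, mlen: int) -> None:
    if up_dir == -1:
        s = (atg0 + offset) % L
        protected.append((s, s + mlen))
    else:
        s = (atg0 - offset - mlen + 1) % L
        protected.append((s, s + mlen))


def _suppress_background_orfs(
    genome: GenomeRecord, truth: SimTruth, protected: list, min_codons: int, rng: np.random.Generator
) -> GenomeRecord:
    """Insert stop codons into unplanted ORFs until the scanner finds only truth."""
    planted = {(o["start"], o["end"], o["strand"]) for o in truth.orfs}
    L = genome.length
    seq = list(genome.sequence)

    def free(p0: int, n: int) -> bool:
        for (s, e) in protected:
            for q in range(p0, p0 + n):
                qm = q % L
                if s <= qm < e or s <= qm + L < e:
                    return False
        return True

    for _ in range(60):
        spurious = [
            o
            for o in scan_orfs(
                GenomeRecord(genome.id, "".join(seq), genome.circular, genome.features),
                min_codons=min_codons,
            )
            if (o.start, o.end, o.strand) not in planted
        ]
        if not spurious:
            break
        for o in spurious:
            nt_len = 3 * (o.length_codons + 1)
            # pick an unprotected in-frame codon near the middle of the ORF
            placed = False
            for ci in range(o.length_codons // 2, o.length_codons):
                if o.strand == "+":
                    p0 = (o.start - 1 + 3 * ci) % L
                    codon = "TAA"
                else:
                    p0 = (o.end - 1 - 3 * ci - 2) % L
                    codon = reverse_complement("TAA")
                if free(p0, 3) and p0 + 3 <= L:
                    for k, ch in enumerate(codon):
                        seq[p0 + k] = ch
                    placed = True
                    break
            if not placed:
                warnings.warn(f"could not break spurious ORF at {o.start}..{o.end} ({o.strand})")
    return GenomeRecord(genome.id, "".join(seq), genome.circular, genome.features)


def _calibrate_gc(
    genome: GenomeRecord, gc: float, protected: list, rng: np.random.Generator
) -> GenomeRecord:
    """Flip free background bases so the genome-wide G+C count is exact."""
    L = genome.length
    target = round(gc * L)
    seq = list(genome.sequence)
    prot_mask = np.zeros(L, dtype=bool)
    for (s, e) in protected:
        idx = np.arange(s, e) % L
        prot_mask[idx] = True
    current = sum(1 for b in seq if b in "GC")
    delta = target - current
    if delta == 0:
        return genome
    if delta > 0:
        donors = [i for i in range(L) if not prot_mask[i] and seq[i] in "AT"]
        swap = {"A": "G", "T": "C"}
    else:
        donors = [i for i in range(L) if not prot_mask[i] and seq[i] in "GC"]
        swap = {"G": "A", "C": "T"}
    need = abs(delta)
    if need > len(donors):
        raise ValueError("cannot calibrate GC: not enough free background positions")
    for i in rng.choice(len(donors), size=need, replace=False):
        p = donors[int(i)]
        seq[p] = swap[seq[p]]
    return GenomeRecord(genome.id, "".join(seq), genome.circular, genome.features)


# ---------------------------------------------------------------------------
# Two-parameter substitution process

# base order A, C, G, T; transitions are A<->G and C<->T


def _k80_rate_matrix(kappa: float) -> np.ndarray:
    alpha = kappa / (kappa + 2.0)
    beta = 1.0 / (kappa + 2.0)
    Q = np.array(
        [
            [0.0, beta, alpha, beta],
            [beta, 0.0, beta, alpha],
            [alpha, beta, 0.0, beta],
            [beta, alpha, beta, 0.0],
        ]
    )
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q  # normalized: one expected substitution per site per unit time


def expected_pq(d: float, kappa: float) -> tuple[float, float]:
    """Expected transition and transversion proportions at divergence ``d``."""
    P = expm(_k80_rate_matrix(kappa) * d)
    return float(P[0, 2]), float(P[0, 1] + P[0, 3])


def evolve_k2p(seq: str, d_target: float, kappa: float, seed: int) -> str:
    """Evolve a sequence under the two-parameter process to expected distance d.

    Exact site-wise sampling from the matrix exponential of the normalized
    rate matrix; the expected K2P estimate between input and output is
    ``d_target``.  N positions are left unchanged.  Deterministic given seed.
    """
    if d_target < 0:
        raise ValueError("d_target must be >= 0")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if d_target == 0:
        return seq
    p_ts, p_tv = expected_pq(d_target, kappa)
    if 1.0 - 2.0 * p_ts - p_tv < 0.05 or 1.0 - 2.0 * p_tv < 0.05:
        warnings.warn(
            f"d_target={d_target} is close to saturation; estimates may be undefined"
        )
    P = expm(_k80_rate_matrix(kappa) * d_target)
    rng = np.random.default_rng(seed)
    lut = {b: i for i, b in enumerate(_BASES)}
    codes = np.array([lut.get(b, 4) for b in seq])
    out = codes.copy()
    for b in range(4):
        sites = np.nonzero(codes == b)[0]
        if sites.size:
            out[sites] = rng.choice(4, size=sites.size, p=P[b])
    return "".join(_BASES[c] if c < 4 else seq[i] for i, c in enumerate(out))


def simulate_divergent_pair(
    length: int, d: float, kappa: float, seed: int, gc: float = 0.5
) -> tuple[str, str]:
    """An ancestor and a descendant at expected K2P distance ``d``."""
    rng = np.random.default_rng(seed)
    anc = _codes_to_str(_rand_bases(rng, length, gc))
    return anc, evolve_k2p(anc, d, kappa, seed + 1)


def simulate_star_alignment(
    taxa: list[str], d_from_root: list[float], length: int, kappa: float, seed: int
):
    """Independent evolution of each taxon from one root (a star phylogeny)."""
    from .distances_trees import AlignedSeqSet

    rng = np.random.default_rng(seed)
    root = _codes_to_str(_rand_bases(rng, length, 0.5))
    seqs = [evolve_k2p(root, d, kappa, seed + 1 + i) for i, d in enumerate(d_from_root)]
    return AlignedSeqSet(list(taxa), seqs)


# ---------------------------------------------------------------------------
# Gene-order rearrangement


@dataclass
class RearrangementRecord:
    operations: list[dict]
    permutation: list[int]  # permutation[i] = original index of the gene now at i


def shuffle_gene_order(
    genes: list, n_inversions: int, n_transpositions: int, seed: int
) -> tuple[list, RearrangementRecord]:
    """Apply random segmental inversions and transpositions to a gene list."""
    if n_inversions < 0 or n_transpositions < 0:
        raise ValueError("operation counts must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(genes)
    perm = list(range(n))
    ops: list[dict] = []
    kinds = ["inversion"] * n_inversions + ["transposition"] * n_transpositions
    for kind in kinds:
        if kind == "inversion":
            i, j = sorted(rng.choice(n, size=2, replace=False))
            perm[i : j + 1] = perm[i : j + 1][::-1]
            ops.append({"op": "inversion", "start": int(i), "end": int(j)})
        else:
            i, j = sorted(rng.choice(n, size=2, replace=False))
            block = perm[i : j + 1]
            rest = perm[:i] + perm[j + 1 :]
            k = int(rng.integers(0, len(rest) + 1))
            perm = rest[:k] + block + rest[k:]
            ops.append({"op": "transposition", "start": int(i), "end": int(j), "dest": k})
    return [genes[p] for p in perm], RearrangementRecord(ops, perm)


# ---------------------------------------------------------------------------
# Study-scale synthetic stand-ins

# the 17 core genes whose relative order is conserved across the alpha- and
# betabaculovirus genomes compared in parity-plot studies
CONSERVED_CLUSTER_17 = [
    "ac77", "ac78", "ac80", "ac81", "ac83", "ac89", "ac90", "ac92", "ac93",
    "ac94", "ac95", "ac96", "ac98", "ac99", "ac100", "ac101", "ac103",
]


def simulate_reference_like_genome(seed: int = 0) -> tuple[GenomeRecord, SimTruth]:
    """A synthetic stand-in genome with the characteristics of the study isolate.

    Synthetic: no real sequence data is used.  The layout plants the reported
    genome-scale characteristics — 129,528 bp, 41.23% G+C, 139 annotated ORFs
    (75 in the polyhedrin sense, 64 opposite), 5 *hr* loci of 5-16 imperfect
    28-bp palindromic repeats, a 264-codon ORF6 with early and late promoter
    motifs, a 74-codon ORF90 (early) and 53-codon ORF102 (no motifs), and an
    831-codon ie-1-like ORF132 on the plus strand at 120,978..123,473 — so
    every downstream stage can be exercised against known truth.
    """
    rng = np.random.default_rng(seed)
    L = 129528
    gc = 0.4123
    n_orfs = 139
    special_lengths = {1: 245, 6: 264, 90: 74, 102: 53, 132: 831}
    # ORF132 gets no planted motifs: its upstream window abuts the preceding
    # ORF block, and the study's point about it is the absent early motif
    special_promoters = {6: ("early", "late"), 90: ("early",), 102: (), 132: ()}
    special_genes = {1: "polh", 132: "ie-1"}
    # strands: ORF1 (polh) and ORF132 forced '+'; 73 more '+' among the rest
    strands = {1: "+", 132: "+"}
    others = [i for i in range(1, n_orfs + 1) if i not in strands]
    plus_extra = rng.permutation(len(others))[:73]
    for k, idx in enumerate(others):
        strands[idx] = "+" if k in set(int(x) for x in plus_extra) else "-"

    lengths = {}
    for i in range(1, n_orfs + 1):
        if i in special_lengths:
            lengths[i] = special_lengths[i]
        elif i > 132:
            lengths[i] = int(np.clip(rng.lognormal(np.log(100), 0.4), 50, 170))
        else:
            lengths[i] = int(np.clip(rng.lognormal(np.log(190), 0.55), 50, 600))
    # region A holds ORFs 1..131 and the five hr arrays before the fixed ORF132
    hr_counts = [16, 9, 5, 8, 12]
    hr_positions_after = {25: 0, 45: 1, 70: 2, 95: 3, 120: 4}  # hr index after these ORFs
    region_a_end = 120978 - 1 - 3  # leave room for the ORF132 guard
    blocks_a = sum(3 * (lengths[i] + 1) + 6 for i in range(1, 132))
    hr_blocks = [c * 28 + (c - 1) * 30 for c in hr_counts]
    n_slots = 131 + len(hr_counts)
    slack = region_a_end - blocks_a - sum(hr_blocks) - 90 * n_slots
    while slack < 0:  # shrink the longest non-special ORFs until the layout fits
        big = max((i for i in range(1, 132) if i not in special_lengths), key=lambda i: lengths[i])
        lengths[big] = max(50, lengths[big] - 50)
        blocks_a = sum(3 * (lengths[i] + 1) + 6 for i in range(1, 132))
        slack = region_a_end - blocks_a - sum(hr_blocks) - 90 * n_slots
    extra = rng.multinomial(slack, np.ones(n_slots) / n_slots)

    orf_plans: list[OrfPlan] = []
    hr_plans: list[HrPlan] = []
    cursor = 0
    slot = 0
    for i in range(1, 132):
        cursor += 90 + int(extra[slot])
        slot += 1
        blen = 3 * (lengths[i] + 1) + 6
        start = cursor + 3 + 1 if strands[i] == "+" else cursor + 1
        orf_plans.append(
            OrfPlan(
                length_codons=lengths[i],
                strand=strands[i],
                promoters=special_promoters.get(i, ()),
                start=start,
                gene=special_genes.get(i),
            )
        )
        cursor += blen
        if i in hr_positions_after:
            h = hr_positions_after[i]
            cursor += 90 + int(extra[slot])
            slot += 1
            hr_plans.append(HrPlan(n_repeats=hr_counts[h], start=cursor + 1))
            cursor += hr_blocks[h]
    # ORF132 at the printed coordinates, then ORFs 133..139 in the tail
    orf_plans.append(OrfPlan(length_codons=831, strand="+", start=120978, gene="ie-1"))
    cursor = 123473 + 3
    for i in range(133, n_orfs + 1):
        cursor += 120
        blen = 3 * (lengths[i] + 1) + 6
        if cursor + blen > L - 10:
            raise ValueError("tail layout infeasible")
        start = cursor + 3 + 1 if strands[i] == "+" else cursor + 1
        orf_plans.append(OrfPlan(length_codons=lengths[i], strand=strands[i], start=start))
        cursor += blen

    spec = SimSpec(
        genome_length=L,
        orfs=orf_plans,
        hrs=hr_plans,
        gc=gc,
        seed=int(rng.integers(0, 2**31 - 1)),
        exact_gc_count=True,
    )
    genome, truth = simulate_genome(spec)
    genome.id = f"synthetic_reference_like_seed{seed}"
    return genome, truth


def simulate_core_order_profiles(seed: int = 0, n_genomes: int = 5):
    """Synthetic core-gene order profiles for several genomes.

    Each profile contains all 38 core genes.  The 17-gene conserved cluster
    keeps its relative order in every genome; the other 21 core genes are
    inserted at random positions, each genome is randomly rotated, and some
    genomes are reversed — emulating genome maps with arbitrary origins and
    orientations.  Returns (profiles, truth_cluster).
    """
    from .comparative import CORE_GENES, CoreOrderProfile

    rng = np.random.default_rng(seed)
    others = [g for g in CORE_GENES if g not in CONSERVED_CLUSTER_17]
    profiles = []
    for k in range(n_genomes):
        order = list(CONSERVED_CLUSTER_17)
        for g in others:
            order.insert(int(rng.integers(0, len(order) + 1)), g)
        rot = int(rng.integers(0, len(order)))
        order = order[rot:] + order[:rot]
        if k and rng.random() < 0.5:
            order = order[::-1]
        strands = ["+" if rng.random() < 0.5 else "-" for _ in order]
        profiles.append(CoreOrderProfile(genome_id=f"synthetic_genome_{k + 1}", genes=list(zip(order, strands))))
    return profiles, set(CONSERVED_CLUSTER_17)
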