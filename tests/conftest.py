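"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by exhaustive enumeration,
not by calling the implementation under test.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from baculokit.genome_io import GenomeRecord

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
STOPS = {"TAA", "TAG", "TGA"}


def revcomp_oracle(s: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(s))


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def orf_oracle(sequence: str, circular: bool, min_codons: int):
    """Exhaustive maximal-ORF enumeration: every ATG..stop substring, grouped
    by stop, keeping the 5'-most in-frame ATG since the previous stop.

    Returns a set of (start, end, strand) in 1-based inclusive genome
    coordinates, with start > end for origin-spanning ORFs.
    """
    L = len(sequence)
    found = set()
    for strand in "+-":
        s = sequence if strand == "+" else revcomp_oracle(sequence)
        t = s + s if circular else s
        span = len(t)
        # all ATG..stop candidates, any frame
        per_stop: dict[int, list[int]] = {}
        for a in range(span - 2):
            if t[a : a + 3] != "ATG":
                continue
            b = a + 3
            while b + 3 <= span:
                if t[b : b + 3] in STOPS:
                    per_stop.setdefault(b, []).append(a)
                    break
                b += 3
        candidates = []  # (genome stop end, start0, end0_exclusive)
        for stop, starts in per_stop.items():
            a = min(starts)  # the 5'-most ATG per stop is the maximal start
            nt_len = stop + 3 - a
            if nt_len // 3 - 1 < min_codons:
                continue
            if circular:
                if a >= L or nt_len > L:
                    continue
                candidates.append(((stop + 2) % L + 1, a, stop + 3))
            else:
                candidates.append((stop + 3, a, stop + 3))
        # on a circle the same genome stop can be reached twice in the doubled
        # string; only the longest ORF per genome stop is maximal
        best: dict[int, tuple[int, int]] = {}
        for key, a, b in candidates:
            if key not in best or (b - a) > (best[key][1] - best[key][0]):
                best[key] = (a, b)
        for a, b in best.values():
            if strand == "+":
                g_start, g_end = a + 1, b
            else:
                g_start, g_end = L - b + 1, L - a
            if circular:
                g_start = (g_start - 1) % L + 1
                g_end = (g_end - 1) % L + 1
            found.add((g_start, g_end, strand))
    return found


def palindrome_oracle(sequence: str, circular: bool, unit_len: int, max_mm: int):
    """All windows whose Hamming distance to their own reverse complement is
    within max_mm, as (start, mismatches) pairs, 1-based; no deduplication."""
    s = sequence + (sequence[: unit_len - 1] if circular else "")
    out = []
    for i in range(len(s) - unit_len + 1):
        w = s[i : i + unit_len]
        if "N" in w:
            continue
        rc = revcomp_oracle(w)
        mm = sum(1 for a, b in zip(w, rc) if a != b)
        if mm <= max_mm:
            out.append((i + 1, mm))
    return out


def cyclic_canonical(order: tuple) -> tuple:
    """Canonical form of a cyclic sequence under rotation and reversal."""
    variants = []
    for seq in (order, tuple(reversed(order))):
        for r in range(len(seq)):
            variants.append(seq[r:] + seq[:r])
    return min(variants)


def core_cluster_oracle(orders: list[list[str]]):
    """Exhaustive search over subsets of the shared genes for the largest set
    with identical cyclic order (up to rotation/reversal) in every profile."""
    shared = set(orders[0])
    for o in orders[1:]:
        shared &= set(o)
    best: tuple[int, tuple] = (0, ())
    genes = sorted(shared)
    for r in range(len(genes), 0, -1):
        for combo in itertools.combinations(genes, r):
            sub = set(combo)
            forms = {cyclic_canonical(tuple(g for g in o if g in sub)) for o in orders}
            if len(forms) == 1:
                cand = (r, tuple(sorted(combo)))
                if cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                    best = cand
        if best[0] == r:
            break
    return set(best[1])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_genome(rng):
    """A 3 kb random circular genome with no planted structure."""
    return GenomeRecord(id="rand3k", sequence=random_seq(rng, 3000), circular=True)
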