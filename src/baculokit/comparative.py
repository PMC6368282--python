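"""Cross-genome comparison: homolog maps, gene parity plots, core-gene order.

Baculovirus comparative genomics leans on two classic devices reproduced
here.  The *gene parity plot* places each homologous ORF pair at (ordinal
position in genome A, ordinal position in genome B): collinear genomes fall
on the diagonal, inversions form anti-diagonal runs, and ORFs private to one
genome sit on its axis.  The *conserved core-gene cluster* is the largest
subset of the 38 family-wide core genes whose relative circular order is the
same in every genome compared, allowing each genome one global rotation
and/or reversal (genome maps have an arbitrary origin and printed strand).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "CORE_GENES",
    "HomologMap",
    "ParityData",
    "CoreOrderProfile",
    "map_homologs",
    "parity_data",
    "conserved_core_cluster",
    "exclusive_orfs",
    "unique_orfs",
    "plot_parity",
]

# The 38 genes found in every sequenced baculovirus genome, keyed by their
# AcMNPV ORF number with the common name where one is in wide use.  The
# 17-member lineage-conserved order cluster discussed in the literature is a
# subset of these.
CORE_GENES: dict[str, str | None] = {
    "ac6": "lef-2",
    "ac14": "lef-1",
    "ac22": "pif-2",
    "ac40": "p47",
    "ac50": "lef-8",
    "ac53": None,
    "ac54": "vp1054",
    "ac62": "lef-9",
    "ac65": "dnapol",
    "ac66": None,
    "ac68": "pif-6",
    "ac75": None,
    "ac77": "vlf-1",
    "ac78": None,
    "ac80": "gp41",
    "ac81": None,
    "ac83": "vp91",
    "ac89": "vp39",
    "ac90": "lef-4",
    "ac92": "p33",
    "ac93": "p18",
    "ac94": "odv-e25",
    "ac95": "helicase",
    "ac96": "pif-4",
    "ac98": "38k",
    "ac99": "lef-5",
    "ac100": "p6.9",
    "ac101": "p40",
    "ac103": "p48",
    "ac109": "odv-ec43",
    "ac115": "pif-3",
    "ac119": "pif-1",
    "ac133": "alk-exo",
    "ac138": "p74",
    "ac142": "p49",
    "ac143": "odv-e18",
    "ac144": "odv-ec27",
    "ac148": "odv-e56",
}


@dataclass
class HomologMap:
    genome_a: str
    genome_b: str
    pairs: list[tuple[str, str]]
    exclusive_a: list[str]
    exclusive_b: list[str]


@dataclass
class ParityData:
    points: list[tuple[int, int, bool]]  # (rank_a, rank_b, is_core)
    axis_points_a: list[tuple[int, int]]  # (rank_a, 0)
    axis_points_b: list[tuple[int, int]]  # (0, rank_b)


@dataclass
class CoreOrderProfile:
    genome_id: str
    genes: list[tuple[str, str]]  # (core-gene identifier, strand) in genome order

    def __post_init__(self) -> None:
        names = [g for g, _ in self.genes]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate core genes in profile {self.genome_id}")
        unknown = set(names) - set(CORE_GENES)
        if unknown:
            raise ValueError(f"not in the core-gene vocabulary: {sorted(unknown)}")

    @property
    def order(self) -> list[str]:
        return [g for g, _ in self.genes]


def _label_of(orf) -> str | None:
    return getattr(orf, "gene", None)


def _kmers(protein: str, k: int = 4) -> set[str]:
    return {protein[i : i + k] for i in range(len(protein) - k + 1)}


def map_homologs(orfs_a: list, orfs_b: list, mode: str = "labels", min_score: int = 5) -> HomologMap:
    """Pair homologous ORFs between two annotation sets.

    ``labels`` mode pairs ORFs sharing an identical gene-name qualifier (the
    curated route; duplicate labels within one genome are an error).  ``rbh``
    mode pairs reciprocal best matches by shared-peptide k-mer score (distinct
    amino-acid 4-mers in common), requiring score >= ``min_score``; it exists
    so synthetic comparisons need no external search tool.
    """
    if not orfs_a or not orfs_b:
        raise ValueError("both annotation sets must be non-empty")
    ga = getattr(orfs_a[0], "genome_id", "A")
    gb = getattr(orfs_b[0], "genome_id", "B")
    pairs: list[tuple[str, str]] = []
    if mode == "labels":
        for orfs, which in ((orfs_a, "A"), (orfs_b, "B")):
            labels = [_label_of(o) for o in orfs if _label_of(o)]
            if len(labels) != len(set(labels)):
                dup = sorted({l for l in labels if labels.count(l) > 1})
                raise ValueError(f"duplicate labels in genome {which}: {dup}")
        by_label_b = {_label_of(o): o for o in orfs_b if _label_of(o)}
        paired_b = set()
        for o in orfs_a:
            lab = _label_of(o)
            if lab and lab in by_label_b:
                pairs.append((o.orf_id, by_label_b[lab].orf_id))
                paired_b.add(by_label_b[lab].orf_id)
    elif mode == "rbh":
        ka = {o.orf_id: _kmers(o.protein) for o in orfs_a}
        kb = {o.orf_id: _kmers(o.protein) for o in orfs_b}

        def best(query_kmers, pool):
            # tie-break: highest score, then lexicographically smallest id
            scored = [(len(query_kmers & km), oid) for oid, km in pool.items()]
            top = max(s for s, _ in scored)
            return top, min(oid for s, oid in scored if s == top)

        best_ab = {o.orf_id: best(ka[o.orf_id], kb) for o in orfs_a}
        best_ba = {o.orf_id: best(kb[o.orf_id], ka) for o in orfs_b}
        for o in orfs_a:
            score, hit = best_ab[o.orf_id]
            if score >= min_score and best_ba[hit][1] == o.orf_id and best_ba[hit][0] >= min_score:
                pairs.append((o.orf_id, hit))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    paired_a = {a for a, _ in pairs}
    paired_b = {b for _, b in pairs}
    return HomologMap(
        genome_a=ga,
        genome_b=gb,
        pairs=pairs,
        exclusive_a=[o.orf_id for o in orfs_a if o.orf_id not in paired_a],
        exclusive_b=[o.orf_id for o in orfs_b if o.orf_id not in paired_b],
    )


def parity_data(
    hmap: HomologMap,
    order_a: list[str],
    order_b: list[str],
    core_ids_a: set[str] | None = None,
) -> ParityData:
    """Turn a homolog map into gene parity plot coordinates.

    ``order_a``/``order_b`` list every ORF id of each genome in published map
    order (polyhedrin first by convention); ranks are 1-based positions in
    these lists.  Exclusive ORFs become axis points.
    """
    rank_a = {oid: i + 1 for i, oid in enumerate(order_a)}
    rank_b = {oid: i + 1 for i, oid in enumerate(order_b)}
    core_ids_a = core_ids_a or set()
    points = []
    for a, b in hmap.pairs:
        if a not in rank_a:
            raise ValueError(f"ORF {a!r} in map but missing from order_a")
        if b not in rank_b:
            raise ValueError(f"ORF {b!r} in map but missing from order_b")
        points.append((rank_a[a], rank_b[b], a in core_ids_a))
    for a in hmap.exclusive_a:
        if a not in rank_a:
            raise ValueError(f"ORF {a!r} in map but missing from order_a")
    for b in hmap.exclusive_b:
        if b not in rank_b:
            raise ValueError(f"ORF {b!r} in map but missing from order_b")
    return ParityData(
        points=points,
        axis_points_a=[(rank_a[a], 0) for a in hmap.exclusive_a],
        axis_points_b=[(0, rank_b[b]) for b in hmap.exclusive_b],
    )


def exclusive_orfs(hmap: HomologMap) -> tuple[list[str], list[str]]:
    """The ORFs private to each genome of a pairwise comparison."""
    return list(hmap.exclusive_a), list(hmap.exclusive_b)


def unique_orfs(focal_maps: list[HomologMap]) -> list[str]:
    """ORFs of the focal genome (genome_a of every map) absent from all partners."""
    if not focal_maps:
        return []
    unique = set(focal_maps[0].exclusive_a)
    for m in focal_maps[1:]:
        unique &= set(m.exclusive_a)
    return sorted(unique)


# ---------------------------------------------------------------------------
# Conserved core-gene order


def _chain_len(positions: list[dict[str, int]], genes: list[str]) -> int:
    """Longest gene chain increasing in every profile's position vector.

    Exact: a common subsequence of permutations over a shared alphabet is
    precisely a chain in the coordinatewise dominance order, and the longest
    chain is the longest path in that DAG.
    """
    genes = sorted(genes, key=lambda g: positions[0][g])
    best_at: dict[str, int] = {}
    for g in genes:
        best = 1
        for h in genes:
            if positions[0][h] >= positions[0][g]:
                break
            if all(p[h] < p[g] for p in positions):
                best = max(best, best_at[h] + 1)
        best_at[g] = best
    return max(best_at.values(), default=0)


def _max_cluster_through(orders: list[list[str]], forced: list[str]) -> int:
    """Largest order-conserved subset containing every gene in ``forced``.

    Anchors the circle at ``forced[0]``, tries every per-profile reversal,
    requires the forced genes to appear in one common relative order, and
    sums the longest chains in the gaps between consecutive forced genes.
    Returns 0 when no valid subset contains all forced genes.
    """
    anchor = forced[0]
    others = set(orders[0])
    best = 0
    for flips in itertools.product((False, True), repeat=len(orders) - 1):
        oriented = [orders[0]] + [
            list(reversed(o)) if f else o for o, f in zip(orders[1:], flips)
        ]
        positions = []
        for o in oriented:
            i = o.index(anchor)
            rot = o[i:] + o[:i]
            positions.append({g: j for j, g in enumerate(rot)})
        rest = sorted((g for g in forced[1:]), key=lambda g: positions[0][g])
        boundaries = [anchor] + rest
        # forced genes must be a chain themselves (consistent in all profiles)
        if any(
            any(p[boundaries[i]] >= p[boundaries[i + 1]] for p in positions)
            for i in range(len(boundaries) - 1)
        ):
            continue
        total = len(boundaries)
        for i in range(len(boundaries)):
            lo = boundaries[i]
            hi = boundaries[i + 1] if i + 1 < len(boundaries) else None
            seg = [
                g
                for g in others
                if g not in forced
                and all(p[lo] < p[g] for p in positions)
                and (hi is None or all(p[g] < p[hi] for p in positions))
            ]
            total += _chain_len(positions, seg)
        best = max(best, total)
    return best


def conserved_core_cluster(profiles: list[CoreOrderProfile]) -> set[str]:
    """Largest core-gene set whose relative circular order is shared by all profiles.

    Each genome may be globally rotated and/or reversed (maps have arbitrary
    origins and printed orientations); genes outside the set are ignored, so
    this is an order-conserved subsequence, not a contiguity requirement.
    Computed exactly: the maximum size comes from a longest-common-chain
    search over every anchor gene and per-profile reversal assignment; among
    maximum-size sets, the one whose sorted name list is lexicographically
    smallest is selected by greedy completion with an exact feasibility test.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    shared = set(profiles[0].order)
    for p in profiles[1:]:
        shared &= set(p.order)
    if not shared:
        return set()
    orders = [[g for g in p.order if g in shared] for p in profiles]
    k = max(_max_cluster_through(orders, [g]) for g in sorted(shared))
    chosen: list[str] = []
    for g in sorted(shared):
        cand = sorted(chosen + [g])
        if _max_cluster_through(orders, cand) >= k:
            chosen = cand
            if len(chosen) == k:
                break
    return set(chosen)


def plot_parity(parity: ParityData, path: str, label_a: str = "genome A", label_b: str = "genome B") -> None:
    """Scatter plot of parity data; core genes highlighted."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    other = [(x, y) for x, y, c in parity.points if not c]
    core = [(x, y) for x, y, c in parity.points if c]
    if other:
        ax.scatter(*zip(*other), marker="^", s=12, color="tab:blue", label="ORF")
    if core:
        ax.scatter(*zip(*core), marker="^", s=16, color="tab:red", label="core gene")
    for pts in (parity.axis_points_a, parity.axis_points_b):
        if pts:
            ax.scatter(*zip(*pts), marker="x", s=10, color="grey")
    ax.set_xlabel(f"ORF rank in {label_a}")
    ax.set_ylabel(f"ORF rank in {label_b}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
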