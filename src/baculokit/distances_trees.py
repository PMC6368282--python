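"""Kimura two-parameter distances, species demarcation and NJ trees.

The Kimura two-parameter (K2P) model corrects observed divergence separately
for transitions (A<->G, C<->T; proportion P) and transversions (proportion Q):

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)   substitutions/site.

Baculovirus taxonomy applies a demarcation rule to K2P distances computed on
partial polh/granulin, lef-8 and lef-9 sequences: isolates more than 0.050
substitutions/site apart are treated as different species.  Trees are built
by canonical neighbor joining, which recovers additive distance matrices
exactly, with nonparametric bootstrap over alignment columns for support.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AlignedSeqSet",
    "K2PResult",
    "DistanceMatrix",
    "SaturationError",
    "k2p",
    "pairwise_matrix",
    "demarcate_species",
    "demarcation_table",
    "nj_tree",
    "bootstrap_support",
    "write_newick",
    "read_newick",
]

logger = logging.getLogger(__name__)

SPECIES_THRESHOLD = 0.050

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_UNAMBIG = {"A", "C", "G", "T"}


class SaturationError(ValueError):
    """The observed divergence is too high for the K2P correction to be defined."""


@dataclass
class AlignedSeqSet:
    """An alignment: equal-length nucleotide strings, gaps as '-'."""

    taxa: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa and sequences differ in number")
        if len(self.taxa) < 2:
            raise ValueError("an alignment needs at least 2 taxa")
        n = len(self.sequences[0])
        if any(len(s) != n for s in self.sequences):
            raise ValueError("aligned sequences must all have equal length")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0])

    @classmethod
    def from_fasta(cls, path: str | Path) -> "AlignedSeqSet":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def resample_columns(self, rng: np.random.Generator) -> "AlignedSeqSet":
        cols = rng.integers(0, self.n_sites, size=self.n_sites)
        seqs = ["".join(s[c] for c in cols) for s in self.sequences]
        return AlignedSeqSet(list(self.taxa), seqs)


@dataclass(frozen=True)
class K2PResult:
    P: float  # transition proportion
    Q: float  # transversion proportion
    d: float  # substitutions/site
    n_sites: int  # pairwise-complete sites used


def k2p(seq_a: str, seq_b: str) -> K2PResult:
    """Kimura two-parameter distance between two aligned sequences.

    Sites where either sequence has a gap or ambiguous base are excluded
    (pairwise deletion).  Raises :class:`SaturationError` when the correction
    logs are undefined.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    n = ts = tv = 0
    for x, y in zip(seq_a, seq_b):
        if x not in _UNAMBIG or y not in _UNAMBIG:
            continue
        n += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no pairwise-complete sites")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P distance undefined at P={P:.4f}, Q={Q:.4f} (saturated divergence)"
        )
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(P=P, Q=Q, d=d, n_sites=n)


def k2p_variance(P: float, Q: float, n: int) -> float:
    """Large-sample variance of the K2P distance estimate (delta method)."""
    c1 = 1.0 / (1.0 - 2.0 * P - Q)
    c2 = 1.0 / (1.0 - 2.0 * Q)
    c3 = 0.5 * (c1 + c2)
    return (c1 * c1 * P + c3 * c3 * Q - (c1 * P + c3 * Q) ** 2) / n


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal; NaN marks undefined entries
    undefined: set[frozenset] = field(default_factory=set)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.taxa.index(pair[0]), self.taxa.index(pair[1])
        return float(self.matrix[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.6f")


def pairwise_matrix(aln: AlignedSeqSet, complete_deletion: bool = False) -> DistanceMatrix:
    """All pairwise K2P distances from an alignment.

    Gap/ambiguous sites are dropped per pair (pairwise deletion) by default,
    or once for every pair (complete deletion).  A saturated pair is reported
    as NaN and recorded in ``undefined`` rather than raising.
    """
    seqs = aln.sequences
    if complete_deletion:
        keep = [
            i
            for i in range(aln.n_sites)
            if all(s[i] in _UNAMBIG for s in seqs)
        ]
        seqs = ["".join(s[i] for i in keep) for s in seqs]
    m = len(aln.taxa)
    out = np.zeros((m, m))
    undefined: set[frozenset] = set()
    for i in range(m):
        for j in range(i + 1, m):
            try:
                out[i, j] = out[j, i] = k2p(seqs[i], seqs[j]).d
            except SaturationError:
                out[i, j] = out[j, i] = np.nan
                undefined.add(frozenset((aln.taxa[i], aln.taxa[j])))
    return DistanceMatrix(list(aln.taxa), out, undefined)


def demarcate_species(
    d: float,
    threshold: float = SPECIES_THRESHOLD,
    lower: float = 0.015,
) -> str:
    """Apply the nucleotide-distance species demarcation rule.

    Strictly above ``threshold``: different_species.  Strictly below
    ``lower``: same_species.  Anything in between (including the threshold
    itself) is undetermined and calls for more data.
    """
    if not math.isfinite(d):
        raise ValueError("distance must be defined")
    if d > threshold:
        return "different_species"
    if d < lower:
        return "same_species"
    return "undetermined"


def demarcation_table(
    dm: DistanceMatrix,
    focal: str,
    threshold: float = SPECIES_THRESHOLD,
) -> pd.DataFrame:
    """Per-taxon demarcation verdicts against a focal isolate."""
    rows = []
    for t in dm.taxa:
        if t == focal:
            continue
        d = dm[focal, t]
        verdict = "undefined" if not math.isfinite(d) else demarcate_species(d, threshold)
        rows.append({"taxon": t, "d": d, "verdict": verdict})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Neighbor joining


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch to zero, moving the deficit to its sister so the
    pairwise path length is preserved; if both are negative the pair is zeroed."""
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Canonical neighbor joining (Saitou-Nei/Studier-Keppler).

    Deterministic: ties in the Q-matrix argmin are broken by the sorted pair
    of cluster representative names (the smallest leaf name in each cluster).
    Returns an unrooted dendropy tree whose seed node is the final
    trifurcation (or bifurcation for 3 taxa joined at a single node).
    """
    if len(dm.taxa) < 3:
        raise ValueError("NJ needs at least 3 taxa")
    if np.isnan(dm.matrix).any():
        bad = sorted(tuple(sorted(p)) for p in dm.undefined)
        raise ValueError(f"distance matrix has undefined entries: {bad}")
    ns = dendropy.TaxonNamespace(dm.taxa)
    nodes: dict[str, dendropy.Node] = {}
    reps: dict[str, str] = {}  # cluster key -> representative (smallest leaf) name
    d: dict[frozenset, float] = {}
    active: list[str] = []
    for i, t in enumerate(dm.taxa):
        node = dendropy.Node(taxon=ns.get_taxon(t))
        nodes[t] = node
        reps[t] = t
        active.append(t)
    for i in range(len(dm.taxa)):
        for j in range(i + 1, len(dm.taxa)):
            d[frozenset((dm.taxa[i], dm.taxa[j]))] = float(dm.matrix[i, j])

    def dist(a: str, b: str) -> float:
        return d[frozenset((a, b))]

    next_id = 0
    while len(active) > 3:
        r = len(active)
        totals = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best_q = math.inf
        best_pair: tuple[str, str] | None = None
        best_key: tuple[str, str] | None = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                x, y = active[ai], active[bi]
                q = (r - 2) * dist(x, y) - totals[x] - totals[y]
                key = tuple(sorted((reps[x], reps[y])))
                if (
                    best_pair is None
                    or q < best_q - 1e-12
                    or (abs(q - best_q) <= 1e-12 and key < best_key)
                ):
                    best_q, best_pair, best_key = q, (x, y), key
        a, b = best_pair  # type: ignore[misc]
        dab = dist(a, b)
        la = 0.5 * dab + (totals[a] - totals[b]) / (2.0 * (r - 2))
        lb = dab - la
        la, lb = _clamp_pair(la, lb)
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        nodes[a].edge.length = la
        parent.add_child(nodes[b])
        nodes[b].edge.length = lb
        new_key = f"__internal{next_id}"
        next_id += 1
        nodes[new_key] = parent
        reps[new_key] = min(reps[a], reps[b])
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((new_key, c))] = 0.5 * (dist(a, c) + dist(b, c) - dab)
        active = [c for c in active if c not in (a, b)] + [new_key]
    # final three clusters join at the unrooted central node
    x, y, z = sorted(active, key=lambda c: reps[c])
    lx = 0.5 * (dist(x, y) + dist(x, z) - dist(y, z))
    ly = 0.5 * (dist(x, y) + dist(y, z) - dist(x, z))
    lz = 0.5 * (dist(x, z) + dist(y, z) - dist(x, y))
    lengths = {x: lx, y: ly, z: lz}
    for c in (x, y, z):
        lengths[c] = max(lengths[c], 0.0)
    root = dendropy.Node()
    for c in (x, y, z):
        root.add_child(nodes[c])
        nodes[c].edge.length = lengths[c]
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of leaf-name frozensets."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(side) < len(leaves) - 1:
            out.add(frozenset((side, leaves - side)))
    return out


def bootstrap_support(
    aln: AlignedSeqSet,
    B: int = 500,
    seed: int = 0,
    complete_deletion: bool = False,
) -> dendropy.Tree:
    """NJ tree with nonparametric bootstrap support on internal edges.

    ``B`` column-resampled replicates each yield an NJ tree; support is the
    percentage of successful replicates containing each bipartition of the
    full-data tree, written as internal node labels.  Replicates whose matrix
    has a saturated pair are skipped and counted (logged as a warning).
    Replicate resampling streams are indexed by (seed, replicate) so results
    do not depend on iteration order.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    full_dm = pairwise_matrix(aln, complete_deletion)
    tree = nj_tree(full_dm)
    counts: dict[frozenset, int] = {bp: 0 for bp in _bipartitions(tree)}
    used = 0
    skipped = 0
    for rep in range(B):
        rng = np.random.default_rng([seed, rep])
        rep_aln = aln.resample_columns(rng)
        rep_dm = pairwise_matrix(rep_aln, complete_deletion)
        if np.isnan(rep_dm.matrix).any():
            skipped += 1
            continue
        used += 1
        rep_bps = _bipartitions(nj_tree(rep_dm))
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    if skipped:
        logger.warning("bootstrap: skipped %d of %d replicates (saturated pairs)", skipped, B)
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    denom = max(used, 1)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        bp = frozenset((side, leaves - side))
        if bp in counts:
            node.label = f"{100.0 * counts[bp] / denom:g}"
    tree.bootstrap_replicates_used = used  # type: ignore[attr-defined]
    tree.bootstrap_replicates_skipped = skipped  # type: ignore[attr-defined]
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    )


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
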