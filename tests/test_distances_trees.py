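"""K2P distances, demarcation, NJ trees and bootstrap."""

import math

import dendropy
import numpy as np
import pytest

from baculokit.distances_trees import (
    AlignedSeqSet,
    DistanceMatrix,
    SaturationError,
    bootstrap_support,
    demarcate_species,
    demarcation_table,
    k2p,
    k2p_variance,
    nj_tree,
    pairwise_matrix,
    read_newick,
    write_newick,
)
from baculokit.synthetic_data import (
    evolve_k2p,
    expected_pq,
    simulate_divergent_pair,
    simulate_star_alignment,
)

from conftest import random_seq


def make_pair(n, ts, tv):
    """Aligned pair with exactly ts transitions and tv transversions over n sites."""
    a = "A" * n
    b = "G" * ts + "C" * tv + "A" * (n - ts - tv)
    return a, b


class TestK2P:
    def test_identical_sequences(self):
        r = k2p("ACGTACGT", "ACGTACGT")
        assert (r.P, r.Q, r.d) == (0.0, 0.0, 0.0)

    def test_closed_form_at_p10_q05(self):
        a, b = make_pair(100, 10, 5)
        r = k2p(a, b)
        assert (r.P, r.Q, r.n_sites) == (0.10, 0.05, 100)
        assert r.d == pytest.approx(0.170181, abs=1e-6)

    def test_symmetry(self, rng):
        a, b = simulate_divergent_pair(500, 0.2, 2.0, seed=4)
        assert k2p(a, b).d == k2p(b, a).d

    def test_gaps_and_ambiguity_excluded_pairwise(self):
        a = "ACGT" + "-" + "ACGT" + "N"
        b = "ACGT" + "A" + "ACGA" + "C"
        r = k2p(a, b)
        assert r.n_sites == 8
        assert r.Q == pytest.approx(1 / 8)  # T<->A is a transversion
        assert r.P == 0.0

    @pytest.mark.parametrize("p", [0.05, 0.1, 0.15])
    def test_reduces_to_jukes_cantor_when_q_is_2p(self, p):
        # with Q = 2P all substitution types are equally likely and K2P
        # collapses to the Jukes-Cantor correction
        n = 10000
        ts = round(p * n)
        tv = 2 * ts
        a, b = make_pair(n, ts, tv)
        r = k2p(a, b)
        p_total = (ts + tv) / n
        jc = -0.75 * math.log(1 - 4 * p_total / 3)
        assert abs(r.d - jc) < 1e-12

    def test_monotone_in_p_and_q(self):
        base = k2p(*make_pair(1000, 100, 50)).d
        assert k2p(*make_pair(1000, 110, 50)).d > base
        assert k2p(*make_pair(1000, 100, 60)).d > base

    def test_saturation_raises(self):
        a, b = make_pair(100, 50, 10)  # 1 - 2P - Q = -0.1
        with pytest.raises(SaturationError):
            k2p(a, b)

    def test_no_complete_sites_rejected(self):
        with pytest.raises(ValueError):
            k2p("---", "AAA")


class TestPairwiseMatrix:
    def test_identical_taxa_zero_matrix(self):
        aln = AlignedSeqSet(["a", "b", "c"], ["ACGT" * 5] * 3)
        dm = pairwise_matrix(aln)
        assert np.allclose(dm.matrix, 0.0)

    def test_symmetric_zero_diagonal(self, rng):
        aln = simulate_star_alignment(["a", "b", "c", "d"], [0.1] * 4, 400, 2.0, seed=9)
        dm = pairwise_matrix(aln)
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.allclose(np.diag(dm.matrix), 0.0)

    def test_saturated_pair_flagged_not_fatal(self):
        # a vs b saturated; the matrix is still returned with a NaN entry
        aln = AlignedSeqSet(
            ["a", "b", "c"],
            ["A" * 60 + "C" * 40, "G" * 60 + "C" * 40, "A" * 60 + "C" * 40],
        )
        dm = pairwise_matrix(aln)
        assert math.isnan(dm["a", "b"])
        assert frozenset(("a", "b")) in dm.undefined
        assert dm["a", "c"] == 0.0

    def test_planted_divergences_recovered_within_3se(self):
        for d_true in (0.05, 0.10, 0.20):
            a, b = simulate_divergent_pair(20000, d_true, 2.0, seed=int(d_true * 1000))
            r = k2p(a, b)
            p_exp, q_exp = expected_pq(d_true, 2.0)
            se = math.sqrt(k2p_variance(p_exp, q_exp, 20000))
            assert abs(r.d - d_true) < 3 * se


class TestDemarcation:
    @pytest.mark.parametrize(
        "d,verdict",
        [
            (0.244, "different_species"),  # the low end of observed polh distances
            (0.0, "same_species"),
            (0.050, "undetermined"),  # boundary is exclusive
            (0.051, "different_species"),
            (0.03, "undetermined"),
        ],
    )
    def test_rule(self, d, verdict):
        assert demarcate_species(d) == verdict

    def test_report_table(self):
        dm = DistanceMatrix(["me", "x", "y"], np.array(
            [[0, 0.244, 0.01], [0.244, 0, 0.3], [0.01, 0.3, 0]]
        ))
        table = demarcation_table(dm, "me")
        assert list(table.verdict) == ["different_species", "same_species"]


def tree_distances(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    out = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            out[(a.label, b.label)] = pdm.distance(a, b)
    return out


def random_additive_matrix(rng, n_taxa):
    """Distance matrix from a random binary tree with random edge lengths."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        rng=__import__("random").Random(int(rng.integers(1 << 30))),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = taxa[i]
    for e in tree.preorder_edge_iter():
        if e.head_node is not tree.seed_node:
            e.length = float(rng.uniform(0.05, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    m = np.zeros((n_taxa, n_taxa))
    labels = sorted(t.label for t in tns)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                m[i, j] = m[j, i] = pdm.distance(tns.get_taxon(a), tns.get_taxon(b))
    return DistanceMatrix(labels, m), tree


class TestNJ:
    def test_three_taxa_closed_form(self):
        m = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], m))
        dists = tree_distances(tree)
        assert dists[("a", "b")] == pytest.approx(5)
        assert dists[("a", "c")] == pytest.approx(9)
        assert dists[("b", "c")] == pytest.approx(10)

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        taxa = ["A", "B", "C", "D"]
        d = {("A", "B"): 3, ("A", "C"): 8, ("A", "D"): 9,
             ("B", "C"): 9, ("B", "D"): 10, ("C", "D"): 9}
        m = np.zeros((4, 4))
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i < j:
                    m[i, j] = m[j, i] = d[(a, b)]
        tree = nj_tree(DistanceMatrix(taxa, m))
        dists = tree_distances(tree)
        for (a, b), v in d.items():
            assert dists[(a, b)] == pytest.approx(v, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_recovers_random_planted_additive_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        dm, true_tree = random_additive_matrix(rng, n)
        tree = nj_tree(dm)
        dists = tree_distances(tree)
        true_dists = tree_distances(true_tree)
        for pair, v in true_dists.items():
            assert dists[pair] == pytest.approx(v, abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_topology_agrees_with_dendropy_nj(self, seed):
        # independent cross-check against dendropy's own NJ implementation
        rng = np.random.default_rng(100 + seed)
        dm, _ = random_additive_matrix(rng, 8)
        ours = nj_tree(dm)
        csv = "," + ",".join(dm.taxa) + "\n"
        for i, t in enumerate(dm.taxa):
            csv += t + "," + ",".join(str(x) for x in dm.matrix[i]) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv), taxon_namespace=dendropy.TaxonNamespace(dm.taxa)
        )
        theirs = pdm.nj_tree()
        assert _unrooted_bipartitions(ours, dm.taxa) == _unrooted_bipartitions(theirs, dm.taxa)

    def test_tie_breaking_stable_across_input_order(self):
        # ultrametric matrix with equal joins: output invariant to taxon order
        taxa = ["a", "b", "c", "d"]
        m = np.array(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], dtype=float
        )
        t1 = nj_tree(DistanceMatrix(taxa, m))
        perm = [2, 3, 0, 1]
        m2 = m[np.ix_(perm, perm)]
        t2 = nj_tree(DistanceMatrix([taxa[i] for i in perm], m2))
        assert _unrooted_bipartitions(t1, taxa) == _unrooted_bipartitions(t2, taxa)
        assert tree_distances(t1) == tree_distances(t2)

    def test_undefined_entries_named_in_error(self):
        m = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        dm = DistanceMatrix(["a", "b", "c"], m, undefined={frozenset(("a", "b"))})
        with pytest.raises(ValueError, match="a.*b"):
            nj_tree(dm)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


def _unrooted_bipartitions(tree, taxa):
    full = frozenset(taxa)
    out = set()
    for n in tree.preorder_node_iter():
        if n.is_leaf() or n.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in n.leaf_iter())
        if 1 < len(side) < len(full) - 1:
            out.add(frozenset((side, full - side)))
    return out


class TestBootstrap:
    def test_perfect_signal_gives_full_support(self):
        # two clean clades, the same unambiguous columns repeated many times
        block = {"a": "AAAAAAAAAA", "b": "AAAAAAAAAT",
                 "c": "GGAAAAAAAA", "d": "GGAAAAAAAT"}
        aln = AlignedSeqSet(list(block), [v * 40 for v in block.values()])
        tree = bootstrap_support(aln, B=50, seed=1)
        supports = [float(n.label) for n in tree.preorder_node_iter()
                    if not n.is_leaf() and n.label is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_star_signal_has_weak_support(self):
        # no true internal edge: equal independent divergence from one root,
        # so any resolved bipartition is noise and support stays low
        supports = []
        for seed in range(5):
            aln = simulate_star_alignment(
                ["a", "b", "c", "d"], [0.15] * 4, 300, 2.0, seed=seed
            )
            tree = bootstrap_support(aln, B=100, seed=seed)
            supports.extend(float(n.label) for n in tree.preorder_node_iter()
                            if not n.is_leaf() and n.label is not None)
        assert float(np.median(supports)) < 80

    def test_determinism_under_fixed_seed(self):
        aln = simulate_star_alignment(["a", "b", "c", "d", "e"],
                                      [0.05, 0.1, 0.15, 0.2, 0.1], 500, 2.0, seed=2)
        t1 = bootstrap_support(aln, B=30, seed=9)
        t2 = bootstrap_support(aln, B=30, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_newick_roundtrip_preserves_everything(self, tmp_path):
        aln = simulate_star_alignment(["a", "b", "c", "d"], [0.1, 0.1, 0.2, 0.2], 400, 2.0, seed=3)
        tree = bootstrap_support(aln, B=20, seed=5)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert _unrooted_bipartitions(back, [t.label for t in tree.taxon_namespace]) == \
            _unrooted_bipartitions(tree, [t.label for t in tree.taxon_namespace])
        orig = sorted(round(e.length, 10) for e in tree.preorder_edge_iter() if e.length)
        got = sorted(round(e.length, 10) for e in back.preorder_edge_iter() if e.length)
        assert got == orig
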