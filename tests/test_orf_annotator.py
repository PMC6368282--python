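"""ORF scanning against exhaustive oracles, promoter motifs, overlaps."""

import numpy as np
import pytest

from baculokit.genome_io import GenomeRecord
from baculokit.orf_annotator import (
    OrfAnnotation,
    orf_overlaps,
    orientation_summary,
    scan_orfs,
    scan_promoter_motifs,
)
from baculokit.synthetic_data import OrfPlan, SimSpec, simulate_genome

from conftest import orf_oracle, random_seq


class TestScanOrfs:
    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("circular", [True, False])
    def test_matches_exhaustive_oracle_on_random_sequence(self, seed, circular):
        rng = np.random.default_rng(seed)
        g = GenomeRecord("g", random_seq(rng, 5000, gc=0.42), circular=circular)
        got = {(o.start, o.end, o.strand) for o in scan_orfs(g, min_codons=20, circular=circular)}
        assert got == orf_oracle(g.sequence, circular, min_codons=20)

    def test_below_threshold_excluded(self):
        spec = SimSpec(2000, orfs=[OrfPlan(60, "+"), OrfPlan(49, "-")], seed=11,
                       suppress_orfs_above=50)
        g, truth = simulate_genome(spec)
        found = scan_orfs(g, min_codons=50)
        assert [(o.start, o.end, o.strand, o.length_codons) for o in found] == [
            (truth.orfs[0]["start"], truth.orfs[0]["end"], "+", 60)
        ]

    def test_origin_spanning_orf_detected(self):
        spec = SimSpec(2000, orfs=[OrfPlan(70, "+", start=1900)], seed=7)
        g, truth = simulate_genome(spec)
        found = {(o.start, o.end, o.strand): o for o in scan_orfs(g, min_codons=50)}
        key = (1900, (1900 + 3 * 71 - 1) % 2000, "+")
        assert key in found  # detected with start > end across the origin
        orf = found[key]
        assert orf.start > orf.end
        assert orf.protein.startswith("M") and "*" not in orf.protein
        # and the doubled-sequence oracle agrees on the full output
        got = {(o.start, o.end, o.strand) for o in scan_orfs(g, min_codons=50)}
        assert got == orf_oracle(g.sequence, True, 50)

    @pytest.mark.parametrize("seed", range(4))
    def test_every_orf_translates_cleanly(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = GenomeRecord("g", random_seq(rng, 4000), circular=True)
        for o in scan_orfs(g, min_codons=15):
            assert o.protein.startswith("M")
            assert "*" not in o.protein
            assert len(o.protein) == o.length_codons

    def test_linear_scan_of_doubled_sequence_is_superset(self):
        rng = np.random.default_rng(5)
        seq = random_seq(rng, 3000)
        g = GenomeRecord("g", seq, circular=True)
        circ = {(o.start, o.end, o.strand) for o in scan_orfs(g, min_codons=20)}
        doubled = GenomeRecord("gg", seq + seq, circular=False)
        lin = set()
        for o in scan_orfs(doubled, min_codons=20, circular=False):
            lin.add(((o.start - 1) % 3000 + 1, (o.end - 1) % 3000 + 1, o.strand))
        assert circ <= lin

    def test_upstream_inframe_atg_extends_orf(self):
        # an in-frame upstream ATG with no intervening stop wins: the
        # ie-1-style long-ORF behaviour
        seq = "CC" + "TAA" + "ATG" + "AAA" * 5 + "ATG" + "AAA" * 30 + "TAA" + "CC"
        g = GenomeRecord("g", seq, circular=False)
        found = scan_orfs(g, min_codons=30, circular=False)
        assert len(found) == 1
        assert found[0].start == 6
        assert found[0].length_codons == 37

    def test_internal_starts_flag_exposes_alternatives(self):
        seq = "CC" + "TAA" + "ATG" + "AAA" * 5 + "ATG" + "AAA" * 30 + "TAA" + "CC"
        g = GenomeRecord("g", seq, circular=False)
        found = scan_orfs(g, min_codons=30, circular=False, include_internal_starts=True)
        assert {o.length_codons for o in found} == {37, 31}

    def test_min_codons_validation(self, small_genome):
        with pytest.raises(ValueError):
            scan_orfs(small_genome, min_codons=0)


class TestPromoterMotifs:
    def _genome_with_upstream(self, upstream: str, pad: str = "C"):
        orf_nt = "ATG" + "GCA" * 55 + "TAA"
        seq = pad * 10 + upstream + orf_nt + pad * 10
        g = GenomeRecord("g", seq, circular=False)
        start = 10 + len(upstream) + 1
        orf = OrfAnnotation("ORF1", start, start + len(orf_nt) - 1, "+", 56)
        return g, orf

    def test_late_motif_found_at_planted_offset(self):
        up = "C" * 90 + "ATAAG" + "C" * 25  # motif start 30 bp upstream of ATG
        g, orf = self._genome_with_upstream(up)
        hits = scan_promoter_motifs(g, orf, window=120)
        assert [(h.motif_class, h.offset) for h in hits] == [("late", -30)]

    def test_early_strict_needs_tata_and_cagt_spacing(self):
        up = "C" * 55 + "TATAA" + "C" * 25 + "CAGT" + "C" * 31
        g, orf = self._genome_with_upstream(up)
        hits = scan_promoter_motifs(g, orf, window=120)
        assert [(h.motif_class, h.offset, h.box_offset) for h in hits] == [("early", -35, -65)]
        # CAGT alone is not an early promoter in strict mode
        g2, orf2 = self._genome_with_upstream("C" * 85 + "CAGT" + "C" * 31)
        assert scan_promoter_motifs(g2, orf2, window=120) == []
        assert [h.motif_class for h in scan_promoter_motifs(g2, orf2, window=120, early_mode="relaxed")] == ["early"]

    def test_all_c_upstream_has_no_hits(self):
        g, orf = self._genome_with_upstream("C" * 120)
        assert scan_promoter_motifs(g, orf, window=120) == []

    def test_minus_strand_orf_scans_its_own_strand(self):
        spec = SimSpec(3000, orfs=[OrfPlan(60, "-", promoters=("late",))], seed=13)
        g, truth = simulate_genome(spec)
        orf = OrfAnnotation("ORF1", truth.orfs[0]["start"], truth.orfs[0]["end"], "-", 60)
        hits = scan_promoter_motifs(g, orf, window=120)
        assert ("late", -30) in {(h.motif_class, h.offset) for h in hits}

    def test_window_larger_than_genome_rejected(self):
        g = GenomeRecord("g", "ACGT" * 20, circular=True)
        orf = OrfAnnotation("ORF1", 10, 30, "+", 6)
        with pytest.raises(ValueError):
            scan_promoter_motifs(g, orf, window=100)


class TestOrientationSummary:
    def _orfs(self, strands):
        return [OrfAnnotation(f"ORF{i+1}", 10 * i + 1, 10 * i + 9, s, 2) for i, s in enumerate(strands)]

    def test_counts_and_reference_inclusion(self):
        orfs = self._orfs("++-+--")
        assert orientation_summary(orfs, "ORF1") == {"polh_sense": 3, "anti": 3}

    def test_all_same_strand(self):
        orfs = self._orfs("++++")
        assert orientation_summary(orfs, "ORF2") == {"polh_sense": 4, "anti": 0}

    def test_invariant_under_same_strand_relabeling(self):
        orfs = self._orfs("+-+-+")
        assert orientation_summary(orfs, "ORF1") == orientation_summary(orfs, "ORF3")

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            orientation_summary(self._orfs("++"), "ORF9")


class TestOrfOverlaps:
    def test_printed_ie1_ac146_geometry(self):
        # the genome's unusually long ie-1 ORF fully contains an opposite-
        # strand homolog at the printed coordinates
        ie1 = OrfAnnotation("ORF132", 120978, 123473, "+", 831)
        ac146 = OrfAnnotation("ac146", 122839, 123429, "-", 196)
        rels = orf_overlaps([ie1, ac146], genome_length=129528)
        assert len(rels) == 1
        r = rels[0]
        assert (r.orf_a, r.orf_b, r.relation, r.same_strand) == (
            "ORF132", "ac146", "contained_within", False,
        )

    def test_disjoint_orfs_no_relations(self):
        a = OrfAnnotation("a", 100, 200, "+", 33)
        b = OrfAnnotation("b", 300, 400, "+", 33)
        assert orf_overlaps([a, b], genome_length=1000) == []

    def test_partial_overlap_same_strand(self):
        a = OrfAnnotation("a", 100, 250, "+", 50)
        b = OrfAnnotation("b", 200, 350, "+", 50)
        [r] = orf_overlaps([a, b], genome_length=1000)
        assert r.relation == "partial_overlap" and r.same_strand

    def test_origin_spanning_containment(self):
        big = OrfAnnotation("big", 900, 100, "+", 66)  # wraps a 1 kb circle
        small = OrfAnnotation("small", 950, 20, "-", 20)
        [r] = orf_overlaps([big, small], genome_length=1000)
        assert (r.orf_a, r.relation) == ("big", "contained_within")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_interval_intersection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = 10000
        orfs = []
        for i in range(12):
            s = int(rng.integers(1, L + 1))
            length = int(rng.integers(30, 900))
            e = (s + length - 1) % L + 1 if s + length - 1 > L else s + length - 1
            orfs.append(OrfAnnotation(f"o{i}", s, e, "+-"[int(rng.integers(2))], length // 3))

        def covered(o):
            if o.start <= o.end:
                return set(range(o.start, o.end + 1))
            return set(range(o.start, L + 1)) | set(range(1, o.end + 1))

        expected = set()
        for i in range(len(orfs)):
            for j in range(i + 1, len(orfs)):
                ca, cb = covered(orfs[i]), covered(orfs[j])
                if ca & cb:
                    if cb <= ca:
                        rel = ("contained_within", orfs[i].orf_id, orfs[j].orf_id)
                    elif ca <= cb:
                        rel = ("contained_within", orfs[j].orf_id, orfs[i].orf_id)
                    else:
                        rel = ("partial_overlap", orfs[i].orf_id, orfs[j].orf_id)
                    expected.add(rel)
        got = {(r.relation, r.orf_a, r.orf_b) for r in orf_overlaps(orfs, L)}
        assert got == expected
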