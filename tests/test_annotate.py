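"""Breakpoint annotation: exon boundaries, reading frame, separation, neighbors.

The reading-frame implementation (coding-offset congruence mod 3) is
checked against a brute-force translation oracle: build the fused coding
sequence nucleotide-by-nucleotide, translate it, and ask whether the
downstream partner's native peptide reappears after the junction.
"""

import pytest
from Bio.Seq import Seq

from germfuse.annotate import (
    BreakpointAnnotation,
    FrameStatus,
    are_homologs,
    are_neighbors,
    frame_status,
    genomic_separation,
    locate_breakpoint,
    read_through_strict,
)
from germfuse.fusion_io import Breakpoint, HomologSet, Side, Strand


def bp(chrom, pos, side, strand=Strand.FORWARD):
    return Breakpoint(chrom, pos, strand, side)


def ann(boundary=True, offset=0):
    return BreakpointAnnotation(gene="G", transcript="G.t1", exon_index=1,
                                at_exon_boundary=boundary, cds_offset=offset)


class TestLocateBreakpoint:
    def test_all_junction_facing_edges_detected(self, gene_index):
        """Edge-scan oracle: every exon edge, both sides, both strands."""
        for tx in gene_index.transcripts.values():
            order = tx.exons_tx_order()
            for i, ex in enumerate(order, start=1):
                three_edge = ex.end if tx.strand == "+" else ex.start
                five_edge = ex.start if tx.strand == "+" else ex.end
                a = locate_breakpoint(
                    bp(tx.chrom, three_edge, Side.FIVE_PRIME), gene_index)
                assert a.at_exon_boundary, (tx.tx_id, i, "5' side")
                if a.transcript == tx.tx_id:
                    assert a.exon_index == i
                a = locate_breakpoint(
                    bp(tx.chrom, five_edge, Side.THREE_PRIME), gene_index)
                assert a.at_exon_boundary, (tx.tx_id, i, "3' side")

    def test_mid_intron_position_is_not_boundary(self, gene_index):
        tx = gene_index.transcripts["GC1.t1"]
        pos = tx.exons[0].end + 1  # first base of intron 1
        a = locate_breakpoint(bp(tx.chrom, pos, Side.FIVE_PRIME), gene_index)
        assert a.gene == "GC1"
        assert not a.at_exon_boundary and a.exon_index is None

    def test_intergenic_position_has_no_gene(self, gene_index):
        last = max(g.end for g in gene_index.genes.values()
                   if g.chrom == "chrA")
        a = locate_breakpoint(bp("chrA", last + 100, Side.FIVE_PRIME),
                              gene_index)
        assert a.gene is None and a.cds_offset is None

    def test_absent_chromosome_warns_and_returns_empty(self, gene_index):
        with pytest.warns(UserWarning, match="chrZ"):
            a = locate_breakpoint(bp("chrZ", 5, Side.FIVE_PRIME), gene_index)
        assert a.gene is None

    def test_mid_exon_not_junction_facing_edge(self, gene_index):
        tx = gene_index.transcripts["GC1.t1"]
        ex = tx.exons_tx_order()[2]
        mid = (ex.start + ex.end) // 2
        a = locate_breakpoint(bp(tx.chrom, mid, Side.FIVE_PRIME), gene_index)
        assert not a.at_exon_boundary and a.exon_index == 3


class TestFrameStatus:
    @pytest.mark.parametrize("off5,off3,expected", [
        (0, 0, FrameStatus.IN_FRAME),
        (100, 1, FrameStatus.IN_FRAME),      # 100 ≡ 1 (mod 3)
        (100, 0, FrameStatus.OUT_OF_FRAME),
        (7, 4, FrameStatus.IN_FRAME),
        (7, 5, FrameStatus.OUT_OF_FRAME),
    ])
    def test_offset_congruence(self, off5, off3, expected):
        call = frame_status(ann(offset=off5), ann(offset=off3))
        assert call.status is expected

    def test_not_applicable_off_boundary_or_noncoding(self):
        assert frame_status(ann(boundary=False), ann()).status \
            is FrameStatus.NOT_APPLICABLE
        assert frame_status(ann(offset=None), ann()).status \
            is FrameStatus.NOT_APPLICABLE

    def test_translation_oracle_on_planted_coding_fusions(
            self, cohort, gene_index):
        """Frame calls must agree with peptide-level evidence.

        For every planted exon-boundary coding fusion, splice the 5'
        partner's first off5 coding bases onto the 3' partner's coding
        suffix and translate.  The fusion is in frame iff the native
        downstream peptide reappears intact after the junction.
        """
        checked = 0
        for truth in cohort.truths.values():
            if truth.cds_offset5 is None or truth.cds_offset3 is None:
                continue
            tx5 = gene_index.transcripts[truth.transcript5]
            tx3 = gene_index.transcripts[truth.transcript3]
            cds5 = tx5.cds_sequence(cohort.reference.genome[tx5.chrom])
            cds3 = tx3.cds_sequence(cohort.reference.genome[tx3.chrom])
            fused = cds5[:truth.cds_offset5] + cds3[truth.cds_offset3:]
            fused_pep = str(Seq(fused[: len(fused) // 3 * 3]).translate())
            native_tail = str(Seq(cds3[: len(cds3) // 3 * 3]).translate())[-8:]
            oracle_in_frame = native_tail in fused_pep
            assert (truth.frame == "in_frame") == oracle_in_frame, \
                truth.candidate_id
            # and the annotation pathway agrees with the oracle
            cand = next(c for cs in cohort.patients.values() for c in cs
                        if c.candidate_id == truth.candidate_id)
            call = frame_status(locate_breakpoint(cand.bp5, gene_index),
                                locate_breakpoint(cand.bp3, gene_index))
            assert call.status.value == truth.frame, truth.candidate_id
            checked += 1
        assert checked >= 8  # several coding fusions per patient


class TestSeparation:
    def test_same_chromosome_absolute_distance(self):
        assert genomic_separation(
            bp("chr10", 101554225, Side.FIVE_PRIME),
            bp("chr10", 101515382, Side.THREE_PRIME)) == 38843

    def test_interchromosomal_is_undefined(self):
        assert genomic_separation(bp("chr21", 5, Side.FIVE_PRIME),
                                  bp("chr1", 5, Side.THREE_PRIME)) is None

    def test_symmetric_nonnegative_zero_iff_identical(self):
        a, b = bp("chr1", 100, Side.FIVE_PRIME), bp("chr1", 400, Side.THREE_PRIME)
        assert genomic_separation(a, b) == genomic_separation(b, a) == 300
        assert genomic_separation(
            a, bp("chr1", 100, Side.THREE_PRIME)) == 0


class TestNeighborsAndHomologs:
    def test_neighbors_agree_with_exhaustive_span_scan(self, gene_index):
        genes = list(gene_index.genes.values())
        for a in genes:
            for b in genes:
                if a.symbol == b.symbol or a.chrom != b.chrom:
                    continue
                lo = min(a.end, b.end) + 1
                hi = max(a.start, b.start) - 1
                oracle = not any(
                    g.chrom == a.chrom and g.start >= lo and g.end <= hi
                    for g in genes if g.symbol not in (a.symbol, b.symbol))
                assert are_neighbors(a.symbol, b.symbol, gene_index) == oracle

    def test_intervening_gene_breaks_adjacency(self, gene_index):
        assert are_neighbors("RTA", "RTB", gene_index)
        assert not are_neighbors("DUPA", "DUPB", gene_index)

    def test_different_chromosomes_never_neighbors(self, gene_index):
        assert not are_neighbors("GC1", "GC3", gene_index)

    def test_unknown_gene_warns_false(self, gene_index):
        with pytest.warns(UserWarning):
            assert not are_neighbors("GC1", "NOPE", gene_index)

    def test_strict_read_through_requires_collinearity(self, gene_index):
        # RTA and RTB are adjacent, both forward, RTA upstream
        assert read_through_strict("RTA", "RTB", gene_index)
        assert not read_through_strict("RTB", "RTA", gene_index)

    def test_homology_symmetric_with_self_convention(self):
        hs = HomologSet()
        hs.add("DUPA", "DUPB")
        assert are_homologs("DUPA", "DUPB", hs)
        assert are_homologs("DUPB", "DUPA", hs)
        assert are_homologs("GC1", "GC1", hs)   # self-homology by convention
        assert not are_homologs("GC1", "GC2", hs)
        assert not are_homologs(None, "GC1", hs)
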