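"""Query construction, hit gating/selection and alignment summaries."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germfuse.alignment import (
    GENOME,
    TRANSCRIPTOME,
    AlignConfig,
    AlignmentHit,
    build_queries,
    filter_hits,
    query_id_for,
    read_hits,
    select_top_hits,
    summarize_alignments,
    write_hits,
)
from germfuse.fusion_io import Breakpoint, FusionCandidate, Side, Strand


def make_hit(query_id="c|full", subject="chr1", db=GENOME, identity=100.0,
             q_start=1, q_end=100, s_start=1, s_end=100, bitscore=180.0):
    return AlignmentHit(query_id, subject, db, identity, q_end - q_start + 1,
                        0, 0, q_start, q_end, s_start, s_end, 1e-20, bitscore)


def make_candidate(cid="c", seq5="A" * 60, seq3="C" * 40):
    return FusionCandidate(
        cid, "S1",
        Breakpoint("chrA", 100, Strand.FORWARD, Side.FIVE_PRIME),
        Breakpoint("chrB", 200, Strand.FORWARD, Side.THREE_PRIME),
        3, 2, seq_full=(seq5 or "") + (seq3 or "") or None,
        seq5=seq5, seq3=seq3)


class TestAlignConfig:
    def test_defaults_match_short_sequence_settings(self):
        cfg = AlignConfig()
        assert (cfg.word_size, cfg.evalue_max) == (7, 1.0)
        assert (cfg.min_identity, cfg.min_query_coverage) == (0.90, 0.75)

    @pytest.mark.parametrize("kw", [
        {"min_identity": 0.0}, {"min_query_coverage": 1.5}, {"word_size": 3},
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            AlignConfig(**kw)


class TestBuildQueries:
    def test_concatenation_and_ids(self):
        cand = make_candidate()
        records, unalignable = build_queries(cand)
        assert not unalignable
        assert [r.id for r in records] == ["c|full", "c|seg5", "c|seg3"]
        assert len(records[0].seq) == 100
        assert str(records[0].seq) == str(records[1].seq) + str(records[2].seq)

    def test_segments_sliced_from_full_at_junction(self):
        cand = FusionCandidate(
            "c", "S1",
            Breakpoint("chrA", 1, Strand.FORWARD, Side.FIVE_PRIME),
            Breakpoint("chrB", 2, Strand.FORWARD, Side.THREE_PRIME),
            1, 1, seq_full="A" * 50 + "C" * 50)
        records, _ = build_queries(cand, junction=50)
        by_id = {r.id: str(r.seq) for r in records}
        assert by_id["c|seg5"] == "A" * 50
        assert by_id["c|seg3"] == "C" * 50

    def test_no_sequence_flags_unalignable(self):
        cand = FusionCandidate(
            "c", "S1",
            Breakpoint("chrA", 1, Strand.FORWARD, Side.FIVE_PRIME),
            Breakpoint("chrB", 2, Strand.FORWARD, Side.THREE_PRIME), 1, 1)
        records, unalignable = build_queries(cand)
        assert unalignable and records == []


class TestFilterHits:
    QLEN = {"c|full": 100}

    @pytest.mark.parametrize("identity,q_end,kept", [
        (95.0, 80, True),    # 95% identity, 80% coverage
        (89.0, 99, False),   # below the 90% identity gate
        (100.0, 50, False),  # below the 75% coverage gate
        (90.0, 75, True),    # boundary values are inclusive
    ])
    def test_identity_and_coverage_gates(self, identity, q_end, kept):
        h = make_hit(identity=identity, q_end=q_end)
        out = filter_hits([h], AlignConfig(), self.QLEN)
        assert (len(out) == 1) is kept

    def test_unknown_query_raises_with_id(self):
        with pytest.raises(KeyError, match="ghost"):
            filter_hits([make_hit(query_id="ghost|full")], AlignConfig(),
                        self.QLEN)

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.tuples(st.floats(50, 100), st.integers(1, 100),
                              st.integers(1, 100)), max_size=30))
    def test_agrees_with_brute_force_oracle(self, specs):
        cfg = AlignConfig()
        hits = [make_hit(identity=i, q_start=min(a, b), q_end=max(a, b))
                for i, a, b in specs]
        out = filter_hits(hits, cfg, self.QLEN)
        oracle = [h for h in hits
                  if h.pct_identity >= 90.0
                  and (h.q_end - h.q_start + 1) / 100 >= 0.75]
        assert out == oracle
        assert filter_hits(out, cfg, self.QLEN) == out  # idempotent
        assert all(h in hits for h in out)


class TestSelectTopHits:
    def test_argmax_by_score(self):
        h1, h2 = make_hit(bitscore=100), make_hit(bitscore=80, subject="chr2")
        top = select_top_hits([h2, h1])
        assert top[("c|full", GENOME)] == [h1]

    def test_ties_all_retained_as_ambiguous(self):
        h1 = make_hit(subject="T1", db=TRANSCRIPTOME, bitscore=100)
        h2 = make_hit(subject="T2", db=TRANSCRIPTOME, bitscore=100)
        top = select_top_hits([h1, h2])
        assert len(top[("c|full", TRANSCRIPTOME)]) == 2

    def test_absent_query_yields_no_entry(self):
        assert ("c|seg3", GENOME) not in select_top_hits([make_hit()])


class TestSummaries:
    def test_full_unbroken_transcript_hit(self, gene_index):
        cand = make_candidate(seq5="A" * 60, seq3="C" * 40)
        h = make_hit(query_id="c|full", subject="KT1.t1", db=TRANSCRIPTOME,
                     q_end=100)
        summary = summarize_alignments(cand, select_top_hits([h]), gene_index)
        assert summary.full_unbroken_tx_hit
        assert summary.full_tx_subject == "KT1.t1"
        assert not summary.full_unbroken_genome_hit

    def test_segment_gene_and_chromosome_resolution(self, gene_index):
        cand = make_candidate()
        gc1 = gene_index.genes["GC1"]
        gc3 = gene_index.genes["GC3"]
        hits = [
            make_hit(query_id="c|seg5", subject=gc1.chrom,
                     q_end=60, s_start=gc1.start, s_end=gc1.start + 59),
            make_hit(query_id="c|seg3", subject="GC3.t1", db=TRANSCRIPTOME,
                     q_end=40, s_end=40),
        ]
        summary = summarize_alignments(cand, select_top_hits(hits), gene_index)
        assert summary.seg5_genes == ("GC1",)
        assert summary.seg3_genes == ("GC3",)
        assert summary.seg5_chroms == (gc1.chrom,)
        assert summary.seg3_chroms == (gc3.chrom,)

    def test_no_hits_means_no_alignment(self, gene_index):
        summary = summarize_alignments(make_candidate(), {}, gene_index,
                                       raw_hits=[])
        assert not summary.any_alignment
        assert summary.full_best_raw_coverage == 0.0

    def test_raw_coverage_measured_before_gate(self, gene_index):
        cand = make_candidate()
        raw = [make_hit(query_id="c|full", q_end=55)]  # 55% of full query
        summary = summarize_alignments(cand, {}, gene_index, raw_hits=raw)
        assert summary.full_best_raw_coverage == pytest.approx(0.55)


class TestHitIO:
    def test_tabular_round_trip(self, tmp_path):
        hits = [make_hit(), make_hit(query_id="c|seg5", q_end=60,
                                     db=GENOME, s_start=500, s_end=441)]
        p = tmp_path / "hits.tsv"
        write_hits(hits, p)
        back = read_hits(p, GENOME)
        assert back == hits

    def test_reverse_orientation_signalled_by_subject_coords(self):
        h = make_hit(s_start=500, s_end=441)
        assert h.subject_interval == (441, 500)


class TestExternalAligner:
    """Exercised only when the aligner binary is installed (it is optional)."""

    def test_exact_substring_and_reverse_complement(self, tmp_path):
        import shutil

        from Bio.Seq import Seq

        from germfuse.alignment import AlignerNotFoundError, run_external_aligner

        import numpy as np

        rng = np.random.default_rng(5)
        db_seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
        query = db_seq[400:430]
        rc = str(Seq(query).reverse_complement())
        (tmp_path / "db.fa").write_text(f">subj\n{db_seq}\n")
        (tmp_path / "q.fa").write_text(f">q1|full\n{query}\n>q2|full\n{rc}\n")
        if shutil.which("blastn") is None:
            with pytest.raises(AlignerNotFoundError):
                run_external_aligner(tmp_path / "q.fa", tmp_path / "db.fa",
                                     AlignConfig(), tmp_path / "out.tsv")
            return
        out = run_external_aligner(tmp_path / "q.fa", tmp_path / "db.fa",
                                   AlignConfig(), tmp_path / "out.tsv")
        hits = read_hits(out, GENOME)
        fwd = [h for h in hits if h.query_id == "q1|full"]
        rev = [h for h in hits if h.query_id == "q2|full"]
        assert fwd and fwd[0].pct_identity == 100.0
        assert fwd[0].s_start == 401 and fwd[0].s_end == 430
        assert rev and rev[0].s_start > rev[0].s_end

    def test_empty_query_file_gives_empty_output(self, tmp_path):
        import shutil

        if shutil.which("blastn") is None:
            pytest.skip("external aligner not installed (optional feature)")
        from germfuse.alignment import run_external_aligner

        (tmp_path / "db.fa").write_text(">s\nACGTACGTACGT\n")
        (tmp_path / "q.fa").write_text("")
        out = run_external_aligner(tmp_path / "q.fa", tmp_path / "db.fa",
                                   AlignConfig(), tmp_path / "out.tsv")
        assert out.read_text() == ""
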