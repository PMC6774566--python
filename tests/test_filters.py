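"""Depth, normal-control and cohort-recurrence filter behavior."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germfuse.filters import (
    FusionKey,
    NormalFusionDB,
    build_normal_db,
    cohort_recurrence_filter,
    depth_filter,
    normal_db_filter,
)
from germfuse.fusion_io import (
    Breakpoint,
    CandidateSet,
    FusionCandidate,
    Side,
    Strand,
)


def make_candidate(cid="c1", sample="S1", chrom5="chr1", pos5=100,
                   chrom3="chr2", pos3=200, split=1, spanning=1):
    return FusionCandidate(
        cid, sample,
        Breakpoint(chrom5, pos5, Strand.FORWARD, Side.FIVE_PRIME),
        Breakpoint(chrom3, pos3, Strand.REVERSE, Side.THREE_PRIME),
        split, spanning)


def make_set(cands, sample="S1"):
    return CandidateSet(sample_id=sample, candidates=list(cands))


@st.composite
def candidate_sets(draw):
    n = draw(st.integers(0, 25))
    cands = []
    for i in range(n):
        cands.append(make_candidate(
            cid=f"c{i}",
            chrom5=draw(st.sampled_from(["chr1", "chr2"])),
            pos5=draw(st.integers(1, 50)),
            chrom3=draw(st.sampled_from(["chr1", "chr2"])),
            pos3=draw(st.integers(1, 50)),
            split=draw(st.integers(0, 6)),
            spanning=draw(st.integers(0, 6))))
    return make_set(cands)


class TestFusionKey:
    def test_canonical_ordering(self):
        a = make_candidate(chrom5="chr2", pos5=500, chrom3="chr1", pos3=100)
        b = make_candidate(chrom5="chr1", pos5=100, chrom3="chr2", pos3=500)
        assert FusionKey.from_candidate(a).coords == \
            FusionKey.from_candidate(b).coords

    def test_natural_chromosome_order(self):
        c = make_candidate(chrom5="chr10", pos5=5, chrom3="chr2", pos3=9)
        key = FusionKey.from_candidate(c)
        assert key.chromA == "chr2"  # chr2 before chr10, not lexicographic

    def test_reciprocal_coordinates_keep_distinct_keys(self):
        fwd = make_candidate(chrom5="chr1", pos5=100, chrom3="chr1", pos3=900)
        rec = make_candidate(chrom5="chr1", pos5=905, chrom3="chr1", pos3=103)
        assert FusionKey.from_candidate(fwd).coords != \
            FusionKey.from_candidate(rec).coords


class TestDepthFilter:
    def test_single_split_and_spanning_pair_suffices(self):
        kept, removed = depth_filter(make_set([make_candidate(split=1, spanning=1)]))
        assert len(kept) == 1 and len(removed) == 0

    def test_both_read_classes_required(self):
        # high split support cannot compensate for zero spanning pairs
        kept, removed = depth_filter(make_set([make_candidate(split=5, spanning=0)]))
        assert len(kept) == 0 and len(removed) == 1

    def test_empty_input(self):
        kept, removed = depth_filter(make_set([]))
        assert len(kept) == 0 and len(removed) == 0

    @settings(max_examples=60, derandomize=True)
    @given(candidate_sets(), st.integers(0, 5), st.integers(0, 5))
    def test_partition_idempotence_monotonicity(self, cset, ms, msp):
        kept, removed = depth_filter(cset, ms, msp)
        ids = [c.candidate_id for c in cset]
        assert sorted(c.candidate_id for c in kept.candidates
                      + removed.candidates) == sorted(ids)
        assert not (set(c.candidate_id for c in kept)
                    & set(c.candidate_id for c in removed))
        again, none = depth_filter(kept, ms, msp)
        assert len(none) == 0 and len(again) == len(kept)
        stricter, _ = depth_filter(cset, ms + 1, msp + 1)
        assert len(stricter) <= len(kept)

    @settings(max_examples=60, derandomize=True)
    @given(candidate_sets())
    def test_caller_default_thresholds_never_more_inclusive(self, cset):
        inclusive, _ = depth_filter(cset, 1, 1)
        caller_default, _ = depth_filter(cset, 3, 2)
        assert {c.candidate_id for c in caller_default} <= \
            {c.candidate_id for c in inclusive}


class TestNormalDB:
    def test_three_read_control_event_enters_db(self):
        db = build_normal_db([make_set([make_candidate(split=2, spanning=1)],
                                       sample="N1")])
        assert len(db) == 1

    def test_single_read_event_is_insufficient_evidence(self):
        db = build_normal_db([make_set([make_candidate(split=1, spanning=0)],
                                       sample="N1")])
        assert len(db) == 0
        assert len(db.observations) == 1  # retained for histograms

    def test_per_sample_rule_not_pooled(self):
        sets = [make_set([make_candidate(split=1, spanning=0)], sample=f"N{i}")
                for i in range(2)]
        assert len(build_normal_db(sets)) == 0
        assert len(build_normal_db(sets, pool_samples=True)) == 1

    def test_duplicate_key_in_sample_sums_with_warning(self):
        cset = make_set([make_candidate(cid="a", split=1, spanning=0),
                         make_candidate(cid="b", split=1, spanning=0)],
                        sample="N1")
        with pytest.warns(UserWarning, match="duplicate"):
            db = build_normal_db([cset])
        assert len(db) == 1  # 1+1 reads summed within the sample

    def test_filter_removes_exact_match_keeps_others(self):
        db = build_normal_db([make_set([make_candidate(split=3, spanning=1)],
                                       sample="N1")])
        patient = make_set([make_candidate(cid="hit"),
                            make_candidate(cid="miss", pos5=999)])
        kept, removed = normal_db_filter(patient, db)
        assert [c.candidate_id for c in removed] == ["hit"]
        assert [c.candidate_id for c in kept] == ["miss"]

    def test_fuzz_window_matches_offset_keys(self):
        db = build_normal_db([make_set([make_candidate(pos5=100, pos3=200,
                                                       split=3, spanning=1)],
                                       sample="N1")])
        shifted = make_set([make_candidate(pos5=103, pos3=200)])
        kept, removed = normal_db_filter(shifted, db, fuzz_bp=5)
        assert len(removed) == 1
        kept, removed = normal_db_filter(shifted, db, fuzz_bp=2)
        assert len(kept) == 1

    @settings(max_examples=40, derandomize=True)
    @given(candidate_sets(), st.integers(0, 6))
    def test_fuzz_match_agrees_with_window_oracle(self, cset, fuzz):
        controls = make_set(
            [make_candidate(cid="n", pos5=25, pos3=25, split=3, spanning=1)],
            sample="N1")
        db = build_normal_db([controls])
        kept, removed = normal_db_filter(cset, db, fuzz_bp=fuzz)
        removed_ids = {c.candidate_id for c in removed}
        for c in cset:
            key = FusionKey.from_candidate(c)
            oracle = any(
                key.chromA == dk[0] and key.chromB == dk[2]
                and abs(key.posA - dk[1]) <= fuzz
                and abs(key.posB - dk[3]) <= fuzz
                for dk in db.qualified)
            assert (c.candidate_id in removed_ids) == oracle

    def test_tsv_round_trip(self, tmp_path):
        db = build_normal_db([make_set([make_candidate(split=3, spanning=1),
                                        make_candidate(cid="c2", pos5=7,
                                                       split=1, spanning=0)],
                                       sample="N1")])
        p = tmp_path / "db.tsv"
        db.to_tsv(p)
        back = NormalFusionDB.from_tsv(p)
        assert back.qualified == db.qualified
        assert back.metadata["min_reads"] == "2"

    def test_growing_db_never_grows_kept(self):
        patient = make_set([make_candidate(cid=f"c{i}", pos5=i + 1)
                            for i in range(10)])
        small = build_normal_db(
            [make_set([make_candidate(pos5=3, split=3, spanning=1)], "N1")])
        big = build_normal_db(
            [make_set([make_candidate(pos5=3, split=3, spanning=1),
                       make_candidate(cid="x", pos5=5, split=3, spanning=1)],
                      "N1")])
        kept_small, _ = normal_db_filter(patient, small)
        kept_big, _ = normal_db_filter(patient, big)
        assert {c.candidate_id for c in kept_big} <= \
            {c.candidate_id for c in kept_small}


class TestCohortRecurrence:
    def test_shared_key_removed_from_both_patients(self):
        per = {"A": make_set([make_candidate(cid="a1")], "A"),
               "B": make_set([make_candidate(cid="b1")], "B")}
        out = cohort_recurrence_filter(per)
        assert len(out["A"][1]) == 1 and len(out["B"][1]) == 1

    def test_private_key_kept(self):
        per = {"A": make_set([make_candidate(cid="a1")], "A"),
               "B": make_set([make_candidate(cid="b1", pos5=999)], "B")}
        out = cohort_recurrence_filter(per)
        assert len(out["A"][0]) == 1 and len(out["B"][0]) == 1

    def test_key_in_all_three_removed_from_all(self):
        per = {p: make_set([make_candidate(cid=f"{p}1")], p)
               for p in ("A", "B", "C")}
        out = cohort_recurrence_filter(per)
        assert all(len(kept) == 0 and len(removed) == 1
                   for kept, removed in out.values())

    def test_within_patient_duplicates_do_not_trigger(self):
        per = {"A": make_set([make_candidate(cid="a1"),
                              make_candidate(cid="a2")], "A")}
        out = cohort_recurrence_filter(per)
        assert len(out["A"][0]) == 2
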