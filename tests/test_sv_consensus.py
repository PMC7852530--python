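"""Dual-caller SV consensus, parental subtraction, exclusion and coverage filters."""

import numpy as np
import pytest

from triodnv.annotate import AnnotationTrackSet
from triodnv.io_formats import GenomicInterval, SvCall
from triodnv.sv_consensus import (
    CoverageSet,
    annotation_exclusion,
    coverage_similarity_filter,
    describe_exon_effect,
    intersect_callers,
    reciprocal_overlap,
    run_sv_pipeline,
    subtract_parental,
)


def sv(start, end, svtype="DEL", caller="A", sample="kid", status="called",
       chrom="chr1"):
    return SvCall(chrom, start, end, svtype, (end - start) + 1, caller,
                  sample, status)


class TestReciprocalOverlap:
    def test_half_overlap(self):
        assert reciprocal_overlap(sv(100, 200), sv(150, 250)) == (0.5, 0.5)

    def test_identical_and_disjoint(self):
        assert reciprocal_overlap(sv(100, 200), sv(100, 200)) == (1.0, 1.0)
        assert reciprocal_overlap(sv(100, 200), sv(300, 400)) == (0.0, 0.0)

    def test_symmetry_under_argument_swap(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            s1, s2 = sorted(rng.integers(0, 10_000, 2))
            s3, s4 = sorted(rng.integers(0, 10_000, 2))
            if s2 == s1 or s4 == s3:
                continue
            a, b = sv(int(s1), int(s2)), sv(int(s3), int(s4))
            assert reciprocal_overlap(a, b) == reciprocal_overlap(b, a)[::-1]

    def test_zero_length_interval_raises(self):
        class Stub:
            chrom, start, end, span = "chr1", 100, 100, 0
        with pytest.raises(ValueError):
            reciprocal_overlap(Stub(), sv(100, 200))


class TestIntersectCallers:
    def test_matching_pair_forms_consensus(self):
        out = intersect_callers([sv(100, 1100)], [sv(150, 1150, caller="B")])
        assert len(out) == 1 and out[0].trail["consensus"] is True

    def test_type_mismatch_blocks_consensus(self):
        out = intersect_callers([sv(100, 1100, "DEL")],
                                [sv(100, 1100, "DUP", caller="B")])
        assert out[0].trail["consensus"] is False

    def test_short_variants_excluded(self):
        out = intersect_callers([sv(100, 109)], [sv(100, 109, caller="B")])
        assert out == []  # length 10 is not "larger than 10 bp"

    def test_higher_overlap_pair_wins_contention(self):
        # two caller-A deletions both overlap one caller-B deletion; the
        # higher-reciprocal-overlap pair must be the one kept
        a1, a2 = sv(100, 1100), sv(500, 1500)
        b = sv(480, 1480, caller="B")
        out = intersect_callers([a1, a2], [b])
        by_start = {c.call_a.start: c for c in out}
        assert by_start[500].trail["consensus"] is True
        assert by_start[100].trail["consensus"] is False

    def test_pairing_is_maximal_and_valid(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            calls_a = [sv(int(s), int(s) + int(l))
                       for s, l in zip(rng.integers(0, 50_000, 5),
                                       rng.integers(200, 5000, 5))]
            calls_b = [sv(int(s), int(s) + int(l), caller="B")
                       for s, l in zip(rng.integers(0, 50_000, 5),
                                       rng.integers(200, 5000, 5))]
            out = intersect_callers(calls_a, calls_b)
            used_b = [c.call_b for c in out if c.call_b is not None]
            assert len(used_b) == len(set(id(b) for b in used_b))
            for c in out:
                if c.call_b is not None:
                    fa, fb = reciprocal_overlap(c.call_a, c.call_b)
                    assert min(fa, fb) >= 0.5
            # maximality: no unmatched A/B pair above threshold remains
            unmatched_a = [c.call_a for c in out if c.call_b is None]
            matched_b_ids = {id(b) for b in used_b}
            free_b = [b for b in calls_b if id(b) not in matched_b_ids]
            for a in unmatched_a:
                for b in free_b:
                    fa, fb = reciprocal_overlap(a, b)
                    assert min(fa, fb) < 0.5


class TestSubtractParental:
    def make_candidate(self, start=100, end=1100):
        out = intersect_callers([sv(start, end)],
                                [sv(start, end, caller="B")])
        return out

    @pytest.mark.parametrize("parental,removed", [
        ([sv(200, 1200, sample="dad")], True),            # RO 0.82
        ([], False),
        ([sv(5000, 6000, sample="dad")], False),          # distant locus
        ([sv(200, 1200, sample="dad", status="candidate")], True),
        ([sv(200, 1200, "DUP", sample="dad")], False),    # type mismatch
    ])
    def test_parental_matching(self, parental, removed):
        cands = subtract_parental(self.make_candidate(), parental)
        assert cands[0].trail["parental"] is (not removed)


class TestAnnotationExclusion:
    def tracks(self):
        return AnnotationTrackSet(
            blacklist=[GenomicInterval("chr1", 0, 1000, "bl")],
            repeats=[GenomicInterval("chr1", 5000, 5100, "rep")],
        )

    def test_mostly_blacklisted_removed(self):
        cands = intersect_callers([sv(50, 950)], [sv(50, 950, caller="B")])
        subtract_parental(cands, [])
        annotation_exclusion(cands, self.tracks())
        assert cands[0].trail["annotation"] is False

    def test_small_repeat_overlap_kept(self):
        cands = intersect_callers([sv(4900, 5900)], [sv(4900, 5900, caller="B")])
        subtract_parental(cands, [])
        annotation_exclusion(cands, self.tracks())
        assert cands[0].trail["annotation"] is True

    def test_zero_threshold_removes_any_overlap(self):
        cands = intersect_callers([sv(4900, 5900)], [sv(4900, 5900, caller="B")])
        subtract_parental(cands, [])
        annotation_exclusion(cands, self.tracks(), cover_threshold=0.0)
        assert cands[0].trail["annotation"] is False


class TestCoverageFilter:
    def coverage(self, child, father, mother):
        return CoverageSet({"child": {"chr1": child}, "father": {"chr1": father},
                            "mother": {"chr1": mother}}, bin_size=100)

    def candidate(self, start=2000, end=4000):
        cands = intersect_callers([sv(start, end)], [sv(start, end, caller="B")])
        return cands[0]

    def test_child_only_deletion_dip_passes(self):
        rng = np.random.default_rng(2)
        base = 30 + rng.normal(0, 1, 100)
        child = base.copy()
        child[20:40] *= 0.5
        cov = self.coverage(child, 30 + rng.normal(0, 1, 100),
                            30 + rng.normal(0, 1, 100))
        assert coverage_similarity_filter(self.candidate(), cov) is True

    def test_shared_pattern_fails(self):
        rng = np.random.default_rng(3)
        base = 30 + rng.normal(0, 1, 100)
        base[20:40] *= 0.6
        cov = self.coverage(base.copy(), base.copy(), 30 + rng.normal(0, 1, 100))
        assert coverage_similarity_filter(self.candidate(), cov) is False

    def test_constant_profiles_keep_candidate(self):
        flat = np.full(100, 30.0)
        cov = self.coverage(flat.copy(), flat.copy(), flat.copy())
        assert coverage_similarity_filter(self.candidate(), cov) is True


class TestPipeline:
    def test_planted_truth_recovered_with_attributable_removals(
            self, mini_cfg, mini_tracks, mini_sv):
        cands = run_sv_pipeline(mini_sv.child_callsets, mini_sv.parental_calls,
                                mini_tracks.trackset, mini_sv.coverage)
        outcomes = {}
        for t in mini_sv.truths:
            match = [c for c in cands
                     if c.call_a.chrom == t.chrom and c.call_a.start == t.start]
            assert match, f"no candidate for planted {t.sv_id}"
            outcomes[t.sv_id] = (t.expected_stage, match[0].first_failed,
                                 match[0].final)
        for sv_id, (expected, failed, final) in outcomes.items():
            assert failed == expected, sv_id
            assert final == (expected is None), sv_id

    def test_monotone_filtering(self, mini_cfg, mini_tracks, mini_sv):
        cands = run_sv_pipeline(mini_sv.child_callsets, mini_sv.parental_calls,
                                mini_tracks.trackset, mini_sv.coverage)
        caller_a_keys = {(c.chrom, c.start) for c in
                         mini_sv.child_callsets["callerA"]}
        consensus = {(c.call_a.chrom, c.call_a.start) for c in cands
                     if c.trail["consensus"]}
        final = {(c.call_a.chrom, c.call_a.start) for c in cands if c.final}
        assert final <= consensus <= caller_a_keys

    def test_empty_second_callset_yields_nothing_final(self, mini_tracks):
        cands = run_sv_pipeline({"A": [sv(100, 1100)], "B": []}, [],
                                mini_tracks.trackset, None)
        assert all(not c.final for c in cands)
        assert cands[0].first_failed == "consensus"

    def test_removals_name_exactly_one_first_failing_stage(
            self, mini_cfg, mini_tracks, mini_sv):
        cands = run_sv_pipeline(mini_sv.child_callsets, mini_sv.parental_calls,
                                mini_tracks.trackset, mini_sv.coverage)
        for c in cands:
            if not c.final:
                assert c.first_failed is not None
                stages = list(c.trail)
                # nothing evaluated after the first failure
                assert stages[-1] == c.first_failed


class TestExonEffect:
    def test_multi_exon_deletion_description(self):
        iv = GenomicInterval
        exons = [iv("chr1", 1000 + i * 1000, 1200 + i * 1000, "exon", "+")
                 for i in range(8)]
        tracks = AnnotationTrackSet(
            gene_features=exons,
            gene_spans=[iv("chr1", 1000, 8200, "RBM10", "+")],
        )
        deletion = sv(3000, 7300)
        assert describe_exon_effect(deletion, tracks) == \
            "deletion of exons 3-7 of RBM10"

    def test_minus_strand_numbering_reversed(self):
        iv = GenomicInterval
        exons = [iv("chr1", 1000 + i * 1000, 1200 + i * 1000, "exon", "-")
                 for i in range(5)]
        tracks = AnnotationTrackSet(
            gene_features=exons,
            gene_spans=[iv("chr1", 1000, 5200, "G", "-")],
        )
        assert describe_exon_effect(sv(1000, 1300), tracks) == \
            "deletion of exon 5 of G"

    def test_no_exon_overlap_returns_none(self):
        tracks = AnnotationTrackSet(
            gene_features=[GenomicInterval("chr1", 1000, 1200, "exon", "+")],
            gene_spans=[GenomicInterval("chr1", 1000, 2000, "G", "+")],
        )
        assert describe_exon_effect(sv(5000, 6000), tracks) is None
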