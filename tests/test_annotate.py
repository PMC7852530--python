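"""Gene-position classes, chromatin states, TFBS counts and the GC filter."""

import pandas as pd
import pytest

from triodnv.annotate import (
    AnnotationTrackSet,
    CdsModel,
    annotate_positions,
    chromatin_state,
    classify_gene_position,
    count_tfbs,
    gc_filter,
    is_nonsynonymous,
)
from triodnv.io_formats import GenomicInterval


@pytest.fixture()
def toy_tracks():
    """A hand-built single-gene landscape on a 3 kb chromosome.

    + strand gene: TSS 1000, UTR5 [1000,1100), exon [1100,1400),
    intron [1400,1700), exon [1700,2000), UTR3 [2000,2100).
    Promoter chromatin [500,1500), enhancer [2500,2600),
    DHS [900,1200), 12 stacked TFBS over [1050,1080).
    """
    iv = GenomicInterval
    seq = "A" * 3000
    # tile [0,100) all G, tile [100,200) exactly 75 GC, tile [200,300) 50 GC
    seq = ("G" * 100 + "G" * 75 + "A" * 25 + "GC" * 25 + "AT" * 25 + seq[300:])
    return AnnotationTrackSet(
        gene_features=[
            iv("chr1", 1000, 1100, "UTR5", "+"),
            iv("chr1", 1100, 1400, "exon", "+"),
            iv("chr1", 1400, 1700, "intron", "+"),
            iv("chr1", 1700, 2000, "exon", "+"),
            iv("chr1", 2000, 2100, "UTR3", "+"),
        ],
        tss=[iv("chr1", 1000, 1001, "G1", "+")],
        gene_spans=[iv("chr1", 1000, 2100, "G1", "+")],
        chromatin=[iv("chr1", 500, 1500, "Promoter"),
                   iv("chr1", 2500, 2600, "Enhancer")],
        dhs=[iv("chr1", 900, 1200, "DHS")],
        tfbs=[iv("chr1", 1050, 1080, f"TF{i}") for i in range(12)]
        + [iv("chr1", 1060, 1070, "TFx")],
        difficult_promoters=[iv("chr1", 2700, 2800, "difficult")],
        reference={"chr1": seq},
    )


class TestGeneClass:
    @pytest.mark.parametrize("pos,expected", [
        (1150, "exon"),
        (1050, "UTR5"),
        (2050, "UTR3"),
        (1500, "intron"),
        (500, "upstream"),      # 500 bp 5' of the TSS
        (999, "upstream"),
        (2150, "downstream"),
        (5000, "intergenic"),   # beyond the downstream window
    ])
    def test_positions_with_precedence(self, toy_tracks, pos, expected):
        assert classify_gene_position("chr1", pos, toy_tracks) == expected

    def test_minus_strand_upstream_is_right_of_tss(self):
        iv = GenomicInterval
        tracks = AnnotationTrackSet(
            gene_features=[iv("chr1", 500, 1000, "exon", "-")],
            tss=[iv("chr1", 999, 1000, "G", "-")],
            gene_spans=[iv("chr1", 500, 1000, "G", "-")],
        )
        assert classify_gene_position("chr1", 1500, tracks) == "upstream"
        assert classify_gene_position("chr1", 300, tracks) == "downstream"

    def test_unknown_chromosome_falls_back_to_intergenic(self, toy_tracks):
        assert classify_gene_position("chr9", 100, toy_tracks) == "intergenic"

    def test_classes_partition_a_cohort(self, mini_cfg, mini_tracks):
        from triodnv.synth import simulate_control_set
        df = simulate_control_set(mini_cfg, mini_tracks, size=2000)
        assert df["gene_class"].notna().all()
        assert len(df) == df["gene_class"].value_counts().sum()


class TestChromatinAndTfbs:
    def test_covering_interval_label(self, toy_tracks):
        assert chromatin_state("chr1", 700, toy_tracks) == "Promoter"
        assert chromatin_state("chr1", 2550, toy_tracks) == "Enhancer"
        assert chromatin_state("chr1", 2200, toy_tracks) == "Other"

    def test_half_open_boundaries(self, toy_tracks):
        assert chromatin_state("chr1", 500, toy_tracks) == "Promoter"
        assert chromatin_state("chr1", 1500, toy_tracks) == "Other"

    def test_stacked_site_counts(self, toy_tracks):
        assert count_tfbs("chr1", 1065, toy_tracks) == 13
        assert count_tfbs("chr1", 1055, toy_tracks) == 12
        assert count_tfbs("chr1", 2900, toy_tracks) == 0

    def test_empty_track_counts_zero(self):
        tracks = AnnotationTrackSet()
        assert count_tfbs("chr1", 100, tracks) == 0


class TestGcFilter:
    def test_pure_gc_window_excluded(self, toy_tracks):
        assert gc_filter("chr1", 50, toy_tracks) is True

    def test_exactly_75_percent_is_excluded(self, toy_tracks):
        assert gc_filter("chr1", 150, toy_tracks) is True

    def test_half_gc_window_kept(self, toy_tracks):
        assert gc_filter("chr1", 250, toy_tracks) is False

    def test_difficult_promoter_always_excluded(self, toy_tracks):
        assert gc_filter("chr1", 2750, toy_tracks) is True

    def test_position_beyond_sequence_end_raises(self, toy_tracks):
        with pytest.raises(ValueError):
            gc_filter("chr1", 5000, toy_tracks)

    def test_precomputed_windows_used_without_reference(self):
        tracks = AnnotationTrackSet(
            gc_windows=[GenomicInterval("chr1", 300, 400, "highGC")])
        assert gc_filter("chr1", 350, tracks) is True
        assert gc_filter("chr1", 450, tracks) is False


class TestNonsynonymous:
    @pytest.fixture()
    def cds_tracks(self):
        # + strand CDS "ATGAAA CTT TAA"-style: ATG AAA CCC TAG split over 2 exons
        seq = "T" * 100 + "ATGAAA" + "T" * 10 + "CCCTAG" + "T" * 100
        exons = [(100, 106), (116, 122)]
        return AnnotationTrackSet(
            cds={"G": CdsModel("G", "chr1", "+", exons)},
            reference={"chr1": seq},
        )

    def test_missense_and_synonymous_calls(self, cds_tracks):
        # codon 2 is AAA (Lys): AAA->AAG stays Lys, AAA->ACA becomes Thr
        assert is_nonsynonymous("chr1", 105, "A", "G", cds_tracks) is False
        assert is_nonsynonymous("chr1", 104, "A", "C", cds_tracks) is True

    def test_minus_strand_codon_orientation(self):
        # - strand gene: genomic "CTATTT CAT" reversed-complemented reads ATG AAA TAG
        seq = "G" * 100 + "CTATTTCAT" + "G" * 100
        tracks = AnnotationTrackSet(
            cds={"G": CdsModel("G", "chr1", "-", [(100, 109)])},
            reference={"chr1": seq},
        )
        # genomic T at 105 is codon-2 position; T->C changes AAA (Lys) -> GAA? no:
        # complement of C is G, cds codon AAA -> AGA (Arg): nonsynonymous
        assert is_nonsynonymous("chr1", 104, "T", "C", tracks) is True
        # third codon base wobble: genomic T at 103 -> C gives AAA -> AAG (Lys)
        assert is_nonsynonymous("chr1", 103, "T", "C", tracks) is False

    def test_returns_none_without_model(self, toy_tracks):
        toy_no_cds = toy_tracks
        assert is_nonsynonymous("chr1", 1150, "A", "T", toy_no_cds) is None


class TestCohortAnnotation:
    def test_matches_generator_ground_truth(self, mini_cfg, mini_tracks, mini_cohort):
        """Annotation recovers the feature memberships the generator planted."""
        truths = mini_cohort.ledger.dnvs
        df = pd.DataFrame([{"chrom": t.chrom, "pos": t.pos, "ref": t.ref,
                            "alt": t.alt} for t in truths])
        ann = annotate_positions(mini_tracks.trackset, df)
        for t, row in zip(truths, ann.itertuples(index=False)):
            assert (row.chromatin == "Promoter") == t.features["promoter"], t
            assert bool(row.dhs) == t.features["dhs"], t
            assert (row.tfbs_count >= 10) == t.features["tfbs"], t
            assert bool(row.gc_excluded) == t.features["gc_excluded"], t

    def test_annotation_is_order_independent(self, mini_cfg, mini_tracks):
        from triodnv.synth import simulate_control_set
        df = simulate_control_set(mini_cfg, mini_tracks, size=500)
        base = df[["chrom", "pos", "ref", "alt"]]
        shuffled = base.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = annotate_positions(mini_tracks.trackset, base)
        b = annotate_positions(mini_tracks.trackset, shuffled)
        merged = a.merge(b, on=["chrom", "pos"], suffixes=("_a", "_b"))
        assert (merged["gene_class_a"] == merged["gene_class_b"]).all()
        assert (merged["tfbs_count_a"] == merged["tfbs_count_b"]).all()

    def test_gc_tiling_is_stable(self, toy_tracks):
        # the same variant always maps to the same 100 bp tile
        assert all(gc_filter("chr1", p, toy_tracks) for p in range(100, 200))
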