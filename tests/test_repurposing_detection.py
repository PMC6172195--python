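import math

import pytest

from regswitch.config import PipelineConfig
from regswitch.element_annotation import RegulatoryElement
from regswitch.genome_io import GenomicInterval, OrthologyMap, TranscriptModel
from regswitch.repurposing_detection import (
    classify_pe_elements,
    detect_pe_elements,
    filter_truncated_isoform_artifacts,
    pe_vs_inactive_enrichment,
)

from conftest import detected_site_keys, planted_site_keys


def identity_maps(length=1_000_000):
    ab = OrthologyMap(
        "A", "B",
        [(GenomicInterval("A1", 0, length), GenomicInterval("B1", 0, length), "+")],
    )
    ba = OrthologyMap(
        "B", "A",
        [(GenomicInterval("B1", 0, length), GenomicInterval("A1", 0, length), "+")],
    )
    return ab, ba


def enhancer(start, end, chrom="A1"):
    return RegulatoryElement(
        GenomicInterval(chrom, start, end), "enhancer",
        element_id=f"enh:{chrom}:{start}-{end}",
    )


def b_transcript(tid, tss, strand="+", length=3000, chrom="B1", stable=True):
    fpkm = {("liver", "r1"): 8.0 if stable else 0.2}
    if strand == "+":
        exons = [GenomicInterval(chrom, tss, tss + length, strand)]
    else:
        exons = [GenomicInterval(chrom, tss - length, tss, strand)]
    return TranscriptModel(tid, f"g_{tid}", exons, fpkm)


class TestDetection:
    def test_single_base_window_overlap_detected(self):
        ab, ba = identity_maps()
        # projection [5000,6000); window upstream of TSS 6499 is [5999,6499)
        pe = detect_pe_elements(
            [enhancer(5000, 6000)], ab, ba, [b_transcript("t", 6499)]
        )
        assert len(pe) == 1 and pe[0].b_transcript_id == "t"

    def test_body_only_overlap_not_detected(self):
        ab, ba = identity_maps()
        # TSS at 4000: window [3500,4000) is upstream of the projection
        pe = detect_pe_elements(
            [enhancer(5000, 6000)], ab, ba, [b_transcript("t", 4000)]
        )
        assert pe == []

    def test_nearest_tss_wins_on_multiple_windows(self):
        ab, ba = identity_maps()
        # projection midpoint 5500; both windows overlap the projection
        near = b_transcript("near", 5600)
        far = b_transcript("far", 6400)
        pe = detect_pe_elements([enhancer(5000, 6000)], ab, ba, [far, near])
        assert pe[0].b_transcript_id == "near"

    def test_unmapped_enhancer_skipped(self):
        ab, ba = identity_maps()
        pe = detect_pe_elements(
            [enhancer(5000, 6000, chrom="A9")], ab, ba, [b_transcript("t", 6400)]
        )
        assert pe == []

    def test_noise_free_synthetic_recovery(self, default_result):
        truth_keys = planted_site_keys(default_result.dataset.truth)
        detected = detected_site_keys(default_result)
        assert detected == truth_keys  # sensitivity and precision both 1.0


class TestIsoformFilter:
    def _pe(self, tid, tx_list):
        ab, ba = identity_maps()
        return detect_pe_elements(
            [enhancer(5000, 6000)], ab, ba,
            [t for t in tx_list if t.transcript_id == tid],
        )

    def test_downstream_isoform_of_upstream_promoter_removed(self):
        short = b_transcript("short", 6400)
        long = TranscriptModel(
            "long", "g_short",
            [GenomicInterval("B1", 5400, 9400, "+")],
            {("liver", "r1"): 5.0},
        )
        pe = self._pe("short", [short, long])
        kept = filter_truncated_isoform_artifacts(pe, [short, long], {"short", "long"})
        assert kept == []

    def test_single_isoform_locus_retained(self):
        tx = b_transcript("only", 6400)
        pe = self._pe("only", [tx])
        assert filter_truncated_isoform_artifacts(pe, [tx], {"only"}) == pe

    def test_unstable_upstream_isoform_does_not_remove(self):
        short = b_transcript("short", 6400)
        long = TranscriptModel(
            "long", "g_short",
            [GenomicInterval("B1", 5400, 9400, "+")],
            {("liver", "r1"): 0.2},
        )
        pe = self._pe("short", [short, long])
        kept = filter_truncated_isoform_artifacts(pe, [short, long], {"short"})
        assert kept == pe

    def test_filter_never_increases_count(self, default_result):
        ds = default_result.dataset
        from regswitch.pipeline import annotate_species  # noqa: F401
        # the filtered pipeline set can only be a subset of the unfiltered one
        assert len(default_result.pe_elements) <= len(ds.truth.planted_pe) + len(
            [d for d in ds.truth.decoys if d[3] == "truncated_isoform"]
        )


class TestClassification:
    def test_overlap_with_a_transcript_is_extended(self):
        ab, ba = identity_maps()
        btx = b_transcript("t", 6499)
        pe = detect_pe_elements([enhancer(5000, 6000)], ab, ba, [btx])
        a_tx = TranscriptModel(
            "a", "ga", [GenomicInterval("A1", 7000, 9000, "+")], {}
        )
        out = classify_pe_elements(pe, ba, [a_tx], [btx])
        assert out[0].category == "extended"

    def test_intergenic_projection_is_novel(self):
        ab, ba = identity_maps()
        btx = b_transcript("t", 6499)
        pe = detect_pe_elements([enhancer(5000, 6000)], ab, ba, [btx])
        a_tx = TranscriptModel(
            "a", "ga", [GenomicInterval("A1", 50_000, 60_000, "+")], {}
        )
        out = classify_pe_elements(pe, ba, [a_tx], [btx])
        assert out[0].category == "novel"

    def test_unprojectable_transcript_is_novel(self):
        ab, ba = identity_maps()
        btx = b_transcript("t", 6499)
        pe = detect_pe_elements([enhancer(5000, 6000)], ab, ba, [btx])
        empty_ba = OrthologyMap("B", "A", [])
        out = classify_pe_elements(pe, empty_ba, [], [btx])
        assert out[0].category == "novel"

    def test_categories_partition_synthetic_output(self, default_result):
        truth = {
            (p.a_chrom, p.a_start, p.a_end): p.category
            for p in default_result.dataset.truth.planted_pe
        }
        for elem in default_result.pe_elements:
            key = (
                elem.a_enhancer.interval.seq_name,
                elem.a_enhancer.interval.start,
                elem.a_enhancer.interval.end,
            )
            assert elem.category == truth[key]


class TestEnrichment:
    def test_printed_counts_reproduce_fold_difference(self):
        res = pe_vs_inactive_enrichment(184, 97_405, 79, 181_688)
        assert res.rate_ratio == pytest.approx(4.34, abs=0.01)
        assert res.rate_ratio > 4.03
        assert res.p_value < 1e-9

    def test_symmetric_counts(self):
        res = pe_vs_inactive_enrichment(10, 1000, 10, 1000)
        assert res.rate_ratio == 1.0 and res.p_value == 1.0

    def test_zero_numerator(self):
        res = pe_vs_inactive_enrichment(0, 1000, 5, 1000)
        assert res.rate_ratio == 0.0
        assert 0 < res.p_value <= 1

    def test_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            pe_vs_inactive_enrichment(1, 0, 1, 100)

    def test_gc_matched_control_keeps_enrichment_sign(self, default_result):
        """With matched GC distributions the planted enrichment direction
        is unchanged."""
        from regswitch.element_annotation import gc_matched_subsample
        from regswitch.config import AnnotationConfig
        from regswitch.repurposing_detection import count_promoter_orthologous

        res = default_result
        cfg = res.config
        ds = res.dataset
        ann_cfg = AnnotationConfig(gc_match_threshold=0.46, gc_match_max_n=30_000)
        me, mi = gc_matched_subsample(
            res.annotations["A"].enhancers, res.annotations["A"].inactive, ann_cfg, 0
        )
        map_ab, map_ba = ds.maps[("A", "B")], ds.maps[("B", "A")]
        stable_b = res.annotations["B"].stable_transcripts
        e_hit, e_tested = count_promoter_orthologous(
            [e.interval for e in me], map_ab, map_ba, stable_b, cfg
        )
        i_hit, i_tested = count_promoter_orthologous(
            [e.interval for e in mi], map_ab, map_ba, stable_b, cfg
        )
        matched = pe_vs_inactive_enrichment(e_hit, e_tested, max(i_hit, 0), i_tested)
        assert matched.rate_ratio > 1 or math.isinf(matched.rate_ratio)
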