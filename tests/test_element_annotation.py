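import numpy as np
import pytest

from regswitch.config import AnnotationConfig
from regswitch.element_annotation import (
    RegulatoryElement,
    call_enhancers,
    call_stable_transcripts,
    define_promoters,
    gc_matched_subsample,
    harmonize_peak_replicates,
    sample_inactive_regions,
)
from regswitch.genome_io import GenomicInterval, PeakCall, TranscriptModel


def peak(start, end, score, summit=None, chrom="chr1"):
    return PeakCall(GenomicInterval(chrom, start, end), score, summit)


def transcript(tid, exon_coords, strand="+", fpkm=None, chrom="chr1"):
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_coords]
    return TranscriptModel(tid, f"g_{tid}", exons, fpkm or {})


class TestHarmonize:
    def test_three_of_three_consensus_centered_on_summit(self):
        reps = [[peak(5000, 6000, 90 + i, summit=499)] for i in range(3)]
        (cons,) = harmonize_peak_replicates(reps, top_n=10)
        assert (cons.start, cons.end) == (4999, 5999)

    def test_one_of_three_dropped(self):
        reps = [[peak(5000, 6000, 90)], [], []]
        assert harmonize_peak_replicates(reps, top_n=10) == []

    def test_top_n_ranking(self):
        reps = [
            [peak(0, 1000, 10), peak(5000, 6000, 7), peak(9000, 10_000, 3)]
            for _ in range(3)
        ]
        out = harmonize_peak_replicates(reps, top_n=1)
        assert len(out) == 1 and out[0].start == 0

    def test_two_replicates_require_both(self):
        reps = [[peak(0, 1000, 10)], [peak(500, 1500, 8)]]
        assert len(harmonize_peak_replicates(reps, top_n=10)) == 1
        reps = [[peak(0, 1000, 10)], [peak(5000, 6000, 8)]]
        assert harmonize_peak_replicates(reps, top_n=10) == []

    def test_single_merged_sample_kept_as_is(self):
        out = harmonize_peak_replicates([[peak(100, 700, 5, summit=300)]], top_n=10)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (0, 1000)  # clipped at contig start

    def test_clipping_at_contig_bounds(self):
        out = harmonize_peak_replicates(
            [[peak(0, 400, 5)] for _ in range(3)],
            top_n=10,
            contig_lengths={"chr1": 600},
        )
        assert (out[0].start, out[0].end) == (0, 600)


class TestStableTranscripts:
    def _tx(self, fpkms, span_end):
        fpkm = {("liver", f"r{i}"): v for i, v in enumerate(fpkms)}
        return transcript("t", [(0, span_end)], fpkm=fpkm)

    def test_mean_above_threshold_retained(self):
        out = call_stable_transcripts([self._tx((1.5, 0.9), 1500)], "liver")
        assert len(out) == 1

    def test_mean_exactly_one_excluded(self):
        assert call_stable_transcripts([self._tx((1.0, 1.0), 1500)], "liver") == []

    def test_span_exactly_1000_excluded(self):
        assert call_stable_transcripts([self._tx((5.0,), 1000)], "liver") == []

    def test_absent_organ_warns(self):
        with pytest.warns(UserWarning):
            out = call_stable_transcripts([self._tx((5.0,), 1500)], "kidney")
        assert out == []


class TestPromoters:
    def test_plus_strand_window(self):
        (el,) = define_promoters([transcript("t", [(10_000, 12_000)])])
        assert (el.interval.start, el.interval.end) == (9000, 10_000)

    def test_minus_strand_window(self):
        (el,) = define_promoters([transcript("t", [(18_000, 20_000)], strand="-")])
        assert (el.interval.start, el.interval.end) == (20_000, 21_000)

    def test_clipped_at_contig_start(self):
        (el,) = define_promoters([transcript("t", [(300, 2000)])])
        assert (el.interval.start, el.interval.end) == (0, 300)

    def test_shared_tss_isoforms_merged(self):
        txs = [
            transcript("t1", [(10_000, 12_000)]),
            transcript("t2", [(10_000, 13_000)]),
        ]
        out = define_promoters(txs, organs_by_transcript={"t1": {"liver"}, "t2": {"brain"}})
        assert len(out) == 1
        assert out[0].organs_active == {"liver", "brain"}


class TestEnhancers:
    def _call(self, dhs, k27ac=(), k4me1=(), k4me3=(), txs=(), cage=()):
        return call_enhancers(list(dhs), list(k27ac), list(k4me1), list(k4me3), list(txs), list(cage))

    def test_rule_conjunction(self):
        dhs = [GenomicInterval("c", 5000, 6000)]
        k27 = [GenomicInterval("c", 5500, 6500)]
        k4me3 = [GenomicInterval("c", 11_000, 12_000)]  # 5 kb away
        out = self._call(dhs, k27ac=k27, k4me3=k4me3)
        assert len(out) == 1 and out[0].provenance == "chromatin"

    def test_dhs_without_active_mark_excluded(self):
        assert self._call([GenomicInterval("c", 5000, 6000)]) == []

    def test_k4me3_gap_999_excluded_1000_kept(self):
        dhs = [GenomicInterval("c", 5000, 6000)]
        k27 = [GenomicInterval("c", 5000, 6000)]
        near = [GenomicInterval("c", 6999, 7999)]   # gap 999
        far = [GenomicInterval("c", 7000, 8000)]    # gap 1000
        assert self._call(dhs, k27ac=k27, k4me3=near) == []
        assert len(self._call(dhs, k27ac=k27, k4me3=far)) == 1

    def test_unstable_transcript_exon_overlap_excluded(self):
        dhs = [GenomicInterval("c", 5000, 6000)]
        k27 = [GenomicInterval("c", 5000, 6000)]
        unstable = transcript("u", [(5800, 7000)], fpkm={("liver", "r1"): 0.1}, chrom="c")
        assert self._call(dhs, k27ac=k27, txs=[unstable]) == []

    def test_tss_upstream_window_overlap_excluded(self):
        dhs = [GenomicInterval("c", 5000, 6000)]
        k27 = [GenomicInterval("c", 5000, 6000)]
        tx = transcript("t", [(6500, 8000)], chrom="c")  # upstream window [5500,6500)
        assert self._call(dhs, k27ac=k27, txs=[tx]) == []

    def test_cage_enhancers_appended_with_provenance(self):
        cage = [GenomicInterval("c", 9000, 10_000)]
        out = self._call([], cage=cage)
        assert len(out) == 1 and out[0].provenance == "CAGE"

    def test_order_invariance(self):
        dhs = [GenomicInterval("c", s, s + 1000) for s in (5000, 25_000, 45_000)]
        k27 = [GenomicInterval("c", s + 100, s + 1100) for s in (5000, 25_000, 45_000)]
        fwd = self._call(dhs, k27ac=k27)
        rev = self._call(list(reversed(dhs)), k27ac=list(reversed(k27)))
        assert [e.interval for e in fwd] == [e.interval for e in rev]


class TestInactiveSampling:
    def _config(self, target=20):
        return AnnotationConfig(inactive_target=target)

    def test_fully_masked_genome_yields_nothing(self):
        with pytest.warns(UserWarning):
            out = sample_inactive_regions(
                {"c": 10_000},
                [],
                masks=[GenomicInterval("c", 0, 10_000)],
                config=self._config(),
                seed=0,
            )
        assert out == []

    def test_exclusion_distance_respected(self):
        out = sample_inactive_regions(
            {"c": 10_000},
            [GenomicInterval("c", 4000, 5000)],
            config=self._config(),
            seed=0,
        )
        for el in out:
            assert el.interval.end <= 3000 or el.interval.start >= 6000

    def test_non_overlapping_and_deterministic(self):
        args = ({"c": 100_000}, [], (), self._config(50), 42)
        a = sample_inactive_regions(*args)
        b = sample_inactive_regions(*args)
        assert [e.interval for e in a] == [e.interval for e in b]
        ivs = sorted((e.interval.start, e.interval.end) for e in a)
        assert all(x[1] <= y[0] for x, y in zip(ivs, ivs[1:]))


class TestGCMatching:
    def _elem(self, eid, gc, cls="enhancer"):
        iv = GenomicInterval("c", 1000 * (abs(hash(eid)) % 1000), 1000 * (abs(hash(eid)) % 1000) + 1000)
        el = RegulatoryElement(iv, cls, element_id=eid)
        el.gc = gc
        return el

    def test_nearest_match(self):
        enh = [self._elem("e", 0.40)]
        inact = [self._elem("i1", 0.39, "inactive"), self._elem("i2", 0.45, "inactive")]
        _, matched = gc_matched_subsample(enh, inact)
        assert matched[0].gc == 0.39

    def test_threshold_excludes_high_gc_enhancers(self):
        enh = [self._elem("e", 0.47)]
        inact = [self._elem("i", 0.40, "inactive"), self._elem("i2", 0.41, "inactive")]
        me, mi = gc_matched_subsample(enh, inact, AnnotationConfig(gc_match_threshold=0.46))
        assert me == [] and mi == []

    def test_equidistant_tie_goes_to_lower_gc(self):
        enh = [self._elem("e", 0.40)]
        inact = [self._elem("lo", 0.38, "inactive"), self._elem("hi", 0.42, "inactive")]
        _, matched = gc_matched_subsample(enh, inact)
        assert matched[0].gc == 0.38

    def test_pool_too_small_rejected(self):
        enh = [self._elem(f"e{i}", 0.40) for i in range(3)]
        inact = [self._elem("i", 0.40, "inactive")]
        with pytest.raises(ValueError):
            gc_matched_subsample(enh, inact)

    def test_matched_distributions_similar(self):
        from regswitch.stat_tests import mann_whitney_u

        rng = np.random.default_rng(9)
        enh = [self._elem(f"e{i}", g) for i, g in enumerate(rng.normal(0.40, 0.02, 80))]
        inact = [
            self._elem(f"i{i}", g, "inactive")
            for i, g in enumerate(rng.normal(0.41, 0.03, 400))
        ]
        me, mi = gc_matched_subsample(enh, inact, AnnotationConfig(gc_match_threshold=0.46))
        res = mann_whitney_u([e.gc for e in me], [i.gc for i in mi])
        assert res.p_value > 0.05


class TestClassDisjointness:
    def test_classes_disjoint_on_pipeline_output(self, default_result):
        for ann in default_result.annotations.values():
            enh = {(e.interval.seq_name, e.interval.start) for e in ann.enhancers}
            prom = {(e.interval.seq_name, e.interval.start) for e in ann.promoters}
            inact = {(e.interval.seq_name, e.interval.start) for e in ann.inactive}
            assert not (enh & inact) and not (enh & prom) and not (prom & inact)
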