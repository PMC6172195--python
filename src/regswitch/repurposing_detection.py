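"""Detection and classification of P/E elements.

A P/E element is an enhancer in species A whose reciprocal ortholog in
the sister species B overlaps the 500-nt window upstream of a stable
transcript's TSS — i.e. a locus with enhancer signatures on one side and
promoter activity on the other.  Candidates explained by 5'-truncated
isoforms of loci with an alternative upstream promoter are removed, and
the survivors are split into *novel* (species-specific transcribed locus)
and *extended* (new 5' isoform of a shared locus) categories.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .config import PipelineConfig
from .element_annotation import RegulatoryElement, upstream_window
from .genome_io import GenomicInterval, OrthologyMap, TranscriptModel
from .orthology_mapping import project_interval, reciprocal_ortholog
from .stat_tests import fisher_exact_2x2

__all__ = [
    "PEElement",
    "EnrichmentResult",
    "detect_pe_elements",
    "count_promoter_orthologous",
    "filter_truncated_isoform_artifacts",
    "classify_pe_elements",
    "pe_vs_inactive_enrichment",
]


@dataclass(frozen=True)
class PEElement:
    a_enhancer: RegulatoryElement
    b_interval: GenomicInterval
    b_transcript_id: str
    category: str | None = None  # novel | extended, set by classify
    organs_active_b: frozenset[str] = frozenset()


@dataclass(frozen=True)
class EnrichmentResult:
    pe_count: int
    enh_tested: int
    ctrl_count: int
    ctrl_tested: int
    rate_ratio: float
    p_value: float


def _promoter_windows(
    transcripts: list[TranscriptModel], window: int
) -> list[tuple[GenomicInterval, TranscriptModel]]:
    out = []
    for tx in transcripts:
        w = upstream_window(tx.tss, tx.strand, window, tx.seq_name)
        if w is not None:
            out.append((w, tx))
    return out


def detect_pe_elements(
    a_enhancers: list[RegulatoryElement],
    map_ab: OrthologyMap,
    map_ba: OrthologyMap,
    b_stable_transcripts: list[TranscriptModel],
    config: PipelineConfig | None = None,
    organs_by_transcript: dict[str, set[str]] | None = None,
) -> list[PEElement]:
    """One P/E element per enhancer whose B ortholog hits a stable
    TSS-upstream window.

    When the projection overlaps windows of several transcripts with
    distinct TSSs, the transcript whose TSS is nearest the projection
    midpoint wins (ties to the smallest TSS coordinate).
    """
    config = config or PipelineConfig()
    windows = _promoter_windows(
        b_stable_transcripts, config.annotation.pe_overlap_window
    )
    out = []
    for enh in a_enhancers:
        target = reciprocal_ortholog(
            enh.interval, map_ab, map_ba, config.min_match_sister
        )
        if target is None:
            continue
        hits = [(w, tx) for w, tx in windows if w.overlaps(target)]
        if not hits:
            continue
        mid = (target.start + target.end) // 2
        _w, tx = min(hits, key=lambda wt: (abs(wt[1].tss - mid), wt[1].tss))
        organs = (
            frozenset(organs_by_transcript.get(tx.transcript_id, set()))
            if organs_by_transcript
            else frozenset()
        )
        out.append(PEElement(enh, target, tx.transcript_id, None, organs))
    return out


def count_promoter_orthologous(
    intervals: list[GenomicInterval],
    map_ab: OrthologyMap,
    map_ba: OrthologyMap,
    b_stable_transcripts: list[TranscriptModel],
    config: PipelineConfig | None = None,
) -> tuple[int, int]:
    """Control-path counterpart of detection for arbitrary intervals
    (e.g. inactive regions): returns ``(n_promoter_orthologous,
    n_with_ortholog_tested)``."""
    config = config or PipelineConfig()
    windows = _promoter_windows(
        b_stable_transcripts, config.annotation.pe_overlap_window
    )
    tested = hit = 0
    for iv in intervals:
        target = reciprocal_ortholog(iv, map_ab, map_ba, config.min_match_sister)
        if target is None:
            continue
        tested += 1
        if any(w.overlaps(target) for w, _tx in windows):
            hit += 1
    return hit, tested


def group_transcripts_into_loci(
    transcripts: list[TranscriptModel],
) -> dict[str, int]:
    """transcript_id → locus index; loci are connected components of
    same-strand exonic overlap (≥1 bp)."""
    order = sorted(
        range(len(transcripts)),
        key=lambda i: (transcripts[i].seq_name, transcripts[i].span.start),
    )
    parent = list(range(len(transcripts)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    def exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
        if a.seq_name != b.seq_name or a.strand != b.strand:
            return False
        return any(ea.overlaps(eb) for ea in a.exons for eb in b.exons)

    active: list[int] = []
    current_chrom: str | None = None
    for i in order:
        tx = transcripts[i]
        if tx.seq_name != current_chrom:
            active = []
            current_chrom = tx.seq_name
        active = [j for j in active if transcripts[j].span.end > tx.span.start]
        for j in active:
            if exonic_overlap(tx, transcripts[j]):
                union(i, j)
        active.append(i)
    return {transcripts[i].transcript_id: find(i) for i in range(len(transcripts))}


def filter_truncated_isoform_artifacts(
    pe: list[PEElement],
    b_transcripts_all: list[TranscriptModel],
    b_stable_ids: set[str] | None = None,
) -> list[PEElement]:
    """Drop P/E elements attached to shorter isoforms of transcribed loci
    that have an alternative, upstream promoter.

    Only *stable* isoforms define alternative promoters; the upstream
    relation is strand-aware (smaller TSS coordinate on +, larger on −).
    """
    if b_stable_ids is None:
        b_stable_ids = {tx.transcript_id for tx in b_transcripts_all}
    locus_of = group_transcripts_into_loci(b_transcripts_all)
    by_id = {tx.transcript_id: tx for tx in b_transcripts_all}
    out = []
    for elem in pe:
        tx = by_id.get(elem.b_transcript_id)
        if tx is None:
            out.append(elem)
            continue
        locus = locus_of[tx.transcript_id]
        has_upstream = False
        for other in b_transcripts_all:
            if (
                other.transcript_id == tx.transcript_id
                or locus_of[other.transcript_id] != locus
                or other.transcript_id not in b_stable_ids
            ):
                continue
            if (tx.strand == "+" and other.tss < tx.tss) or (
                tx.strand == "-" and other.tss > tx.tss
            ):
                has_upstream = True
                break
        if not has_upstream:
            out.append(elem)
    return out


def classify_pe_elements(
    pe: list[PEElement],
    map_ba: OrthologyMap,
    a_transcripts_all: list[TranscriptModel],
    b_transcripts: list[TranscriptModel],
    min_match: float = 0.6,
) -> list[PEElement]:
    """Set novel/extended categories.

    The B transcript's exonic span is projected back to A; overlap (≥1 bp,
    strand-ignored) with any A transcript span means *extended*, otherwise
    (including unprojectable spans) *novel*.
    """
    by_id = {tx.transcript_id: tx for tx in b_transcripts}
    a_spans = [tx.span for tx in a_transcripts_all]
    out = []
    for elem in pe:
        tx = by_id[elem.b_transcript_id]
        proj = project_interval(tx.span, map_ba, min_match)
        category = "novel"
        if proj.target is not None and any(
            proj.target.overlaps(span) for span in a_spans
        ):
            category = "extended"
        out.append(replace(elem, category=category))
    return out


def pe_vs_inactive_enrichment(
    pe_count: int, enh_tested: int, ctrl_count: int, ctrl_tested: int
) -> EnrichmentResult:
    """Fold-enrichment of promoter-orthologous enhancers over inactive
    controls, with a two-sided Fisher's exact test."""
    if enh_tested <= 0 or ctrl_tested <= 0:
        raise ValueError("tested totals must be positive")
    result, _odds = fisher_exact_2x2(
        [[pe_count, enh_tested - pe_count], [ctrl_count, ctrl_tested - ctrl_count]]
    )
    if ctrl_count > 0:
        rate_ratio = (pe_count / enh_tested) / (ctrl_count / ctrl_tested)
    else:
        rate_ratio = float("inf") if pe_count else float("nan")
    return EnrichmentResult(
        pe_count, enh_tested, ctrl_count, ctrl_tested, rate_ratio, result.p_value
    )
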