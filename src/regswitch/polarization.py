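"""Outgroup polarization of P/E elements and turnover contingency tables.

The direction of a repurposing event (enhancer→promoter vs
promoter→enhancer) is inferred from an outgroup species O: the O ortholog
of each P/E element is classified as promoter (overlapping the upstream
window of a stable transcript), enhancer (overlapping a qualifying
H3K27ac peak), or none — promoter evidence takes precedence.  Ancestral
element sets (reference elements whose O ortholog retains the same
activity) are then tabulated into a 2×2 of repurposing vs loss, tested
with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import PipelineConfig
from .element_annotation import (
    IntervalIndex,
    RegulatoryElement,
    upstream_window,
)
from .genome_io import GenomicInterval, OrthologyMap, TranscriptModel
from .orthology_mapping import project_interval, reciprocal_ortholog
from .stat_tests import fisher_exact_2x2

__all__ = [
    "OutgroupState",
    "TurnoverTable",
    "SpeciesAnnotations",
    "assign_outgroup_state",
    "define_ancestral_elements",
    "tabulate_turnover",
    "repurposing_bias_test",
]


@dataclass(frozen=True)
class OutgroupState:
    element_id: str
    state: str  # enhancer | promoter | none

    def __post_init__(self) -> None:
        if self.state not in ("enhancer", "promoter", "none"):
            raise ValueError(f"bad outgroup state {self.state!r}")


@dataclass(frozen=True)
class TurnoverTable:
    """rows: (ancestral enhancer, ancestral promoter) × columns:
    (repurposed, lost); totals include conserved elements."""

    enh_repurposed: int
    enh_lost: int
    prom_repurposed: int
    prom_lost: int
    enh_total: int
    prom_total: int

    def __post_init__(self) -> None:
        if min(
            self.enh_repurposed, self.enh_lost, self.prom_repurposed,
            self.prom_lost, self.enh_total, self.prom_total,
        ) < 0:
            raise ValueError("negative count")
        if self.enh_repurposed + self.enh_lost > self.enh_total:
            raise ValueError("enhancer row exceeds its total")
        if self.prom_repurposed + self.prom_lost > self.prom_total:
            raise ValueError("promoter row exceeds its total")

    @property
    def counts(self) -> list[list[int]]:
        return [
            [self.enh_repurposed, self.enh_lost],
            [self.prom_repurposed, self.prom_lost],
        ]


@dataclass
class SpeciesAnnotations:
    """Everything polarization needs to know about one species."""

    k27ac: list[GenomicInterval]
    k4me3: list[GenomicInterval]
    transcripts_all: list[TranscriptModel]
    stable_transcripts: list[TranscriptModel]
    contig_lengths: dict[str, int] | None = None


def _promoter_index(
    annotations: SpeciesAnnotations, window: int
) -> IntervalIndex:
    ivs = []
    for tx in annotations.stable_transcripts:
        limit = (
            annotations.contig_lengths.get(tx.seq_name)
            if annotations.contig_lengths
            else None
        )
        w = upstream_window(tx.tss, tx.strand, window, tx.seq_name, limit)
        if w is not None:
            ivs.append(w)
    return IntervalIndex(ivs)


def _qualifying_enhancer_peaks(
    annotations: SpeciesAnnotations, promoter_window: int
) -> IntervalIndex:
    """H3K27ac peaks that qualify as enhancer evidence: not overlapping
    any H3K4me3 peak, any transcript's upstream window, or any exon."""
    k4me3 = IntervalIndex(annotations.k4me3)
    excl: list[GenomicInterval] = []
    for tx in annotations.transcripts_all:
        excl.extend(tx.exons)
        limit = (
            annotations.contig_lengths.get(tx.seq_name)
            if annotations.contig_lengths
            else None
        )
        w = upstream_window(tx.tss, tx.strand, promoter_window, tx.seq_name, limit)
        if w is not None:
            excl.append(w)
    tx_idx = IntervalIndex(excl)
    keep = [
        p
        for p in annotations.k27ac
        if not k4me3.overlaps(p) and not tx_idx.overlaps(p)
    ]
    return IntervalIndex(keep)


def assign_outgroup_state(
    ortholog: GenomicInterval,
    annotations: SpeciesAnnotations,
    config: PipelineConfig | None = None,
    element_id: str = "",
) -> OutgroupState:
    """Classify a projected interval in the outgroup.

    Promoter (overlap with the 1000-nt upstream window of a stable
    transcript) takes precedence over enhancer (overlap with a qualifying
    H3K27ac peak); anything else is none.
    """
    config = config or PipelineConfig()
    window = config.annotation.promoter_window
    if _promoter_index(annotations, window).overlaps(ortholog):
        return OutgroupState(element_id, "promoter")
    if _qualifying_enhancer_peaks(annotations, window).overlaps(ortholog):
        return OutgroupState(element_id, "enhancer")
    return OutgroupState(element_id, "none")


def _conserved_as_promoter(
    target: GenomicInterval,
    annotations: SpeciesAnnotations,
    assoc_window: int,
) -> bool:
    return _promoter_index(annotations, assoc_window).overlaps(target)


def define_ancestral_elements(
    ref_promoters: list[RegulatoryElement],
    ref_enhancers: list[RegulatoryElement],
    map_to_sister: OrthologyMap,
    map_from_sister: OrthologyMap,
    map_to_outgroup: OrthologyMap,
    outgroup: SpeciesAnnotations,
    config: PipelineConfig | None = None,
) -> tuple[list[RegulatoryElement], list[RegulatoryElement]]:
    """Reference elements whose activity is ancestral.

    An element must align to both other clade species (reciprocal
    projection for the sister leg, single-direction projection with the
    outgroup min-match for the outgroup leg).  Ancestral promoters
    associate with a stable outgroup transcript (upstream 500-nt window);
    ancestral enhancers overlap a qualifying outgroup H3K27ac peak and
    carry no promoter or H3K4me3 association there.
    """
    config = config or PipelineConfig()
    prom_idx = _promoter_index(outgroup, config.annotation.promoter_window)
    assoc_idx = _promoter_index(outgroup, config.ancestral_assoc_window)
    enh_idx = _qualifying_enhancer_peaks(outgroup, config.annotation.promoter_window)
    k4me3_idx = IntervalIndex(outgroup.k4me3)

    def aligned(iv: GenomicInterval) -> GenomicInterval | None:
        if (
            reciprocal_ortholog(
                iv, map_to_sister, map_from_sister, config.min_match_sister
            )
            is None
        ):
            return None
        return project_interval(iv, map_to_outgroup, config.min_match_outgroup).target

    anc_promoters = []
    for el in ref_promoters:
        og = aligned(el.interval)
        if og is not None and assoc_idx.overlaps(og):
            anc_promoters.append(el)
    anc_enhancers = []
    for el in ref_enhancers:
        og = aligned(el.interval)
        if og is None:
            continue
        if enh_idx.overlaps(og) and not prom_idx.overlaps(og) and not k4me3_idx.overlaps(og):
            anc_enhancers.append(el)
    return anc_enhancers, anc_promoters


def tabulate_turnover(
    ancestral_enhancers: list[RegulatoryElement],
    ancestral_promoters: list[RegulatoryElement],
    map_to_sister: OrthologyMap,
    map_from_sister: OrthologyMap,
    sister: SpeciesAnnotations,
    pe_element_ids: set[str],
    config: PipelineConfig | None = None,
) -> TurnoverTable:
    """2×2 turnover counts for ancestral elements.

    Repurposed ancestral enhancer: a member of the P/E set.  Repurposed
    ancestral promoter: the symmetric promoter-to-enhancer event (sister
    ortholog overlapping a qualifying enhancer peak without promoter
    conservation).  Lost: not conserved in the sister species.  Conserved
    elements appear in the totals only.
    """
    config = config or PipelineConfig()
    window = config.annotation.promoter_window
    enh_idx = _qualifying_enhancer_peaks(sister, window)
    prom_idx = _promoter_index(sister, window)
    assoc_idx = _promoter_index(sister, config.ancestral_assoc_window)
    k4me3_idx = IntervalIndex(sister.k4me3)

    enh_rep = enh_lost = 0
    for el in ancestral_enhancers:
        if el.element_id in pe_element_ids:
            enh_rep += 1
            continue
        target = reciprocal_ortholog(
            el.interval, map_to_sister, map_from_sister, config.min_match_sister
        )
        conserved = (
            target is not None
            and enh_idx.overlaps(target)
            and not prom_idx.overlaps(target)
            and not k4me3_idx.overlaps(target)
        )
        if not conserved:
            enh_lost += 1

    prom_rep = prom_lost = 0
    for el in ancestral_promoters:
        target = reciprocal_ortholog(
            el.interval, map_to_sister, map_from_sister, config.min_match_sister
        )
        if target is not None and assoc_idx.overlaps(target):
            continue  # conserved
        if target is not None and enh_idx.overlaps(target):
            prom_rep += 1
        else:
            prom_lost += 1

    return TurnoverTable(
        enh_rep,
        enh_lost,
        prom_rep,
        prom_lost,
        len(ancestral_enhancers),
        len(ancestral_promoters),
    )


def repurposing_bias_test(table: TurnoverTable) -> dict[str, float]:
    """Odds ratio and Fisher p for enhancer- vs promoter-repurposing, plus
    the per-row loss rates and the repurposing rate ratio.

    A zero denominator reports the odds ratio as +inf while the p-value is
    still computed.
    """
    result, odds = fisher_exact_2x2(table.counts)
    enh_loss_rate = table.enh_lost / table.enh_total if table.enh_total else float("nan")
    prom_loss_rate = (
        table.prom_lost / table.prom_total if table.prom_total else float("nan")
    )
    if table.prom_total and table.enh_total and table.prom_repurposed:
        rate_ratio = (table.enh_repurposed / table.enh_total) / (
            table.prom_repurposed / table.prom_total
        )
    else:
        rate_ratio = float("inf") if table.enh_repurposed else float("nan")
    return {
        "odds_ratio": odds,
        "p_value": result.p_value,
        "enhancer_loss_rate": enh_loss_rate,
        "promoter_loss_rate": prom_loss_rate,
        "repurposing_rate_ratio": rate_ratio,
    }
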