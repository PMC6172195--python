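"""Per-species calling of promoters, enhancers, and inactive controls.

Promoters are the 1000 nt upstream of a stable transcript's TSS.
Enhancers are DNase hypersensitive sites supported by H3K27ac and/or
H3K4me1, purged of anything promoter-like: no H3K4me3 peak closer than
1000 nt (gap semantics; overlap counts as distance 0) and no overlap with
the TSS-upstream window or exons of any transcript, stable or unstable.
Inactive controls are uniformly sampled 1000-nt loci at least 1000 nt from
any chromatin signal, exon, or masked repeat/duplication.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .config import AnnotationConfig
from .genome_io import GenomicInterval, PeakCall, TranscriptModel

__all__ = [
    "RegulatoryElement",
    "IntervalIndex",
    "harmonize_peak_replicates",
    "call_stable_transcripts",
    "stability_by_organ",
    "define_promoters",
    "call_enhancers",
    "sample_inactive_regions",
    "gc_matched_subsample",
]


@dataclass
class RegulatoryElement:
    interval: GenomicInterval
    element_class: str  # promoter | enhancer | inactive
    organs_active: set[str] = field(default_factory=set)
    provenance: str = "chromatin"  # chromatin | CAGE (enhancers)
    gc: float | None = None
    cpg: float | None = None
    element_id: str = ""
    transcript_id: str | None = None  # promoters: source transcript

    def __post_init__(self) -> None:
        if self.element_class not in ("promoter", "enhancer", "inactive"):
            raise ValueError(f"bad element class {self.element_class!r}")


class IntervalIndex:
    """Sorted per-contig interval arrays for overlap and gap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.seq_name, []).append((iv.start, iv.end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            # merge overlapping spans so queries are a single bisect
            merged: list[list[int]] = []
            for s, e in pairs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = np.array([m[0] for m in merged])
            self._ends[chrom] = np.array([m[1] for m in merged])

    def overlaps(self, iv: GenomicInterval, pad: int = 0) -> bool:
        """True when ``iv`` is within ``pad`` nt of (or overlapping) any
        indexed interval; ``pad`` implements gap-<-pad exclusion rules."""
        starts = self._starts.get(iv.seq_name)
        if starts is None:
            return False
        ends = self._ends[iv.seq_name]
        # merged spans are disjoint and sorted, so ends are sorted too:
        # the candidate with the largest end among starts < query_end+pad
        # is the last one.
        i = int(np.searchsorted(starts, iv.end + pad, side="left"))
        return i > 0 and int(ends[i - 1]) > iv.start - pad


def _top_n(peaks: Sequence[PeakCall], top_n: int) -> list[PeakCall]:
    """Top peaks by descending score; ties broken by (contig, start)."""
    ranked = sorted(
        peaks, key=lambda p: (-p.score, p.interval.seq_name, p.interval.start)
    )
    return ranked[:top_n]


def _resize_on(
    anchor: PeakCall, width: int, contig_lengths: dict[str, int] | None
) -> GenomicInterval:
    """``width``-nt interval centered on the anchor summit, clipped at
    contig bounds (length relaxed to min(width, contig))."""
    chrom = anchor.interval.seq_name
    center = anchor.summit
    start = center - width // 2
    end = start + width
    limit = None if contig_lengths is None else contig_lengths.get(chrom)
    if start < 0:
        start, end = 0, min(width, limit) if limit else width
    if limit is not None and end > limit:
        end = limit
        start = max(0, end - width)
    return GenomicInterval(chrom, start, end, ".", label=anchor.interval.label)


def harmonize_peak_replicates(
    replicates: Sequence[Sequence[PeakCall]],
    top_n: int,
    min_replicates: int = 3,
    peak_resize: int = 1000,
    contig_lengths: dict[str, int] | None = None,
) -> list[GenomicInterval]:
    """Replicate-consensus peak set, resized around summits.

    Per replicate the ``top_n`` peaks by score are kept.  Overlapping
    peaks (≥1 bp) across replicates form a locus; a locus survives when
    supported by ≥``min_replicates`` replicates (both when exactly two
    replicates exist; every peak when a single merged sample is given).
    The consensus coordinate is ``peak_resize`` nt centered on the summit
    of the highest-score supporting peak.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    kept = [_top_n(rep, top_n) for rep in replicates]
    if len(kept) == 1:
        return [_resize_on(p, peak_resize, contig_lengths) for p in kept[0]]
    required = 2 if len(kept) == 2 else min(min_replicates, len(kept))

    events = sorted(
        (p.interval.seq_name, p.interval.start, p.interval.end, ri, p)
        for ri, rep in enumerate(kept)
        for p in rep
    )
    out: list[GenomicInterval] = []
    cluster: list[tuple[int, PeakCall]] = []
    cluster_end = -1
    cluster_chrom = None

    def flush() -> None:
        reps = {ri for ri, _p in cluster}
        if len(reps) >= required:
            anchor = max(cluster, key=lambda t: t[1].score)[1]
            out.append(_resize_on(anchor, peak_resize, contig_lengths))

    for chrom, start, end, ri, peak in events:
        if cluster and (chrom != cluster_chrom or start >= cluster_end):
            flush()
            cluster = []
        cluster.append((ri, peak))
        cluster_chrom = chrom
        cluster_end = end if len(cluster) == 1 else max(cluster_end, end)
    if cluster:
        flush()
    out.sort(key=lambda iv: (iv.seq_name, iv.start))
    return out


def stability_by_organ(
    transcripts: Iterable[TranscriptModel], config: AnnotationConfig
) -> dict[str, set[str]]:
    """organ → set of stable transcript ids (mean FPKM > threshold and
    span > min length, strict inequalities)."""
    out: dict[str, set[str]] = {}
    for tx in transcripts:
        if len(tx.span) <= config.min_tx_length:
            continue
        for organ in tx.organs():
            mean = tx.mean_fpkm(organ)
            if mean is not None and mean > config.fpkm_threshold:
                out.setdefault(organ, set()).add(tx.transcript_id)
    return out


def call_stable_transcripts(
    transcripts: Sequence[TranscriptModel],
    organ: str,
    config: AnnotationConfig | None = None,
) -> list[TranscriptModel]:
    """Transcripts stable in one organ: mean replicate FPKM strictly > 1
    and genomic span (introns included) strictly > 1000 nt."""
    config = config or AnnotationConfig()
    if not any(organ in tx.organs() for tx in transcripts):
        warnings.warn(f"organ {organ!r} absent from all transcripts")
        return []
    out = []
    for tx in transcripts:
        mean = tx.mean_fpkm(organ)
        if (
            mean is not None
            and mean > config.fpkm_threshold
            and len(tx.span) > config.min_tx_length
        ):
            out.append(tx)
    return out


def upstream_window(
    tss: int, strand: str, window: int, seq_name: str, contig_length: int | None = None
) -> GenomicInterval | None:
    """The ``window`` nt upstream of a TSS, clipped at contig bounds."""
    if strand == "-":
        start, end = tss, tss + window
        if contig_length is not None:
            end = min(end, contig_length)
    else:
        start, end = max(0, tss - window), tss
    if start >= end:
        return None
    return GenomicInterval(seq_name, start, end, strand)


def define_promoters(
    stable_transcripts: Sequence[TranscriptModel],
    window: int = 1000,
    organs_by_transcript: dict[str, set[str]] | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> list[RegulatoryElement]:
    """Promoters: the upstream window of each stable TSS.

    Duplicate intervals (isoforms sharing a TSS) are merged; organ
    activity is the union over merged transcripts.
    """
    seen: dict[GenomicInterval, RegulatoryElement] = {}
    for tx in stable_transcripts:
        limit = None if contig_lengths is None else contig_lengths.get(tx.seq_name)
        iv = upstream_window(tx.tss, tx.strand, window, tx.seq_name, limit)
        if iv is None:
            continue
        organs = (
            set(organs_by_transcript.get(tx.transcript_id, set()))
            if organs_by_transcript
            else set()
        )
        key = GenomicInterval(iv.seq_name, iv.start, iv.end, iv.strand)
        if key in seen:
            seen[key].organs_active |= organs
        else:
            seen[key] = RegulatoryElement(
                iv,
                "promoter",
                organs,
                element_id=f"prom:{iv.seq_name}:{iv.start}-{iv.end}:{iv.strand}",
                transcript_id=tx.transcript_id,
            )
    return sorted(seen.values(), key=lambda e: (e.interval.seq_name, e.interval.start))


def _transcript_exclusion_index(
    transcripts: Iterable[TranscriptModel],
    promoter_window: int,
    contig_lengths: dict[str, int] | None,
) -> IntervalIndex:
    """Exons plus TSS-upstream windows of every transcript, stable or not."""
    ivs: list[GenomicInterval] = []
    for tx in transcripts:
        ivs.extend(tx.exons)
        limit = None if contig_lengths is None else contig_lengths.get(tx.seq_name)
        w = upstream_window(tx.tss, tx.strand, promoter_window, tx.seq_name, limit)
        if w is not None:
            ivs.append(w)
    return IntervalIndex(ivs)


def call_enhancers(
    dhs: Sequence[GenomicInterval],
    k27ac: Sequence[GenomicInterval],
    k4me1: Sequence[GenomicInterval],
    k4me3_all_tissues: Sequence[GenomicInterval],
    all_transcripts: Sequence[TranscriptModel],
    cage_enhancers: Sequence[GenomicInterval] = (),
    config: AnnotationConfig | None = None,
    contig_lengths: dict[str, int] | None = None,
    organs_active: set[str] | None = None,
) -> list[RegulatoryElement]:
    """Chromatin enhancers plus (optionally) CAGE enhancers.

    A DHS qualifies when it overlaps an H3K27ac or H3K4me1 consensus peak
    (≥1 bp), lies ≥1000 nt (gap) from every H3K4me3 peak of every tissue,
    and overlaps neither the promoter window nor the exons of any
    transcript.  CAGE enhancers pass the same exclusions and are appended
    with CAGE provenance.  Output is sorted, hence invariant to input
    order.
    """
    config = config or AnnotationConfig()
    active_idx = IntervalIndex(list(k27ac) + list(k4me1))
    k4me3_idx = IntervalIndex(k4me3_all_tissues)
    tx_idx = _transcript_exclusion_index(
        all_transcripts, config.promoter_window, contig_lengths
    )

    def passes(iv: GenomicInterval) -> bool:
        if k4me3_idx.overlaps(iv, pad=config.bivalence_distance):
            return False
        if tx_idx.overlaps(iv):
            return False
        return True

    out = []
    for iv in dhs:
        if not active_idx.overlaps(iv):
            continue
        if passes(iv):
            out.append(
                RegulatoryElement(
                    iv,
                    "enhancer",
                    set(organs_active or set()),
                    provenance="chromatin",
                    element_id=f"enh:{iv.seq_name}:{iv.start}-{iv.end}",
                )
            )
    for iv in cage_enhancers:
        if passes(iv):
            out.append(
                RegulatoryElement(
                    iv,
                    "enhancer",
                    set(organs_active or set()),
                    provenance="CAGE",
                    element_id=f"cage:{iv.seq_name}:{iv.start}-{iv.end}",
                )
            )
    out.sort(key=lambda e: (e.interval.seq_name, e.interval.start, e.provenance))
    return out


def sample_inactive_regions(
    genome_lengths: dict[str, int],
    exclusion_tracks: Sequence[GenomicInterval],
    masks: Sequence[GenomicInterval] = (),
    config: AnnotationConfig | None = None,
    seed: int | np.random.Generator = 0,
    exons: Sequence[GenomicInterval] = (),
) -> list[RegulatoryElement]:
    """Uniformly sampled non-overlapping inactive loci.

    Rejection sampling with a 50× proposal cap; a proposal is accepted
    when it lies ≥ the exclusion distance from every chromatin signal,
    exon, and mask, and does not overlap a previously accepted locus.
    Deterministic under a fixed seed.
    """
    config = config or AnnotationConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    forbidden = IntervalIndex(
        list(exclusion_tracks) + list(masks) + list(exons)
    )
    length = config.inactive_length
    chroms = sorted(c for c, L in genome_lengths.items() if L >= length)
    if not chroms:
        warnings.warn("no contig long enough for inactive sampling")
        return []
    weights = np.array([genome_lengths[c] - length + 1 for c in chroms], dtype=float)
    weights /= weights.sum()
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out: list[RegulatoryElement] = []
    max_proposals = 50 * config.inactive_target
    proposals = 0
    pad = config.inactive_exclusion_distance
    while len(out) < config.inactive_target and proposals < max_proposals:
        proposals += 1
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        start = int(rng.integers(0, genome_lengths[chrom] - length + 1))
        iv = GenomicInterval(chrom, start, start + length)
        if forbidden.overlaps(iv, pad=pad):
            continue
        spans = taken[chrom]
        i = bisect.bisect_left(spans, (start, start + length))
        if i > 0 and spans[i - 1][1] > start:
            continue
        if i < len(spans) and spans[i][0] < start + length:
            continue
        spans.insert(i, (start, start + length))
        out.append(
            RegulatoryElement(
                iv, "inactive", element_id=f"inact:{chrom}:{start}-{start + length}"
            )
        )
    if not out:
        warnings.warn("no placeable inactive region")
    out.sort(key=lambda e: (e.interval.seq_name, e.interval.start))
    return out


def gc_matched_subsample(
    enhancers: Sequence[RegulatoryElement],
    inactive: Sequence[RegulatoryElement],
    config: AnnotationConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[list[RegulatoryElement], list[RegulatoryElement]]:
    """GC-matched enhancer/inactive subsets.

    Enhancers at or above the GC threshold are removed; up to
    ``gc_match_max_n`` of the rest are sampled, and each is matched
    without replacement to the inactive region with the nearest GC
    content (ties resolved toward the lower GC).
    """
    config = config or AnnotationConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool_e = [e for e in enhancers if e.gc is not None and e.gc < config.gc_match_threshold]
    pool_i = [i for i in inactive if i.gc is not None]
    if len(pool_i) < min(len(pool_e), config.gc_match_max_n):
        raise ValueError("inactive pool smaller than the matched enhancer set")
    if len(pool_e) > config.gc_match_max_n:
        idx = rng.choice(len(pool_e), size=config.gc_match_max_n, replace=False)
        pool_e = [pool_e[int(i)] for i in sorted(idx)]
    # matching: iterate enhancers in deterministic (gc, id) order; keep the
    # inactive pool as a sorted list keyed by gc for bisect lookup
    remaining = sorted(pool_i, key=lambda r: (r.gc, r.element_id))
    keys = [r.gc for r in remaining]
    matched_e, matched_i = [], []
    for enh in sorted(pool_e, key=lambda r: (r.gc, r.element_id)):
        j = bisect.bisect_left(keys, enh.gc)
        best = None
        if j > 0:
            best = j - 1
        if j < len(keys):
            # ties (within float noise) stay on the lower-GC side
            if best is None or abs(keys[j] - enh.gc) < abs(keys[best] - enh.gc) - 1e-12:
                best = j
        ctrl = remaining.pop(best)
        keys.pop(best)
        matched_e.append(enh)
        matched_i.append(ctrl)
    return matched_e, matched_i
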