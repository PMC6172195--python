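"""Interval projection between assemblies through gapless block maps.

Reproduces the liftOver contract the analysis depends on: a minimum
mapped-base fraction (``-minMatch``) for each projection and a reciprocal
(two-way) filter that rejects ambiguous orthology caused by duplications.
Chain scoring and one-to-many output are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import GenomicInterval, OrthologyMap

__all__ = [
    "ProjectionResult",
    "project_interval",
    "project_position",
    "reciprocal_ortholog",
]

# A projected span may bridge target-side gaps (indels between blocks) up
# to this multiple of the source length; beyond that the projection fails.
MAX_SPAN_FACTOR = 10


@dataclass(frozen=True)
class ProjectionResult:
    source: GenomicInterval
    target: GenomicInterval | None
    mapped_fraction: float


def _map_position(pos: int, src: GenomicInterval, tgt: GenomicInterval, orient: str) -> int:
    off = pos - src.start
    if orient == "+":
        return tgt.start + off
    return tgt.end - 1 - off


def project_interval(
    interval: GenomicInterval, map_: OrthologyMap, min_match: float = 0.6
) -> ProjectionResult:
    """Project an interval, requiring ≥ ``min_match`` of its bases mapped.

    The target is the span from the first to the last mapped base
    (orientation-aware).  Projections spanning blocks on different target
    chromosomes fail, as do spans stretched beyond ``MAX_SPAN_FACTOR``
    times the source length.  Strand flips when the covering blocks are
    inverted.
    """
    if not 0 < min_match <= 1:
        raise ValueError("min_match must be in (0, 1]")
    covered = 0
    tgt_chroms: set[str] = set()
    tgt_lo, tgt_hi = None, None
    plus_bases = minus_bases = 0
    for src, tgt, orient in map_.blocks:
        if src.seq_name != interval.seq_name:
            continue
        ov_start = max(interval.start, src.start)
        ov_end = min(interval.end, src.end)
        if ov_start >= ov_end:
            continue
        covered += ov_end - ov_start
        tgt_chroms.add(tgt.seq_name)
        a = _map_position(ov_start, src, tgt, orient)
        b = _map_position(ov_end - 1, src, tgt, orient)
        lo, hi = min(a, b), max(a, b) + 1
        tgt_lo = lo if tgt_lo is None else min(tgt_lo, lo)
        tgt_hi = hi if tgt_hi is None else max(tgt_hi, hi)
        if orient == "+":
            plus_bases += ov_end - ov_start
        else:
            minus_bases += ov_end - ov_start

    fraction = covered / len(interval)
    if fraction < min_match or covered == 0:
        return ProjectionResult(interval, None, fraction)
    if len(tgt_chroms) != 1:
        return ProjectionResult(interval, None, fraction)
    assert tgt_lo is not None and tgt_hi is not None
    if tgt_hi - tgt_lo > MAX_SPAN_FACTOR * len(interval):
        return ProjectionResult(interval, None, fraction)

    strand = interval.strand
    if strand in "+-" and minus_bases > plus_bases:
        strand = "+" if strand == "-" else "-"
    target = GenomicInterval(
        next(iter(tgt_chroms)), tgt_lo, tgt_hi, strand, label=interval.label
    )
    return ProjectionResult(interval, target, fraction)


def project_position(
    seq_name: str, pos: int, map_: OrthologyMap, max_shift: int = 50
) -> tuple[str, int] | None:
    """Project a single position; the nearest mapped base within
    ``max_shift`` nt is used when the position itself falls in a gap."""
    best: tuple[int, str, int] | None = None
    for src, tgt, orient in map_.blocks:
        if src.seq_name != seq_name:
            continue
        clamped = min(max(pos, src.start), src.end - 1)
        dist = abs(clamped - pos)
        if dist > max_shift:
            continue
        mapped = _map_position(clamped, src, tgt, orient)
        if best is None or dist < best[0]:
            best = (dist, tgt.seq_name, mapped)
    if best is None:
        return None
    return best[1], best[2]


def reciprocal_ortholog(
    interval: GenomicInterval,
    map_ab: OrthologyMap,
    map_ba: OrthologyMap,
    min_match: float = 0.6,
) -> GenomicInterval | None:
    """Two-way projection (A→B→A): the B-side target is returned only when
    its back-projection overlaps the original interval by ≥1 bp."""
    fwd = project_interval(interval, map_ab, min_match)
    if fwd.target is None:
        return None
    back = project_interval(fwd.target, map_ba, min_match)
    if back.target is None:
        return None
    if not back.target.overlaps(interval):
        return None
    return fwd.target


def invert_map(map_: OrthologyMap) -> OrthologyMap:
    """Swap source and target sides of a block map."""
    return OrthologyMap(
        map_.target_assembly,
        map_.source_assembly,
        [(tgt, src, orient) for src, tgt, orient in map_.blocks],
    )
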