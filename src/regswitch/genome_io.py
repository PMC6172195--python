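"""Coordinate types and readers/writers for the on-disk formats.

All internal coordinates are 0-based, half-open intervals.  BED and
narrowPeak coordinates are taken as-is; GTF (1-based, closed) is converted
at the boundary (``internal_start = gtf_start - 1``, ``internal_end =
gtf_end``).  The TSS of a transcript is the position of the first
transcribed base: the smallest exon start on the ``+`` strand, the largest
exon end on the ``-`` strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "PeakCall",
    "TranscriptModel",
    "OrthologyMap",
    "ParseError",
    "read_intervals",
    "write_intervals",
    "read_transcript_models",
    "read_sequences",
    "write_sequences",
    "read_orthology_map",
    "write_orthology_map",
]


class ParseError(ValueError):
    """Malformed line in an input file; message names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located, stranded, half-open span on a named sequence."""

    seq_name: str
    start: int
    end: int
    strand: str = "."
    label: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: {self}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when ≥1 base is shared (strand-ignored)."""
        return (
            self.seq_name == other.seq_name
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.seq_name != other.seq_name:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Inter-interval gap in nt; 0 when overlapping; None across contigs."""
        if self.seq_name != other.seq_name:
            return None
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class PeakCall:
    """A scored peak with an optional summit offset (narrowPeak column 10)."""

    interval: GenomicInterval
    score: float
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError(f"summit offset outside peak: {self}")

    @property
    def summit(self) -> int:
        """Absolute summit position; peak midpoint when no summit is given."""
        if self.summit_offset is None:
            return self.interval.start + len(self.interval) // 2
        return self.interval.start + self.summit_offset


@dataclass
class TranscriptModel:
    """An exon chain on one strand with per-(organ, replicate) FPKM values."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    fpkm: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        names = {e.seq_name for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(names) > 1 or len(strands) > 1:
            raise ParseError(
                f"{self.transcript_id}: exons on multiple contigs/strands"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def seq_name(self) -> str:
        return self.exons[0].seq_name

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        """Genomic span, introns included."""
        return GenomicInterval(
            self.seq_name,
            self.exons[0].start,
            self.exons[-1].end,
            self.strand,
            label=self.transcript_id,
        )

    @property
    def tss(self) -> int:
        """First transcribed base: min start on +, max end on −."""
        if self.strand == "-":
            return self.exons[-1].end
        return self.exons[0].start

    def mean_fpkm(self, organ: str) -> float | None:
        vals = [v for (o, _r), v in self.fpkm.items() if o == organ]
        if not vals:
            return None
        return sum(vals) / len(vals)

    def organs(self) -> set[str]:
        return {o for (o, _r) in self.fpkm}


@dataclass
class OrthologyMap:
    """Ordered, gapless, co-linear blocks pairing spans of two assemblies.

    Within each block source and target have equal length; indels live
    between blocks.  ``orientation`` is ``+`` (co-linear) or ``-``
    (inverted).
    """

    source_assembly: str
    target_assembly: str
    blocks: list[tuple[GenomicInterval, GenomicInterval, str]]

    def __post_init__(self) -> None:
        for src, tgt, orient in self.blocks:
            if len(src) != len(tgt):
                raise ValueError(
                    f"block length mismatch: {src} vs {tgt}"
                )
            if orient not in ("+", "-"):
                raise ValueError(f"bad orientation {orient!r}")
        self.blocks.sort(key=lambda b: (b[0].seq_name, b[0].start))
        by_chrom: dict[str, int] = {}
        for src, _tgt, _o in self.blocks:
            prev = by_chrom.get(src.seq_name, -1)
            if src.start < prev:
                raise ValueError(f"overlapping source blocks at {src}")
            by_chrom[src.seq_name] = src.end

    def mapped_source_length(self) -> int:
        return sum(len(src) for src, _t, _o in self.blocks)


# ---------------------------------------------------------------------------
# Interval / peak I/O


def read_intervals(path: str | Path, format: str = "BED"):
    """Read a BED or narrowPeak file.

    Returns ``list[GenomicInterval]`` for BED, ``list[PeakCall]`` for
    narrowPeak.  Strand ``.`` becomes unstranded; narrowPeak column 10
    of ``-1`` means no summit.
    """
    if format not in ("BED", "narrowPeak"):
        raise ValueError(f"unknown format {format!r}")
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            try:
                start, end = int(cols[1]), int(cols[2])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            if start >= end or start < 0:
                raise ParseError(f"{path}:{lineno}: start >= end")
            label = cols[3] if len(cols) > 3 and cols[3] != "." else None
            score = None
            if len(cols) > 4 and cols[4] not in (".", ""):
                score = float(cols[4])
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "."
            if format == "narrowPeak":
                if len(cols) < 10:
                    raise ParseError(f"{path}:{lineno}: narrowPeak needs 10 columns")
                summit = int(cols[9])
                # the score belongs to the peak, not the bare interval
                iv = GenomicInterval(cols[0], start, end, strand, label)
                out.append(
                    PeakCall(
                        iv,
                        score if score is not None else 0.0,
                        None if summit < 0 else summit,
                    )
                )
            else:
                out.append(GenomicInterval(cols[0], start, end, strand, label, score))
    return out


def write_intervals(items: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6, preserving input order."""
    with open(path, "w") as fh:
        for iv in items:
            if isinstance(iv, PeakCall):  # allow peak lists; emit narrowPeak
                p = iv
                fh.write(
                    "\t".join(
                        [
                            p.interval.seq_name,
                            str(p.interval.start),
                            str(p.interval.end),
                            p.interval.label or ".",
                            _fmt_score(p.score),
                            p.interval.strand,
                            "0",
                            "-1",
                            "-1",
                            str(-1 if p.summit_offset is None else p.summit_offset),
                        ]
                    )
                    + "\n"
                )
            else:
                fh.write(
                    "\t".join(
                        [
                            iv.seq_name,
                            str(iv.start),
                            str(iv.end),
                            iv.label or ".",
                            _fmt_score(iv.score),
                            iv.strand,
                        ]
                    )
                    + "\n"
                )


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "."
    if score == int(score):
        return str(int(score))
    return repr(score)


# ---------------------------------------------------------------------------
# Transcript models


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_transcript_models(
    path: str | Path, expression_path: str | Path | None = None
) -> list[TranscriptModel]:
    """Read exon features from a GTF plus an optional expression TSV.

    The expression table has columns ``transcript_id, organ, replicate,
    fpkm``.  Transcripts lacking expression rows get an empty fpkm
    mapping; expression rows for unknown transcripts are warned about and
    ignored.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    genes: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ParseError(f"{path}:{lineno}: fewer than 9 GTF columns")
            if cols[2] != "exon":
                continue
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            attrs = _parse_gtf_attributes(cols[8])
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ParseError(f"{path}:{lineno}: missing transcript_id")
            iv = GenomicInterval(cols[0], start1 - 1, end1, cols[6])
            exons.setdefault(tid, []).append(iv)
            genes.setdefault(tid, attrs.get("gene_id", tid))

    fpkm: dict[str, dict[tuple[str, str], float]] = {}
    if expression_path is not None:
        with open(expression_path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for name in ("transcript_id", "organ", "replicate", "fpkm"):
                if name not in idx:
                    raise ParseError(f"{expression_path}: missing column {name}")
            for raw in fh:
                cols = raw.rstrip("\n").split("\t")
                tid = cols[idx["transcript_id"]]
                if tid not in exons:
                    warnings.warn(
                        f"expression row for unknown transcript {tid}; ignored"
                    )
                    continue
                fpkm.setdefault(tid, {})[
                    (cols[idx["organ"]], cols[idx["replicate"]])
                ] = float(cols[idx["fpkm"]])

    return [
        TranscriptModel(tid, genes[tid], ivs, fpkm.get(tid, {}))
        for tid, ivs in exons.items()
    ]


def write_transcript_models(
    transcripts: Iterable[TranscriptModel],
    gtf_path: str | Path,
    expression_path: str | Path | None = None,
) -> None:
    """Emit exon features as GTF (1-based closed) plus the expression TSV."""
    with open(gtf_path, "w") as fh:
        for tx in transcripts:
            for iv in tx.exons:
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
                )
                fh.write(
                    "\t".join(
                        [
                            iv.seq_name,
                            "regswitch",
                            "exon",
                            str(iv.start + 1),
                            str(iv.end),
                            ".",
                            iv.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
    if expression_path is not None:
        with open(expression_path, "w") as fh:
            fh.write("transcript_id\torgan\treplicate\tfpkm\n")
            for tx in transcripts:
                for (organ, rep), value in sorted(tx.fpkm.items()):
                    fh.write(f"{tx.transcript_id}\t{organ}\t{rep}\t{value:g}\n")


# ---------------------------------------------------------------------------
# Sequences


def read_sequences(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an uppercased name → sequence mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"{path}: duplicate record name {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_sequences(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Orthology maps

_MAP_COLUMNS = (
    "src_chrom",
    "src_start",
    "src_end",
    "tgt_chrom",
    "tgt_start",
    "tgt_end",
    "orientation",
)


def read_orthology_map(
    path: str | Path,
    source_assembly: str = "source",
    target_assembly: str = "target",
) -> OrthologyMap:
    """Read a block map TSV (our gapless stand-in for chain files)."""
    blocks = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for name in _MAP_COLUMNS:
            if name not in idx:
                raise ParseError(f"{path}: missing column {name}")
        for raw in fh:
            if not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            src = GenomicInterval(
                cols[idx["src_chrom"]],
                int(cols[idx["src_start"]]),
                int(cols[idx["src_end"]]),
            )
            tgt = GenomicInterval(
                cols[idx["tgt_chrom"]],
                int(cols[idx["tgt_start"]]),
                int(cols[idx["tgt_end"]]),
            )
            blocks.append((src, tgt, cols[idx["orientation"]]))
    return OrthologyMap(source_assembly, target_assembly, blocks)


def write_orthology_map(map_: OrthologyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_MAP_COLUMNS) + "\n")
        for src, tgt, orient in map_.blocks:
            fh.write(
                f"{src.seq_name}\t{src.start}\t{src.end}\t"
                f"{tgt.seq_name}\t{tgt.start}\t{tgt.end}\t{orient}\n"
            )
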