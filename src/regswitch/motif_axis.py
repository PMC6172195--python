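"""U1/PAS motif scanning and TSS-anchored density analyses.

Stable transcription is promoted by 5' splice-donor (U1) sites downstream
of a TSS, which protect nascent RNA from premature cleavage, and opposed
by TSS-proximal polyadenylation signals (PAS) that route transcripts to
degradation.  This module scans sequences with position-weight matrices,
anchors the hits on TSSs, and compares the resulting density/distance
profiles between orthologous element sets.

Shipped default matrices encode the canonical donor hexamer (GT core) and
the canonical PAS (AATAAA with the ATTAAA variant); thresholds admit the
canonical variants while rejecting >99% of random hexamers.  User
matrices in the 4-row text format are accepted everywhere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .stat_tests import bh_adjust, mann_whitney_u, wilcoxon_signed_rank

__all__ = [
    "MotifMatrix",
    "MotifHit",
    "DensityProfile",
    "default_u1_matrix",
    "default_pas_matrix",
    "scan_motif",
    "tss_density_profile",
    "closest_motif_distance",
    "u1_before_pas_fraction",
    "compare_axis_between_species",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT_ROWS = [3, 2, 1, 0]  # A<->T, C<->G
DEFAULT_WINDOWS = (200, 400, 600, 800, 1000)


@dataclass(frozen=True)
class MotifMatrix:
    """Log-odds position-weight matrix (rows A,C,G,T) with a hit threshold."""

    name: str
    log_odds: np.ndarray  # shape (4, length)
    score_threshold: float

    def __post_init__(self) -> None:
        if self.log_odds.shape[0] != 4 or self.log_odds.shape[1] < 4:
            raise ValueError("matrix must be 4 rows × ≥4 positions")
        if self.score_threshold > float(self.log_odds.max(axis=0).sum()):
            raise ValueError("threshold exceeds the maximum achievable score")

    @property
    def length(self) -> int:
        return int(self.log_odds.shape[1])

    def score(self, kmer: str) -> float:
        """Score one window; any non-ACGT base gives -inf."""
        total = 0.0
        for j, base in enumerate(kmer.upper()):
            i = _BASE_INDEX.get(base)
            if i is None:
                return -math.inf
            total += float(self.log_odds[i, j])
        return total

    def reverse_complement(self) -> "MotifMatrix":
        return MotifMatrix(
            self.name, self.log_odds[_COMPLEMENT_ROWS, ::-1].copy(), self.score_threshold
        )


@dataclass(frozen=True)
class MotifHit:
    seq_name: str
    position: int  # 0-based start on the forward coordinate system
    strand: str
    score: float


@dataclass(frozen=True)
class DensityProfile:
    """Per-element motif densities per kb, up- and downstream of the TSS."""

    element_id: str
    upstream_per_kb: float
    downstream_per_kb: float
    cumulative: dict[int, tuple[float, float]]  # window -> (up, down)


def _matrix_from_probs(name: str, probs: Sequence[dict[str, float]], threshold_kmers: Sequence[str]) -> MotifMatrix:
    lo = np.empty((4, len(probs)))
    for j, col in enumerate(probs):
        for base, i in _BASE_INDEX.items():
            lo[i, j] = math.log2(col[base] / 0.25)
    m = MotifMatrix(name, lo, -1e9)
    thr = min(m.score(k) for k in threshold_kmers) - 1e-9
    return MotifMatrix(name, lo, thr)


def _col(**kw: float) -> dict[str, float]:
    rest = (1.0 - sum(kw.values())) / (4 - len(kw))
    return {b: kw.get(b, rest) for b in _BASES}


def default_u1_matrix() -> MotifMatrix:
    """Splice-donor matrix; threshold admits GTAAGT and GTGAGT."""
    return _matrix_from_probs(
        "U1",
        [
            _col(G=0.94),
            _col(T=0.94),
            _col(A=0.55, G=0.35),
            _col(A=0.85),
            _col(G=0.85),
            _col(T=0.50, A=0.20, G=0.20),
        ],
        ["GTAAGT", "GTGAGT"],
    )


def default_pas_matrix() -> MotifMatrix:
    """Polyadenylation-signal matrix; threshold admits AATAAA and ATTAAA."""
    return _matrix_from_probs(
        "PAS",
        [
            _col(A=0.92),
            _col(A=0.60, T=0.35),
            _col(T=0.92),
            _col(A=0.92),
            _col(A=0.92),
            _col(A=0.92),
        ],
        ["AATAAA", "ATTAAA"],
    )


def read_matrix(path: str | Path) -> MotifMatrix:
    """Read the 4-row position-weight text format.

    First line: ``#name=<text> threshold=<float>``; then four
    whitespace-separated rows in A, C, G, T order.
    """
    with open(path) as fh:
        header = fh.readline().strip()
        fields = dict(
            part.split("=", 1) for part in header.lstrip("#").split() if "=" in part
        )
        rows = [
            [float(v) for v in fh.readline().split()] for _ in range(4)
        ]
    return MotifMatrix(fields.get("name", "other"), np.asarray(rows), float(fields["threshold"]))


def write_matrix(matrix: MotifMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#name={matrix.name} threshold={matrix.score_threshold!r}\n")
        for row in matrix.log_odds:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        out[arr == ord(base)] = i
    return out


def _strand_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    length = log_odds.shape[1]
    n = codes.size - length + 1
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(length):
        window = codes[j : j + n]
        ok = window >= 0
        valid &= ok
        scores += np.where(ok, log_odds[np.clip(window, 0, 3), j], 0.0)
    scores[~valid] = -np.inf
    return scores


def scan_motif(
    sequence: str, matrix: MotifMatrix, seq_name: str = "seq"
) -> list[MotifHit]:
    """Scan both strands; hits are reported as forward-coordinate starts."""
    if len(sequence) < matrix.length:
        raise ValueError("sequence shorter than the matrix")
    codes = _encode(sequence)
    hits: list[MotifHit] = []
    for strand, mat in (("+", matrix), ("-", matrix.reverse_complement())):
        scores = _strand_scores(codes, mat.log_odds)
        for pos in np.nonzero(scores >= matrix.score_threshold)[0]:
            hits.append(MotifHit(seq_name, int(pos), strand, float(scores[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def _signed_offset(hit_pos: int, tss: int, strand: str) -> int:
    """Sense-oriented offset of a hit start from the TSS (≥0 = downstream)."""
    return hit_pos - tss if strand == "+" else tss - hit_pos


def tss_density_profile(
    tss: int,
    strand: str,
    hits: Iterable[MotifHit],
    windows: Sequence[int] = DEFAULT_WINDOWS,
    element_id: str = "",
    contig_length: int | None = None,
) -> DensityProfile:
    """Per-kb motif densities in sense-oriented windows around a TSS.

    A hit is counted in the window containing its start; hit strand is
    ignored (the sense/antisense contrast comes from which side of the TSS
    is measured).  Windows truncated by a contig end use the effective
    length in the denominator.
    """
    offsets = [_signed_offset(h.position, tss, strand) for h in hits]
    cumulative: dict[int, tuple[float, float]] = {}
    for w in sorted(windows):
        down_n = sum(1 for o in offsets if 0 <= o < w)
        up_n = sum(1 for o in offsets if -w <= o < 0)
        down_len, up_len = w, w
        if contig_length is not None:
            if strand == "+":
                down_len = max(0, min(tss + w, contig_length) - tss)
                up_len = max(0, tss - max(tss - w, 0))
            else:
                down_len = max(0, tss - max(tss - w, 0))
                up_len = max(0, min(tss + w, contig_length) - tss)
        cumulative[w] = (
            up_n / (up_len / 1000) if up_len else math.nan,
            down_n / (down_len / 1000) if down_len else math.nan,
        )
    top = max(windows)
    return DensityProfile(element_id, cumulative[top][0], cumulative[top][1], cumulative)


def closest_motif_distance(
    tss: int, strand: str, hits: Iterable[MotifHit], direction: str
) -> int | None:
    """Distance from the TSS to the nearest hit on the requested side.

    A hit starting exactly at the TSS counts downstream at distance 0.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    offsets = [_signed_offset(h.position, tss, strand) for h in hits]
    side = [o for o in offsets if (o >= 0) == (direction == "down")]
    if not side:
        return None
    return min(abs(o) for o in side)


def u1_before_pas_fraction(
    tss_list: Sequence[tuple[int, str]],
    u1_hits: Sequence[MotifHit],
    pas_hits: Sequence[MotifHit],
    window: int = 1000,
) -> tuple[float, int]:
    """Fraction of TSSs whose nearest downstream U1 precedes the nearest
    downstream PAS.

    A TSS with downstream U1 but no PAS counts as a success; one with
    neither motif is excluded from the denominator.  Returns
    ``(fraction, n_evaluated)``; fraction is ``nan`` when nothing is
    evaluated.
    """
    successes = evaluated = 0
    for tss, strand in tss_list:
        du1 = [
            o for o in (_signed_offset(h.position, tss, strand) for h in u1_hits)
            if 0 <= o < window
        ]
        dpas = [
            o for o in (_signed_offset(h.position, tss, strand) for h in pas_hits)
            if 0 <= o < window
        ]
        if not du1 and not dpas:
            continue
        evaluated += 1
        if du1 and (not dpas or min(du1) < min(dpas)):
            successes += 1
    if evaluated == 0:
        warnings.warn("no TSS with downstream motifs; fraction undefined")
        return math.nan, 0
    return successes / evaluated, evaluated


def compare_axis_between_species(
    profiles_a: Sequence[DensityProfile],
    profiles_b: Sequence[DensityProfile],
    paired: bool = True,
) -> list[dict]:
    """Compare TSS-anchored density profiles between two species.

    Paired mode matches profiles by element id and runs a Wilcoxon
    signed-rank test per (side, window); unpaired mode uses Mann–Whitney.
    BH correction is applied across the whole (side × window) family.
    Means and 95% normal-approximation confidence half-widths are reported
    for the cumulative curves.
    """
    if paired:
        by_id_b = {p.element_id: p for p in profiles_b}
        ids = [p.element_id for p in profiles_a]
        if set(ids) != set(by_id_b):
            raise ValueError("paired comparison requires matching element ids")
        profiles_b = [by_id_b[i] for i in ids]
    windows = sorted(profiles_a[0].cumulative) if profiles_a else []
    rows = []
    for side_idx, side in ((0, "up"), (1, "down")):
        for w in windows:
            va = np.array([p.cumulative[w][side_idx] for p in profiles_a])
            vb = np.array([p.cumulative[w][side_idx] for p in profiles_b])
            row = {
                "side": side,
                "window": w,
                "mean_a": float(np.nanmean(va)),
                "mean_b": float(np.nanmean(vb)),
                "ci_a": float(1.96 * np.nanstd(va, ddof=1) / math.sqrt(len(va)))
                if len(va) > 1
                else math.nan,
                "ci_b": float(1.96 * np.nanstd(vb, ddof=1) / math.sqrt(len(vb)))
                if len(vb) > 1
                else math.nan,
            }
            if len(va) < 2 or len(vb) < 2:
                warnings.warn("too few elements; test skipped")
                row["p"] = math.nan
            elif paired:
                row["p"] = wilcoxon_signed_rank(vb - va).p_value
            else:
                row["p"] = mann_whitney_u(va, vb).p_value
            rows.append(row)
    tested = [r for r in rows if not math.isnan(r["p"])]
    for row, q in zip(tested, bh_adjust([r["p"] for r in tested])):
        row["p_adj"] = q
    return rows
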