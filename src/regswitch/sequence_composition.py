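"""GC/CpG composition metrics and the orthologous-shift resampling test.

The question these tools answer: did promoter-side orthologs of repurposed
elements gain GC/CpG beyond genome-wide drift?  The null is built by
resampling equally sized sets of orthologous inactive-region pairs, which
carry the same assembly-wide compositional skew as the tested pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .stat_tests import TestResult, bh_adjust, mann_whitney_u, wilcoxon_signed_rank

__all__ = [
    "CompositionRecord",
    "ShiftTestResult",
    "gc_content",
    "cpg_frequency",
    "compare_composition_classes",
    "ortholog_shift_resampling_test",
]


@dataclass(frozen=True)
class CompositionRecord:
    element_id: str
    gc: float
    cpg: float


@dataclass(frozen=True)
class ShiftTestResult:
    observed_mean_diff: float
    null_means: tuple[float, ...]
    empirical_p: float
    wilcoxon: TestResult


def gc_content(sequence: str) -> float:
    """(G+C) / (A+C+G+T); N excluded from the denominator.

    Returns ``nan`` when there are no informative bases.
    """
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    informative = gc + s.count("A") + s.count("T")
    if informative == 0:
        return math.nan
    return gc / informative


def cpg_frequency(sequence: str, strict_n: bool = False) -> float:
    """CpG dinucleotide count over dinucleotide positions (length − 1).

    With ``strict_n`` the positions whose window contains an N are removed
    from the denominator as well; by default only the count is affected
    (an N can never be part of a CG).  ``nan`` for sequences shorter
    than 2.
    """
    s = sequence.upper()
    if len(s) < 2:
        return math.nan
    count = s.count("CG")
    denom = len(s) - 1
    if strict_n and "N" in s:
        denom = sum(
            1 for i in range(len(s) - 1) if "N" not in s[i : i + 2]
        )
        if denom == 0:
            return math.nan
    return count / denom


def compare_composition_classes(
    records_by_class: Mapping[str, Sequence[CompositionRecord]],
    metric: str = "gc",
) -> list[dict]:
    """All pairwise Mann–Whitney tests on a composition metric, with BH
    correction across the pair family."""
    if metric not in ("gc", "cpg"):
        raise ValueError("metric must be 'gc' or 'cpg'")
    values = {
        cls: [getattr(r, metric) for r in recs if not math.isnan(getattr(r, metric))]
        for cls, recs in records_by_class.items()
    }
    names = sorted(values)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if len(values[a]) < 2 or len(values[b]) < 2:
                warnings.warn(f"pair ({a}, {b}) skipped: class too small")
                continue
            res = mann_whitney_u(values[a], values[b])
            rows.append(
                {"class_a": a, "class_b": b, "u": res.statistic, "p": res.p_value}
            )
    for row, q in zip(rows, bh_adjust([r["p"] for r in rows])):
        row["p_adj"] = q
    return rows


def ortholog_shift_resampling_test(
    pe_pairs: Sequence[tuple[float, float]],
    inactive_pairs: Sequence[tuple[float, float]],
    n_resamples: int = 10_000,
    seed: int | np.random.Generator = 0,
    direction: str = "greater",
) -> ShiftTestResult:
    """Test whether the mean orthologous shift at tested pairs exceeds the
    genome-wide drift measured at inactive-region pairs.

    ``observed_mean_diff`` is the mean of ``b − a`` over ``pe_pairs``.
    Each resample draws ``len(pe_pairs)`` inactive pairs without
    replacement; the empirical p uses the add-one convention
    ``(1 + #extreme) / (n_resamples + 1)`` so it can never reach zero.  A
    Wilcoxon signed-rank test on the tested pairs is reported alongside.
    """
    if len(inactive_pairs) <= len(pe_pairs):
        raise ValueError("inactive pool must exceed the tested set")
    if direction not in ("greater", "less", "two-sided"):
        raise ValueError(f"bad direction {direction!r}")
    if n_resamples < 100:
        warnings.warn("fewer than 100 resamples; empirical p is coarse")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pe = np.asarray(pe_pairs, dtype=float)
    inact = np.asarray(inactive_pairs, dtype=float)
    observed = float(np.mean(pe[:, 1] - pe[:, 0]))
    diffs = inact[:, 1] - inact[:, 0]
    k = len(pe_pairs)
    null = np.empty(n_resamples)
    for i in range(n_resamples):
        null[i] = diffs[rng.choice(diffs.size, size=k, replace=False)].mean()
    if direction == "greater":
        extreme = int(np.sum(null >= observed))
    elif direction == "less":
        extreme = int(np.sum(null <= observed))
    else:
        center = float(null.mean())
        extreme = int(np.sum(np.abs(null - center) >= abs(observed - center)))
    p = (1 + extreme) / (n_resamples + 1)
    wil = wilcoxon_signed_rank(pe[:, 1] - pe[:, 0])
    return ShiftTestResult(observed, tuple(float(v) for v in null), p, wil)
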