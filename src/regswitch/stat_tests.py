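"""Statistical kernel: exact and rank tests, BH correction, signal ratios.

Thin, explicit wrappers over scipy/statsmodels with the conventions used
throughout the pipeline pinned down: Fisher's exact p is the two-sided sum
of hypergeometric point probabilities no larger than the observed one;
rank tests use exact small-sample paths; zero differences are dropped from
the signed-rank test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "fisher_exact_2x2",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "bh_adjust",
    "normalized_signal_compare",
]

EXACT_MAX_N = 12  # exact enumeration path for rank tests up to this size


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value outside [0,1]: {self.p_value}")


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[TestResult, float]:
    """Two-sided Fisher's exact test on a 2×2 table.

    Returns ``(TestResult, odds_ratio)`` where the odds ratio is the
    unconditional cross-product ratio ``(a·d)/(b·c)`` (``inf`` when the
    denominator is zero, ``nan`` for 0/0).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative count in contingency table")
    if a + b + c + d == 0:
        raise ValueError("all-zero contingency table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = math.nan if a * d == 0 else math.inf
    else:
        odds = (a * d) / (b * c)
    return TestResult(odds, float(p), "fisher_exact", (a + b, c + d)), odds


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> TestResult:
    """Mann–Whitney U test.

    The exact distribution is used when ``len(x)+len(y) <= EXACT_MAX_N``
    and there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= EXACT_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return TestResult(
        float(res.statistic), float(res.pvalue), f"mann_whitney_{method}", (x.size, y.size)
    )


def wilcoxon_signed_rank(
    diffs: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Wilcoxon signed-rank test on a vector of paired differences.

    Zero differences are dropped (Wilcoxon's original treatment).  Exact
    sign enumeration when the nonzero count is ≤ ``EXACT_MAX_N``; normal
    approximation with continuity correction otherwise.  All-zero input
    yields p = 1 with a warning.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("empty sample")
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all differences are zero; signed-rank test degenerate")
        return TestResult(0.0, 1.0, "wilcoxon_degenerate", (0,))
    method = "exact" if nz.size <= EXACT_MAX_N else "approx"
    res = stats.wilcoxon(
        nz, alternative=alternative, zero_method="wilcox", correction=True,
        method="exact" if method == "exact" else "approx",
    )
    return TestResult(
        float(res.statistic), float(min(res.pvalue, 1.0)), f"wilcoxon_{method}", (nz.size,)
    )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in adj]


def normalized_signal_compare(
    signal_by_class: Mapping[str, Sequence[tuple[float, float]]],
    pseudocount: float = 1.0,
) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Input-normalized ChIP signal comparison between element classes.

    Each element contributes ``log2((chip + pseudocount) / (input +
    pseudocount))``; classes are compared pairwise with Mann–Whitney U and
    BH correction across the pair family.
    """
    ratios = {
        cls: np.log2(
            (np.asarray([c for c, _i in vals], dtype=float) + pseudocount)
            / (np.asarray([i for _c, i in vals], dtype=float) + pseudocount)
        )
        for cls, vals in signal_by_class.items()
    }
    pairs = []
    names = sorted(ratios)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if len(ratios[a]) < 2 or len(ratios[b]) < 2:
                warnings.warn(f"class pair ({a}, {b}) skipped: too few elements")
                continue
            res = mann_whitney_u(ratios[a], ratios[b])
            pairs.append({"class_a": a, "class_b": b, "u": res.statistic, "p": res.p_value})
    adj = bh_adjust([row["p"] for row in pairs])
    for row, q in zip(pairs, adj):
        row["p_adj"] = q
    return ratios, pairs
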