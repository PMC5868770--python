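"""Benchmarking statistics for copy-number predictions and SV call sets.

Covers the comparisons used to validate read-depth copy-number estimates
against an orthogonal truth (ddPCR or a published genotype set) and to
score structural-variant call sets against a validated set:

* mean absolute error (MAE), standard deviation of the absolute error
  (SDAE) and accuracy (fraction of samples whose rounded estimate equals
  the integer truth) for paired predicted/true copy numbers;
* a one-sided Wilcoxon signed-rank test on per-sample absolute errors to
  compare two prediction methods;
* reciprocal overlap of intervals and greedy one-to-one call-set matching
  giving sensitivity and precision (match when reciprocal overlap is
  strictly greater than 0.6);
* Spearman correlation of confidence-interval length against the copy
  number estimate (precision degrades as copy number grows).
"""

from __future__ import annotations

import math
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import CNEstimate, round_half_away

__all__ = [
    "ErrorStats",
    "error_stats",
    "paired_sign_test",
    "reciprocal_overlap",
    "match_callsets",
    "spearman_ci_vs_cn",
    "read_measurement_table",
]

Interval = tuple[str, int, int]


class ErrorStats(NamedTuple):
    mae: float
    sdae: float
    accuracy: float


def error_stats(
    predicted: Sequence[float],
    truth: Sequence[float],
    rounded_errors: bool = False,
) -> ErrorStats:
    """MAE, SDAE and accuracy of predictions against integer truth.

    MAE is the mean absolute error and SDAE its sample (n-1) standard
    deviation, both on the unrounded predictions by default
    (``rounded_errors=True`` computes them on the rounded scale instead).
    Accuracy always compares the rounded prediction (half away from zero)
    to the truth.
    """
    pred = np.asarray(predicted, dtype=float)
    true = np.asarray(truth, dtype=float)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("need equal-length, non-empty prediction and truth vectors")
    rounded = np.array([round_half_away(p) for p in pred], dtype=float)
    err = np.abs((rounded if rounded_errors else pred) - true)
    sdae = float(np.std(err, ddof=1)) if err.size > 1 else 0.0
    return ErrorStats(
        mae=float(np.mean(err)),
        sdae=sdae,
        accuracy=float(np.mean(rounded == true)),
    )


def paired_sign_test(
    abs_err_a: Sequence[float],
    abs_err_b: Sequence[float],
) -> float:
    """One-sided Wilcoxon signed-rank p-value that method *a* has smaller
    per-sample absolute errors than method *b*.

    Zero differences are discarded and ties share mid-ranks.  With no
    informative (nonzero) difference the test is undefined and NaN is
    returned.
    """
    a = np.asarray(abs_err_a, dtype=float)
    b = np.asarray(abs_err_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("need equal-length, non-empty error vectors")
    d = a - b
    if np.all(d == 0):
        return math.nan
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="less")
    return float(res.pvalue)


def reciprocal_overlap(a: Interval, b: Interval) -> float:
    """Reciprocal overlap of two intervals: the minimum, over both
    intervals, of shared length divided by own length.  Intervals on
    different chromosomes overlap by 0."""
    (chrom_a, start_a, end_a), (chrom_b, start_b, end_b) = a, b
    if chrom_a != chrom_b:
        return 0.0
    shared = min(end_a, end_b) - max(start_a, start_b)
    if shared <= 0:
        return 0.0
    return min(shared / (end_a - start_a), shared / (end_b - start_b))


def match_callsets(
    calls: Sequence[Interval],
    truth: Sequence[Interval],
    min_ro: float = 0.6,
) -> tuple[float, float]:
    """Sensitivity and precision of ``calls`` against ``truth``.

    Pairs are matched greedily one-to-one by descending reciprocal
    overlap; a pair matches only when its overlap is strictly greater
    than ``min_ro``.  Sensitivity is matched truth over all truth,
    precision matched calls over all calls.  Swapping the two sets swaps
    the two statistics.
    """
    pairs = []
    for i, c in enumerate(calls):
        for j, t in enumerate(truth):
            ro = reciprocal_overlap(c, t)
            if ro > min_ro:
                pairs.append((ro, i, j))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_calls: set[int] = set()
    used_truth: set[int] = set()
    for _, i, j in pairs:
        if i in used_calls or j in used_truth:
            continue
        used_calls.add(i)
        used_truth.add(j)
    sensitivity = len(used_truth) / len(truth) if truth else math.nan
    precision = len(used_calls) / len(calls) if calls else math.nan
    return sensitivity, precision


def spearman_ci_vs_cn(estimates: Iterable[CNEstimate]) -> float:
    """Spearman rank correlation between confidence-interval length and
    the copy-number estimate; NaN for constant input."""
    ests = [e for e in estimates if e.is_call]
    if len(ests) < 3:
        raise ValueError("need at least 3 estimates")
    ci_len = [e.ci_length for e in ests]
    cn = [e.cn_mean for e in ests]
    if len(set(ci_len)) == 1 or len(set(cn)) == 1:
        return math.nan
    rho, _ = stats.spearmanr(cn, ci_len)
    return float(rho)


def read_measurement_table(path: str) -> pd.DataFrame:
    """Read a long-format measurement table (columns ``sample``,
    ``method``, ``value``; tab-separated, header required) into a wide
    sample-by-method frame for paired comparisons."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"sample", "method", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"measurement table is missing columns: {sorted(missing)}")
    wide = df.pivot_table(index="sample", columns="method", values="value",
                          aggfunc="first")
    return wide
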