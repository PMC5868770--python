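"""Detection of large CNVs and whole-chromosome aneuploidies.

The caller scans the GC-corrected per-bin copy-number signal in
fixed-width windows.  A window whose copy-number mean deviates from the
ploidy baseline by more than ``z_threshold`` standard errors is a seed;
adjacent seed windows deviating in the same direction are merged, runs
shorter than ``min_consecutive`` windows are discarded, and each surviving
run is re-scored as a region estimate.  With the defaults (1000 bins of
100 bp per window, z = 5, three consecutive windows) the caller targets
events of roughly a megabase and larger at ~30x depth — the scale at which
split-read and discordant-pair callers lose power and a read-depth
complement is most useful.  The procedure is deterministic given the input
and parameters.

Mosaic whole-chromosome events are best read from the fractional
chromosome-level estimate (``CopyNumberResult.chromosome_cn``); no integer
rounding is forced at chromosome scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .model import CNEstimate, CopyNumberResult

__all__ = ["CNSegment", "call_segments", "segments_to_frame"]


@dataclass(frozen=True)
class CNSegment:
    """A called copy-number segment (non-overlapping within a chromosome)."""

    chrom: str
    start: int
    end: int
    cn_mean: float
    cn_rounded: int
    ci_low: float
    ci_high: float
    n_bins: int

    def svtype(self, ploidy: int = 2) -> str:
        return "DUP" if self.cn_mean > ploidy else "DEL"


def call_segments(
    result: "CopyNumberResult",
    window_bins: int = 1000,
    z_threshold: float = 5.0,
    min_consecutive: int = 3,
    min_window_used: int = 10,
    min_effect: float = 0.3,
) -> list[CNSegment]:
    """Call large CNV segments from a fitted copy-number model.

    Parameters
    ----------
    result
        A fitted :class:`~cnquant.model.CopyNumberResult`.
    window_bins
        Number of consecutive bins per scan window (1000 bins of 100 bp =
        100 kb windows).
    z_threshold
        A window seeds a call when its mean copy number differs from the
        ploidy by more than this many standard errors of the window mean —
        i.e. the window confidence interval at this z excludes the ploidy.
    min_consecutive
        Minimum run length, in windows, of same-direction seeds.
    min_window_used
        Windows with fewer informative bins than this are treated as
        non-deviant (insufficient evidence).
    min_effect
        Minimum absolute deviation from the ploidy, in copies, for a
        window to seed.  With ~1000 informative bins per window the
        standard error of the window mean is of order 0.002 copies, so a
        pure z criterion would fire on sub-percent systematic wobbles of
        the GC fit; requiring a material effect size keeps the caller
        specific to genuine events while costing no power at the ≥1
        copy deviations it targets.
    """
    ploidy = result.model.ploidy
    segments: list[CNSegment] = []
    bins = result.model.bins
    for chrom, sub in bins.groupby("chrom", sort=True):
        sub = sub.sort_values("start", kind="stable").reset_index(drop=True)
        cn = result.bin_cn(sub)
        n_windows = math.ceil(len(sub) / window_bins)
        directions = np.zeros(n_windows, dtype=int)  # -1 loss, 0 neutral, +1 gain
        bounds = []
        for w in range(n_windows):
            lo, hi = w * window_bins, min((w + 1) * window_bins, len(sub))
            bounds.append((int(sub.loc[lo, "start"]), int(sub.loc[hi - 1, "end"])))
            vals = cn[lo:hi]
            vals = vals[~np.isnan(vals)]
            if len(vals) < min_window_used:
                continue
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=result.model.sd_ddof))
            se = sd / math.sqrt(len(vals))
            if abs(mean - ploidy) < min_effect:
                continue
            if se == 0:
                deviant = mean != ploidy
            else:
                deviant = abs(mean - ploidy) / se > z_threshold
            if deviant:
                directions[w] = 1 if mean > ploidy else -1
        # merge same-direction runs of seed windows
        w = 0
        while w < n_windows:
            d = directions[w]
            if d == 0:
                w += 1
                continue
            run_start = w
            while w < n_windows and directions[w] == d:
                w += 1
            if w - run_start < min_consecutive:
                continue
            start = bounds[run_start][0]
            end = bounds[w - 1][1]
            est = result.region_cn(chrom, start, end)
            if not est.is_call:
                continue
            segments.append(
                CNSegment(
                    chrom=str(chrom),
                    start=start,
                    end=end,
                    cn_mean=est.cn_mean,
                    cn_rounded=est.cn_rounded,
                    ci_low=est.ci_low,
                    ci_high=est.ci_high,
                    n_bins=est.n_used,
                )
            )
    return segments


def segments_to_frame(segments: list[CNSegment]) -> pd.DataFrame:
    """Segment list as a BED-like table (empty call sets are valid)."""
    cols = ["chrom", "start", "end", "cn_mean", "cn_rounded",
            "ci_low", "ci_high", "n_bins"]
    if not segments:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([s.__dict__ for s in segments], columns=cols)
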