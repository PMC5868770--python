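"""GC-stratified copy-number model and confidence-scored estimates.

The model assumes that the mean read depth of a copy-number-neutral bin is
a function of its GC content alone.  Fitting estimates that function
non-parametrically: bins are stratified by discretised GC value *k* and the
copy-neutral expectation ``ref[k]`` is the mean coverage of the stratum.
Strata built from too few bins (fewer than ``s_cutoff``, default 50) or
with an abnormal mean coverage (outside ``[c_low, c_high]``, defaults 10
and 100, tuned for ~30x genomes) are rejected and never used.  Sex
chromosomes are excluded from the fit so hemizygosity cannot bias the
diploid baseline, and bins below an optional mapping-quality floor are
dropped.

A bin *r* with coverage ``C_r`` in an accepted stratum *k* then has copy
number

    CN_r = P * C_r / ref[k]

where ``P`` is the organism's ploidy (2 for human autosomes).  The copy
number of a region *R* is the mean of its per-bin values, with a normal
95% confidence interval

    CI = mean(CN_r) +/- 1.96 * sigma / sqrt(n)

where ``sigma`` is the standard deviation of the ``CN_r`` and ``n`` the
number of non-excluded bins.  Bins are excluded when their GC is masked
(``-1``) or their stratum was rejected.

``sum`` targets (a locus present as *m* near-identical reference copies)
multiply every per-bin value by *m* before averaging, so both the estimate
and its confidence interval are on the total-copy scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gc import GC_DECIMALS, MASKED
from .io import normalize_chrom, read_bins
from .regions import RegionSpec, Subregion

__all__ = [
    "CNEstimate",
    "GCReference",
    "CopyNumberModel",
    "CopyNumberResult",
    "build_reference",
    "round_half_away",
]

DEFAULT_EXCLUDED_CHROMS = ("X", "Y")
Z_95 = 1.96


def round_half_away(x: float) -> int:
    """Round to the nearest integer with halves away from zero.

    Avoids banker's-rounding surprises at x.5 copy numbers.
    """
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class CNEstimate:
    """A copy-number estimate for one target region.

    ``cn_mean`` is the average per-bin copy number, ``cn_rounded`` its
    integer rounding (half away from zero), ``ci_low``/``ci_high`` the 95%
    confidence bounds, ``n_used`` the number of non-excluded bins, and
    ``fraction_used`` the fraction of bins intersecting the region that
    were informative.  A region with no informative bin is a no-call:
    ``n_used == 0`` and the numeric fields are NaN.
    """

    cn_mean: float
    cn_rounded: int | None
    ci_low: float
    ci_high: float
    n_used: int
    n_total: int
    fraction_used: float
    label: str = ""

    @property
    def is_call(self) -> bool:
        return self.n_used > 0

    @property
    def ci_length(self) -> float:
        return self.ci_high - self.ci_low

    @classmethod
    def no_call(cls, n_total: int, label: str = "") -> "CNEstimate":
        return cls(math.nan, None, math.nan, math.nan, 0, n_total, 0.0, label)

    def as_row(self) -> dict:
        return {
            "region": self.label,
            "cn_mean": self.cn_mean,
            "cn_rounded": self.cn_rounded,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_used": self.n_used,
            "fraction_used": self.fraction_used,
        }


@dataclass(frozen=True)
class GCReference:
    """Copy-neutral expected coverage per discrete GC stratum.

    ``table`` is indexed by the GC value *k* (rounded to percent
    resolution) with columns ``mean`` (stratum mean coverage), ``count``
    (contributing bins) and ``accepted`` (both cutoffs satisfied).
    Rejected strata are retained for inspection but :meth:`lookup` treats
    them as excluded.
    """

    table: pd.DataFrame
    s_cutoff: int
    c_low: float
    c_high: float

    def lookup(self, k: float) -> float | None:
        """Expected coverage for stratum ``k``; None when the stratum was
        never observed or rejected (exclusion is a value, not an error)."""
        if k == MASKED:
            return None
        k = round(k, GC_DECIMALS)
        if k not in self.table.index:
            return None
        row = self.table.loc[k]
        return float(row["mean"]) if bool(row["accepted"]) else None

    @property
    def accepted(self) -> pd.DataFrame:
        return self.table[self.table["accepted"]]

    def to_csv(self, path: str) -> None:
        out = self.table.reset_index()
        out.columns = ["gc", "mean_coverage", "n_bins", "accepted"]
        out.to_csv(path, sep="\t", index=False)


def build_reference(
    bins: pd.DataFrame,
    s_cutoff: int = 50,
    c_low: float = 10.0,
    c_high: float = 100.0,
    mapq_min: float | None = None,
    excluded_chroms: Iterable[str] = DEFAULT_EXCLUDED_CHROMS,
) -> GCReference:
    """Estimate the copy-neutral coverage for every observed GC stratum.

    Contributing bins: unmasked GC, chromosome not in ``excluded_chroms``
    (sex chromosomes by default), and mean mapping quality at or above
    ``mapq_min`` when both are available.  A stratum is accepted when it
    has at least ``s_cutoff`` bins and its mean coverage lies within
    ``[c_low, c_high]``, boundaries inclusive.  The cutoffs guard against
    sparsely observed and systematically abnormal strata; the coverage
    bounds presuppose roughly 30x data and must be overridden for datasets
    far from that depth.
    """
    excluded = {normalize_chrom(c) for c in excluded_chroms}
    mask = (bins["gc"] != MASKED) & ~bins["chrom"].map(normalize_chrom).isin(excluded)
    if mapq_min is not None and "mapq" in bins.columns:
        mask &= bins["mapq"] >= mapq_min
    usable = bins[mask]
    if usable.empty:
        raise ValueError(
            "no usable bins to build a GC reference: every bin is masked or on "
            "an excluded chromosome"
        )
    strata = usable.groupby(usable["gc"].round(GC_DECIMALS))["coverage"].agg(
        mean="mean", count="size"
    )
    strata["accepted"] = (
        (strata["count"] >= s_cutoff)
        & (strata["mean"] >= c_low)
        & (strata["mean"] <= c_high)
    )
    if not strata["accepted"].any():
        raise ValueError(
            "every GC stratum was rejected; lower s_cutoff or adjust the "
            "coverage bounds c_low/c_high to match the dataset's depth"
        )
    strata.index.name = "gc"
    return GCReference(strata, s_cutoff, c_low, c_high)


class CopyNumberModel:
    """Copy-number model over a genome-wide bin table.

    Parameters
    ----------
    bins
        Bin table with columns ``chrom, start, end, gc, coverage`` and an
        optional ``mapq``, as produced by :func:`cnquant.io.read_bins` or
        the simulator.
    ploidy
        Baseline copy count of the organism (2 for human autosomes).  All
        estimates are reported on this scale; no sex inference is done, so
        a male X reports ~1 against the autosomal diploid baseline.
    s_cutoff, c_low, c_high, mapq_min, excluded_chroms
        Reference-fit quality controls, see :func:`build_reference`.
    sd_ddof
        Delta degrees of freedom of the confidence-interval standard
        deviation (0 = population convention, the default).
    """

    def __init__(
        self,
        bins: pd.DataFrame,
        ploidy: int = 2,
        s_cutoff: int = 50,
        c_low: float = 10.0,
        c_high: float = 100.0,
        mapq_min: float | None = None,
        excluded_chroms: Iterable[str] = DEFAULT_EXCLUDED_CHROMS,
        sd_ddof: int = 0,
    ) -> None:
        if ploidy <= 0:
            raise ValueError("ploidy must be a positive integer")
        missing = {"chrom", "start", "end", "gc", "coverage"} - set(bins.columns)
        if missing:
            raise ValueError(f"bin table is missing columns: {sorted(missing)}")
        bins = bins.copy()
        bins["chrom"] = bins["chrom"].map(normalize_chrom)
        self.bins = bins.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        self.ploidy = ploidy
        self.s_cutoff = s_cutoff
        self.c_low = c_low
        self.c_high = c_high
        self.mapq_min = mapq_min
        self.excluded_chroms = tuple(normalize_chrom(c) for c in excluded_chroms)
        self.sd_ddof = sd_ddof

    @classmethod
    def from_files(cls, gc_bed: str, coverage_bed: str, **kwargs) -> "CopyNumberModel":
        """Build a model from a GC BED and a coverage BED sharing one binning."""
        return cls(read_bins(gc_bed, coverage_bed), **kwargs)

    def fit(self) -> "CopyNumberResult":
        """Fit the GC-stratified copy-neutral reference and return results."""
        reference = build_reference(
            self.bins,
            s_cutoff=self.s_cutoff,
            c_low=self.c_low,
            c_high=self.c_high,
            mapq_min=self.mapq_min,
            excluded_chroms=self.excluded_chroms,
        )
        return CopyNumberResult(self, reference)


class CopyNumberResult:
    """Fitted copy-number model: the GC reference plus estimation methods."""

    def __init__(self, model: CopyNumberModel, reference: GCReference) -> None:
        self.model = model
        self.reference = reference
        # accepted-stratum lookup vector for fast per-bin normalisation
        acc = reference.accepted
        self._ref_map = acc["mean"]

    # -- per-bin copy number -------------------------------------------------

    def bin_cn(self, bins: pd.DataFrame | None = None) -> np.ndarray:
        """Per-bin copy numbers ``P * C / ref[k]``; NaN marks excluded bins
        (masked GC or rejected stratum)."""
        if bins is None:
            bins = self.model.bins
        k = bins["gc"].round(GC_DECIMALS)
        ref = k.map(self._ref_map)
        ref[bins["gc"] == MASKED] = np.nan
        return (self.model.ploidy * bins["coverage"] / ref).to_numpy()

    # -- region estimation ---------------------------------------------------

    def _select(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """Bins overlapping [start, end) on ``chrom`` by at least 1 bp."""
        b = self.model.bins
        chrom = normalize_chrom(chrom)
        return b[(b["chrom"] == chrom) & (b["end"] > start) & (b["start"] < end)]

    def _estimate(self, bins: pd.DataFrame, multiplier: int = 1,
                  label: str = "") -> CNEstimate:
        n_total = len(bins)
        if n_total == 0:
            return CNEstimate.no_call(0, label)
        cn = self.bin_cn(bins) * multiplier
        cn = cn[~np.isnan(cn)]
        n = len(cn)
        if n == 0:
            return CNEstimate.no_call(n_total, label)
        mean = float(np.mean(cn))
        sd = float(np.std(cn, ddof=self.model.sd_ddof)) if n > self.model.sd_ddof else 0.0
        half = Z_95 * sd / math.sqrt(n)
        return CNEstimate(
            cn_mean=mean,
            cn_rounded=round_half_away(mean),
            ci_low=mean - half,
            ci_high=mean + half,
            n_used=n,
            n_total=n_total,
            fraction_used=n / n_total,
            label=label,
        )

    def region_cn(self, chrom: str, start: int, end: int,
                  label: str | None = None) -> CNEstimate:
        """Copy-number estimate over one interval (0-based half-open)."""
        label = label if label is not None else f"{chrom}:{start}-{end}"
        return self._estimate(self._select(chrom, start, end), label=label)

    def composite_cn(self, spec: RegionSpec) -> CNEstimate:
        """Estimate a ``sum``/``avg`` target.

        ``avg`` pools the bins of every sub-region; ``sum`` additionally
        multiplies each per-bin copy number by the number of sub-regions,
        so the estimate (and its confidence interval) is the total copy
        count of the multi-copy locus.
        """
        pooled = pd.concat(
            [self._select(s.chrom, s.start, s.end) for s in spec.subregions]
        )
        m = len(spec.subregions) if spec.operation == "sum" else 1
        return self._estimate(pooled, multiplier=m, label=spec.label)

    def genotype(self, specs: Sequence[RegionSpec]) -> pd.DataFrame:
        """Estimate every target; returns the tab-table printed by the CLI."""
        return pd.DataFrame([self.composite_cn(s).as_row() for s in specs])

    # -- chromosome-scale estimation ------------------------------------------

    def chromosome_cn(self, chrom: str) -> CNEstimate:
        """GC-corrected copy number of a whole chromosome.

        Fractional values are meaningful: a mosaic loss of X in 30% of
        cells yields ~1.7 copies.
        """
        chrom = normalize_chrom(chrom)
        sel = self.model.bins[self.model.bins["chrom"] == chrom]
        if sel.empty:
            raise ValueError(f"chromosome {chrom!r} has no bins")
        return self._estimate(sel, label=chrom)

    def raw_coverage_cn(self, chrom: str) -> float:
        """Baseline chromosome copy number without GC correction:
        ``P * mean(coverage on chrom) / mean(autosomal coverage)``.

        Kept for benchmarking — when the chromosome's GC composition
        differs from the autosomal average, this estimate inherits the
        full GC bias that :meth:`chromosome_cn` removes.
        """
        b = self.model.bins
        chrom = normalize_chrom(chrom)
        on = b.loc[b["chrom"] == chrom, "coverage"]
        if on.empty:
            raise ValueError(f"chromosome {chrom!r} has no bins")
        auto = b.loc[~b["chrom"].isin(set(self.model.excluded_chroms) | {chrom}),
                     "coverage"]
        if auto.empty or auto.mean() == 0:
            raise ValueError("no autosomal coverage to scale against")
        return self.model.ploidy * float(on.mean()) / float(auto.mean())

    def call_segments(self, **kwargs):
        """Scan the genome for large CNV segments; see
        :func:`cnquant.segment.call_segments`."""
        from .segment import call_segments

        return call_segments(self, **kwargs)

    # -- reporting -------------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary (reference quality and parameters)."""
        t = self.reference.table
        acc = t[t["accepted"]]
        lines = [
            "Copy-number model fit",
            "=" * 54,
            f"{'Bins (total)':<34}{len(self.model.bins):>20}",
            f"{'Bins masked (GC = -1)':<34}{int((self.model.bins['gc'] == MASKED).sum()):>20}",
            f"{'GC strata observed':<34}{len(t):>20}",
            f"{'GC strata accepted':<34}{len(acc):>20}",
            f"{'Median copy-neutral coverage':<34}{acc['mean'].median():>20.3f}",
            f"{'Ploidy P':<34}{self.model.ploidy:>20}",
            f"{'S_cutoff (min bins/stratum)':<34}{self.model.s_cutoff:>20}",
            f"{'Coverage bounds [c_low, c_high]':<34}"
            f"{f'[{self.model.c_low:g}, {self.model.c_high:g}]':>20}",
            f"{'Excluded chromosomes':<34}{','.join(self.model.excluded_chroms) or '-':>20}",
            "=" * 54,
        ]
        return "\n".join(lines)
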