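"""Coverage-level WGS simulator with known copy-number truth.

The generator emits the exact GC/coverage bin dialect the rest of the
package consumes, together with a truth table, so the full estimation
pipeline can be exercised end-to-end without external data.  It models

* per-bin GC content drawn from a two-component normal mixture emulating
  the mammalian genomic GC distribution (bulk around 41% GC with a
  GC-rich shoulder), rounded to percent resolution and clipped to
  [0.25, 0.75];
* a small fraction of masked bins (GC = -1) mimicking high-N and
  low-complexity regions;
* read counts per bin that are negative-binomial (gamma-mixed Poisson),
  i.e. overdispersed relative to Poisson as real WGS coverage is, with
  mean  ``depth * gc_bias(GC) * CN / 2``  per base;
* an optional unimodal GC-bias curve (default: peak efficiency at GC
  0.45 falling off ~20% at the extremes, a mild PCR-free-library-like
  bias);
* CNVs injected as interval rescalings, and mosaic whole-chromosome
  aneuploidies as coverage mixtures ``(1 - f) * 2 + f * clone_cn``.

What it does not model: mappability structure, alignment artefacts,
inter-bin correlation, and read-level errors — so recovery results on
simulated data bound what is attainable on real genomes from above.

One integer seed drives a single generator stream; regeneration from the
same parameters and seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gc import GC_DECIMALS, MASKED

__all__ = [
    "SimulationTruth",
    "default_gc_bias",
    "flat_gc_bias",
    "steep_gc_bias",
    "simulate_genome_bins",
    "inject_cnv",
    "simulate_mosaic_chromosome",
]


def default_gc_bias(gc: np.ndarray) -> np.ndarray:
    """Unimodal coverage-efficiency curve: 1.0 at GC 0.45, ~0.8 at the
    extremes (mild, PCR-free-like)."""
    gc = np.asarray(gc, dtype=float)
    return 0.8 + 0.2 * np.exp(-((gc - 0.45) ** 2) / (2 * 0.15**2))


def steep_gc_bias(gc: np.ndarray) -> np.ndarray:
    """Strong bias curve (~60% falloff), emulating heavy library GC bias."""
    gc = np.asarray(gc, dtype=float)
    return 0.4 + 0.6 * np.exp(-((gc - 0.45) ** 2) / (2 * 0.12**2))


def flat_gc_bias(gc: np.ndarray) -> np.ndarray:
    """No GC dependence (bias correction becomes the identity)."""
    return np.ones_like(np.asarray(gc, dtype=float))


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset.

    ``baseline`` maps each chromosome to its background copy number
    (possibly fractional after a mosaic event); ``events`` lists injected
    interval CNVs.  ``cn_at`` resolves the true copy number of any
    interval that does not straddle an event boundary.
    """

    baseline: dict[str, float]
    events: list[tuple[str, int, int, float]] = field(default_factory=list)
    mean_depth: float = 30.0
    seed: int | None = None

    def cn_at(self, chrom: str, start: int, end: int) -> float:
        for c, s, e, copies in self.events:
            if c == chrom and start >= s and end <= e:
                return copies
            if c == chrom and start < e and end > s:
                raise ValueError(
                    f"{chrom}:{start}-{end} straddles an injected event boundary"
                )
        return self.baseline[chrom]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chrom": c, "start": -1, "end": -1, "cn": cn, "kind": "baseline"}
            for c, cn in sorted(self.baseline.items())
        ] + [
            {"chrom": c, "start": s, "end": e, "cn": cn, "kind": "event"}
            for c, s, e, cn in self.events
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "cn", "kind"])

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _draw_gc(rng: np.random.Generator, n: int, shift: float = 0.0) -> np.ndarray:
    """GC mixture: 85% bulk N(0.41, 0.06) + 15% GC-rich N(0.55, 0.05)."""
    comp = rng.random(n) < 0.85
    gc = np.where(
        comp,
        rng.normal(0.41 + shift, 0.06, n),
        rng.normal(0.55 + shift, 0.05, n),
    )
    return np.clip(gc, 0.25, 0.75).round(GC_DECIMALS)


def _nb_coverage(
    rng: np.random.Generator,
    mean_bases: np.ndarray,
    dispersion: float,
    bin_size: int,
) -> np.ndarray:
    """Per-bin mean depth from overdispersed base counts.

    Counts are gamma-mixed Poisson with variance ``mu + dispersion*mu^2``.
    ``dispersion = 0`` disables sampling entirely (coverage equals its
    expectation exactly), which is the noiseless limit used by exact
    tests; negative values are rejected.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    mean_bases = np.maximum(np.asarray(mean_bases, dtype=float), 0.0)
    if dispersion == 0:
        return mean_bases / bin_size
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean_bases * dispersion)
    counts = rng.poisson(lam)
    return counts / bin_size


def simulate_genome_bins(
    n_chroms: int = 2,
    chrom_length: int = 1_000_000,
    bin_size: int = 100,
    mean_depth: float = 30.0,
    gc_bias: Callable[[np.ndarray], np.ndarray] = default_gc_bias,
    dispersion: float = 0.002,
    masked_fraction: float = 0.02,
    chrom_names: Sequence[str] | None = None,
    chrom_gc_shift: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate a diploid genome's GC/coverage bin table.

    Parameters
    ----------
    n_chroms, chrom_length, bin_size
        Genome geometry; chromosomes are named "1", "2", ... unless
        ``chrom_names`` is given (use "X" to exercise sex-chromosome
        handling).
    mean_depth
        Haploid-pair (copy-number 2) mean depth at peak GC efficiency.
    gc_bias
        Coverage-efficiency curve evaluated at each bin's GC.
    dispersion
        Negative-binomial overdispersion of per-bin base counts.
    masked_fraction
        Fraction of bins whose GC is set to the ``-1`` sentinel.
    chrom_gc_shift
        Optional per-chromosome shift of the GC mixture location, used to
        give a chromosome a GC composition unlike the autosomal average.
    seed
        Single integer governing all randomness.
    """
    if chrom_names is None:
        chrom_names = [str(i + 1) for i in range(n_chroms)]
    if len(chrom_names) != n_chroms:
        raise ValueError("chrom_names length must equal n_chroms")
    rng = np.random.default_rng(seed)
    shift = dict(chrom_gc_shift or {})
    frames = []
    for name in chrom_names:
        starts = np.arange(0, chrom_length, bin_size)
        ends = np.minimum(starts + bin_size, chrom_length)
        n = len(starts)
        gc = _draw_gc(rng, n, shift.get(name, 0.0))
        masked = rng.random(n) < masked_fraction
        mean_bases = mean_depth * gc_bias(gc) * (ends - starts)
        coverage = _nb_coverage(rng, mean_bases, dispersion, bin_size)
        gc = np.where(masked, MASKED, gc)
        frames.append(
            pd.DataFrame(
                {"chrom": name, "start": starts, "end": ends,
                 "gc": gc, "coverage": coverage}
            )
        )
    bins = pd.concat(frames, ignore_index=True)
    truth = SimulationTruth(
        baseline={name: 2.0 for name in chrom_names},
        mean_depth=mean_depth,
        seed=seed,
    )
    return bins, truth


def inject_cnv(
    bins: pd.DataFrame,
    truth: SimulationTruth,
    chrom: str,
    start: int,
    end: int,
    copies: float,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Rescale coverage in [start, end) on ``chrom`` to ``copies`` and
    record the event.  Overlapping a previously injected event is an
    error (stacked rescalings would corrupt the recorded truth)."""
    if copies < 0:
        raise ValueError("copies must be non-negative")
    for c, s, e, _ in truth.events:
        if c == chrom and start < e and end > s:
            raise ValueError(
                f"event {chrom}:{start}-{end} overlaps existing event {c}:{s}-{e}"
            )
    bins = bins.copy()
    in_region = (bins["chrom"] == chrom) & (bins["end"] > start) & (bins["start"] < end)
    if not in_region.any():
        raise ValueError(f"no bins in {chrom}:{start}-{end}")
    bins.loc[in_region, "coverage"] *= copies / 2.0
    truth = SimulationTruth(
        baseline=dict(truth.baseline),
        events=truth.events + [(chrom, start, end, float(copies))],
        mean_depth=truth.mean_depth,
        seed=truth.seed,
    )
    return bins, truth


def simulate_mosaic_chromosome(
    bins: pd.DataFrame,
    truth: SimulationTruth,
    chrom: str,
    clone_cn: float,
    fraction: float,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Apply a mosaic aneuploidy: a clone at ``clone_cn`` copies in a
    ``fraction`` of cells gives effective copy number
    ``(1 - fraction) * 2 + fraction * clone_cn`` for the whole chromosome."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be within [0, 1]")
    effective = (1 - fraction) * 2.0 + fraction * clone_cn
    bins = bins.copy()
    on = bins["chrom"] == chrom
    if not on.any():
        raise ValueError(f"chromosome {chrom!r} has no bins")
    bins.loc[on, "coverage"] *= effective / 2.0
    baseline = dict(truth.baseline)
    baseline[chrom] = effective
    truth = SimulationTruth(
        baseline=baseline,
        events=list(truth.events),
        mean_depth=truth.mean_depth,
        seed=truth.seed,
    )
    return bins, truth
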