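"""Per-bin GC content and uninformative-bin masking.

Copy-number estimation from read depth requires a per-bin GC profile of the
reference genome: read depth depends on fragment GC content, so coverage is
normalised within GC strata.  Bins that carry no usable signal are masked by
setting their GC value to the sentinel ``-1``:

* bins whose fraction of undetermined bases (``N``) is at or above a
  threshold (default 20%), and
* low-complexity (repetitive) bins, detected from the frequency of the most
  frequent overlapping 3-mer, ``f3mer_max = count(3mer_max) / (L - 2)``.
  A bin is repetitive when ``f3mer_max`` strictly exceeds 0.2.  For a
  maximally complex sequence every 3-mer is equally frequent and
  ``f3mer_max`` approaches 1/64.

Masked bins are excluded from reference construction and copy-number
estimation downstream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd
from pyfaidx import Fasta

__all__ = [
    "MASKED",
    "SequenceBin",
    "gc_fraction",
    "n_content_mask",
    "complexity_frequency",
    "mask_low_complexity",
    "profile_sequence_bin",
    "profile_genome",
    "write_gc_bed",
]

#: Sentinel GC value marking a bin as uninformative.
MASKED = -1.0

#: Number of decimals GC fractions are rounded to; defines the discrete GC
#: strata used for reference construction (percent resolution for 100 bp bins).
GC_DECIMALS = 2

_GC_BASES = frozenset("GCgcSs")
_N_BASES = frozenset("Nn")


@dataclass(frozen=True)
class SequenceBin:
    """A genomic bin with its (possibly masked) GC fraction.

    Coordinates are 0-based half-open.  ``gc`` is a fraction in [0, 1] or
    the sentinel ``-1`` when the bin is masked.
    """

    chrom: str
    start: int
    end: int
    gc: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty bin {self.chrom}:{self.start}-{self.end}")


def gc_fraction(sequence: str) -> float:
    """GC fraction of ``sequence`` among called (non-N) bases.

    Case-insensitive; the IUPAC code S (G or C) counts as GC.  Ns are
    excluded from the denominator so that bins surviving the N-content mask
    do not have their GC deflated by undetermined bases.  Returns 0.0 for a
    sequence of only S... only Ns (such bins are always masked upstream).
    """
    if not sequence:
        raise ValueError("cannot compute GC content of an empty sequence")
    n_gc = sum(1 for b in sequence if b in _GC_BASES)
    n_undet = sum(1 for b in sequence if b in _N_BASES)
    denom = len(sequence) - n_undet
    if denom == 0:
        return 0.0
    return n_gc / denom


def n_content_mask(sequence: str, n_threshold: float = 0.20) -> float:
    """GC fraction of ``sequence``, or ``-1`` if its N content is at or
    above ``n_threshold`` (boundary inclusive)."""
    if not 0 < n_threshold <= 1:
        raise ValueError("n_threshold must be in (0, 1]")
    if not sequence:
        raise ValueError("cannot compute N content of an empty sequence")
    n_undet = sum(1 for b in sequence if b in _N_BASES)
    if n_undet / len(sequence) >= n_threshold:
        return MASKED
    return gc_fraction(sequence)


def complexity_frequency(sequence: str) -> float:
    """Frequency of the most frequent overlapping 3-mer.

    ``f3mer_max = max 3-mer count / (L - 2)`` where L is the sequence
    length; there are L - 2 overlapping 3-mers.  A homopolymer scores 1.0;
    a maximally complex sequence approaches 1/64.
    """
    L = len(sequence)
    if L < 3:
        raise ValueError(f"need at least 3 bases to assess complexity, got {L}")
    seq = sequence.upper()
    counts = Counter(seq[i : i + 3] for i in range(L - 2))
    return max(counts.values()) / (L - 2)


def mask_low_complexity(
    gc: float, f3mermax: float, complexity_threshold: float = 0.2
) -> float:
    """Return ``-1`` if ``f3mermax`` strictly exceeds the threshold, else
    ``gc`` unchanged.  The boundary value itself is not masked."""
    if not 0 < complexity_threshold <= 1:
        raise ValueError("complexity_threshold must be in (0, 1]")
    if f3mermax > complexity_threshold:
        return MASKED
    return gc


def profile_sequence_bin(
    sequence: str,
    n_threshold: float = 0.20,
    complexity_threshold: float = 0.2,
) -> float:
    """Apply both masks to one bin sequence and return its GC value.

    The two masks commute: either may fire independently and the result is
    ``-1`` as soon as one does.  Unmasked values are rounded to the discrete
    GC strata used everywhere downstream.
    """
    gc = n_content_mask(sequence, n_threshold)
    if gc == MASKED:
        return MASKED
    gc = mask_low_complexity(gc, complexity_frequency(sequence), complexity_threshold)
    if gc == MASKED:
        return MASKED
    return round(gc, GC_DECIMALS)


def profile_genome(
    fasta_path: str,
    bin_size: int = 100,
    n_threshold: float = 0.20,
    complexity_threshold: float = 0.2,
) -> pd.DataFrame:
    """Tile every contig of an indexed FASTA into non-overlapping bins and
    compute each bin's masked GC fraction.

    The last bin of a contig may be shorter than ``bin_size``; it is emitted
    with its true length so the tiling covers every position exactly once.
    Bins shorter than 3 bp (possible only for tiny tail bins) are masked.

    Returns a DataFrame with columns ``chrom, start, end, gc``.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be positive")
    fasta = Fasta(fasta_path, as_raw=True, sequence_always_upper=True)
    names = list(fasta.keys())
    if len(set(names)) != len(names):
        raise ValueError("duplicate chromosome names in FASTA")
    rows: list[tuple[str, int, int, float]] = []
    for name in names:
        length = len(fasta[name])
        for start in range(0, length, bin_size):
            end = min(start + bin_size, length)
            seq = str(fasta[name][start:end])
            if end - start < 3:
                gc = MASKED
            else:
                gc = profile_sequence_bin(seq, n_threshold, complexity_threshold)
            rows.append((name, start, end, gc))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gc"])


def write_gc_bed(profile: pd.DataFrame, path: str) -> None:
    """Write a GC profile as 4-column tab-separated BED-like text."""
    profile.to_csv(path, sep="\t", header=False, index=False,
                   columns=["chrom", "start", "end", "gc"])
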