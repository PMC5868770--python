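# Methods

## Model and assumptions

`cnquant` estimates copy number from binned read depth under three
assumptions: (i) the expected depth of a copy-neutral bin is a function of
its GC content only; (ii) depth scales linearly with copy number; and
(iii) per-bin depths within a region are exchangeable, so the region mean
is normally distributed by the central limit theorem. The GC dependence is
estimated non-parametrically from the sample itself — the mean coverage of
every discretised GC stratum — rather than by a smooth fit, which keeps
the correction assumption-free at the cost of discarding strata with too
few bins. No paired or panel-of-normals reference is needed: a single
genome is sufficient.

The per-bin estimate is CN_r = P·C_r/ref[k]; a region's estimate is the
mean of its non-excluded bins with the 95% normal interval
mean ± 1.96·σ/√n. `sum` targets multiply every per-bin value by the number
of sub-regions before averaging, so the estimate and its interval are on
the total-copy scale of a multi-copy locus; `avg` pools sub-region bins
unweighted.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `bin_size` | 100 bp | genome tiling; matches the upstream coverage extractor |
| `n_threshold` | 0.20 | mask a bin when its fraction of N bases is ≥ this (inclusive) |
| `complexity_threshold` | 0.2 | mask when the most frequent 3-mer frequency, max count/(L−2), exceeds this (strict) |
| `s_cutoff` | 50 bins | minimum stratum size for an accepted GC reference entry |
| `c_low`, `c_high` | 10, 100 × | accepted range of a stratum's mean coverage, boundaries inclusive; presupposes ~30× data and **must be overridden for datasets far from 30×** |
| `mapq_min` | unset | if set and the coverage file has a mapping-quality column, bins below it are excluded from the reference fit |
| `excluded_chroms` | X, Y | chromosomes left out of the reference (hemizygosity would bias it); names compared after stripping a `chr` prefix |
| `ploidy` | 2 | baseline copy count; estimates are always on the autosomal-diploid scale (male chrX reports ≈ 1); no sex inference is attempted |
| `sd_ddof` | 0 | population-sd convention for the CI σ; 1 switches to the sample convention |

GC values are discretised to two decimals (percent resolution — the
natural granularity of 100 bp bins), giving at most 101 strata; the same
rounding is applied on both the profile and lookup sides so strata always
align. The coverage bounds are applied to the stratum mean, not to
individual bins; no outlier rejection is done within a stratum.

Coordinate conventions: both BED inputs are 0-based half-open; the
`chrom:start-end` region syntax is 1-based inclusive (samtools style) and
converted on parsing. A bin belongs to a region if it overlaps it by at
least one base — with 100 bp bins the edge effect is negligible and
inclusion maximises n. Rounding of copy numbers is half-away-from-zero,
so x.5 always rounds up in magnitude. The GC denominator excludes N
bases: a bin that survives the 20% N mask should not have its GC deflated
by the Ns it does contain. Soft-masked (lowercase) bases are treated as
their uppercase equivalents — soft-masking marks repeats, and repeats are
handled by the complexity filter independently.

## Annotation and filtering

VCF annotation adds namespaced `CNQ_*` INFO tags (declared in the header,
overwritten on re-annotation, so the operation is idempotent) to every
intrachromosomal record; breakends and symbolic records without a usable
END pass through untouched. The deletion filter retains records of length
≥ 500 bp whose mean copy number is below ploidy − 0.5 (i.e. rounding
below the ploidy); the margin is exposed as a flag. This consistency rule
is this package's own reconstruction of a depth-based deletion filter —
minimal, declared, and configurable — and the PASS intersection is
available as a stricter combined filter. Annotated no-call deletions
(entirely masked regions) are removed: they carry no depth support and
masked regions are enriched for artefacts.

## CNV and aneuploidy scanning

The segment caller is deliberately simple and fully deterministic: the
per-bin copy-number signal is scanned in non-overlapping windows of
`window_bins` (default 1000 bins = 100 kb); a window seeds when its mean
deviates from the ploidy by more than `z_threshold` (default 5) standard
errors **and** by at least `min_effect` (default 0.3) copies; adjacent
same-direction seeds merge, runs shorter than `min_consecutive` (default
3) windows are dropped, and each surviving run is re-scored as a region
estimate. The effect-size guard exists because with ~1000 informative
bins a window's standard error is of order 0.002 copies, so a pure z rule
would fire on sub-percent systematic wobble of the GC fit rather than on
genuine events; 0.3 copies is far below the 0.5 that separates integer
states yet far above that wobble. Defaults target events of roughly a
megabase and larger at ~30×; all parameters are exposed.

Whole-chromosome and mosaic events are read from the fractional
chromosome-level estimate instead — a mosaic loss of X in a fraction f of
cells has effective copy number 2(1−f) + k·f, which the chromosome mean
tracks linearly; no rounding is forced at chromosome scale. The
uncorrected baseline (chromosome mean coverage over autosomal mean
coverage, times ploidy) is kept alongside for benchmarking: the
difference between the two isolates exactly the GC correction.

## The simulator

The generator emulates binned WGS coverage, not reads: per-bin GC from a
two-component normal mixture (85% bulk at 0.41 ± 0.06, 15% GC-rich at
0.55 ± 0.05, clipped to [0.25, 0.75] and rounded to percent), a small
masked fraction (2%), and per-bin base counts that are gamma-mixed
Poisson (variance μ + d·μ², default d = 0.002) with mean
depth · bias(GC) · CN/2 — real WGS coverage is overdispersed relative to
Poisson, and the dispersion parameter is exposed. Default depth is 30×
with 100 bp bins. The default bias curve is unimodal with peak efficiency
at GC 0.45 and ~20% falloff at the extremes (PCR-free-like); a steep
variant (~60% falloff) is provided for stress-testing the correction, and
a flat one for exact arithmetic (with `dispersion=0` coverage equals its
expectation exactly). One integer seed drives a single generator stream;
regeneration is bit-identical.

What the simulator does **not** model: mappability structure, alignment
artefacts, inter-bin correlation, batch effects, or read-level error.
Passing the closed-loop tests therefore demonstrates correctness of the
estimation machinery under the stated noise model, and bounds from above
— not guarantees — performance on real genomes.

## Problem sizes and test design

The closed-loop recovery check runs 100 seeded simulations of a
2 × 1 Mb genome (20 000 bins) with one injected CNV of 0–10 copies
spanning 80 bins, and requires the rounded estimate to equal the truth in
≥ 95 of them. The background genome is large relative to the event
because the reference is fitted from the whole sample: an event occupying
a visible fraction of the genome inflates its own normalisation strata
(measurably so at toy scale), exactly as a whole-genome fit would be
contaminated in reality only by a substantial aneuploidy. The mosaic grid
covers losses (clone at 1 copy) and gains (clone at 3) at cell fractions
0–1 in steps of 0.1 on a 3 × 300 kb genome whose X chromosome is GC-poor
(mixture shifted by −0.06) under the steep bias curve — conditions chosen
so the uncorrected baseline is materially biased (≈ 0.16 copies MAE)
while the corrected estimator stays within ±0.1 copies of truth. The
filter workflow uses 20 true 10 kb deletions and 20 copy-neutral decoys
on a 2 × 1 Mb genome. These sizes keep every stochastic check
deterministic under its fixed seeds while leaving the statistics far from
their thresholds.

## Known limitations

* The reference is fitted from the analysed sample, so a large fraction
  of the genome at non-neutral copy number (e.g. high-grade tumour
  aneuploidy) biases all estimates toward neutrality.
* Strata outside the accepted coverage bounds (defaults tuned for ~30×)
  silently shrink the informative bin fraction; the `fraction_used`
  output should be inspected, and the bounds overridden, for unusual
  depths.
* The normal CI understates uncertainty when per-bin noise is correlated
  (GC-adjacent waviness, mappability runs), since bins are treated as
  independent.
* `sum` targets assume reads distribute evenly across the reference
  copies of the locus; paralog-specific estimates are out of scope, as
  are allele-specific copy numbers and integer-state smoothing (HMMs).
* Sub-bin breakpoint precision is out of scope; the segment caller
  complements, rather than replaces, split-read/discordant-pair callers.
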