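# cnquant

GC-corrected, confidence-scored copy-number estimation of arbitrary —
possibly multi-locus — genomic regions from whole-genome-sequencing
coverage profiles.

## The problem

Many clinically and phenotypically important loci are *multi-allelic*
copy-number variants: the salivary amylase gene *AMY1*, for instance, is
represented in the human reference as three near-identical genes
(*AMY1A/B/C*) and segregates in the population at anywhere from 2 to 15+
total copies. Split-read and discordant-pair structural-variant callers
cannot genotype such regions, and most read-depth CNV callers are built
for segmentation, not for asking "how many copies of *this* region does
*this one sample* carry, and how confident are we?". `cnquant` answers
that question from a single genome's binned read depth, and additionally
annotates/filters SV call sets by copy-number consistency and detects
large CNVs and (mosaic) aneuploidies.

## The model

The genome is tiled into non-overlapping bins (100 bp by default), each a
tuple *(chr, start, end, GC, C)* of GC content and mean coverage. Because
sequencing depth depends on fragment GC content, the copy-neutral
expectation is estimated per discretised GC value *k* as the mean coverage
GC<sup>ref</sup><sub>k</sub> of all bins with that GC — excluding masked
bins (≥20% N, or a most-frequent-3-mer frequency above 0.2), sex
chromosomes, and strata with fewer than *S*<sub>cutoff</sub> = 50 bins or
an abnormal mean coverage (outside [10, 100] at ~30× depth). Each bin *r*
in a target region *R* then has

&nbsp;&nbsp;&nbsp;&nbsp;CN<sub>r</sub> = *P* · C<sub>r</sub> / GC<sup>ref</sup><sub>k</sub>,

with *P* the ploidy, and the region estimate is the mean over bins with a
normal 95% confidence interval

&nbsp;&nbsp;&nbsp;&nbsp;CI = CN<sup>tot</sup><sub>r</sub> ± 1.96 σ/√n.

A multi-copy locus is genotyped with a `sum` target — each per-bin value
is multiplied by the number of sub-regions, so the estimate is the total
copy count — while `avg` pools sub-regions to skip low-mappability
stretches:

```
sum(chr1:104198141-104207173|chr1:104230039-104239075|chr1:104292276-104301311)
avg(chr2:1-1000)
```

## Worked example

Genotype a three-locus tandem gene family in a simulated genome whose
carrier has 8 total copies:

```python
import cnquant as cq

bins, truth = cq.simulate_genome_bins(n_chroms=2, chrom_length=1_000_000, seed=42)
for start in (200_000, 230_000, 260_000):         # three reference loci
    bins, truth = cq.inject_cnv(bins, truth, "1", start, start + 9_000, 8 / 3)

result = cq.CopyNumberModel(bins).fit()
print(result.summary())

spec = cq.parse_region("sum(1:200001-209000|1:230001-239000|1:260001-269000)")
est = result.composite_cn(spec)
print(f"copy number : {est.cn_mean:.2f} (rounded {est.cn_rounded})")
print(f"95% CI      : [{est.ci_low:.2f}, {est.ci_high:.2f}]")
print(f"bins used   : {est.n_used} ({est.fraction_used:.0%} of region)")
```

```
Copy-number model fit
======================================================
Bins (total)                                     20000
Bins masked (GC = -1)                              402
GC strata observed                                  47
GC strata accepted                                  39
Median copy-neutral coverage                    29.085
Ploidy P                                             2
S_cutoff (min bins/stratum)                         50
Coverage bounds [c_low, c_high]              [10, 100]
Excluded chromosomes                               X,Y
======================================================
copy number : 7.95 (rounded 8)
95% CI      : [7.91, 8.00]
bins used   : 261 (97% of region)
```

The fit summary reports how many GC strata passed the quality cutoffs and
the copy-neutral depth; the estimate recovers the simulated 8 copies with
a tight confidence interval, and 97% of the region's bins were
informative (the rest fell in masked bins or rejected strata).

The same fitted result drives the other workflows: `result.chromosome_cn("X")`
gives a fractional, mosaic-aware chromosome copy number (with
`result.raw_coverage_cn("X")` as the uncorrected baseline),
`result.call_segments()` scans for large CNVs, and
`cnquant.annotate_vcf` / `cnquant.filter_deletions` tag an SV VCF with
`CNQ_*` INFO fields and drop deletion calls that are not copy-number
consistent. Everything is also reachable from the `cnquant` command line
(`gc`, `genotype`, `annotate`, `filter`, `call`, `simulate`, `eval`).

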