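"""Per-bin and per-region copy-number formulas, sum/avg targets,
region-file parsing, and the confidence interval."""

import math

import numpy as np
import pandas as pd
import pytest

import cnquant as cq
from cnquant import CopyNumberModel, parse_region, parse_region_file, round_half_away
from cnquant.model import CopyNumberResult
from conftest import make_bins


def result_with(bins, reference, **model_kw):
    """Wire a hand-made reference to a bin table, bypassing the fit."""
    return CopyNumberResult(CopyNumberModel(bins, **model_kw), reference)


class TestBinCN:
    def test_direct_formula(self, constant_reference):
        res = result_with(make_bins(n=1, coverage=45.0), constant_reference)
        assert res.bin_cn() == pytest.approx([3.0])  # 2 * 45 / 30

    def test_zero_coverage_is_homozygous_deletion(self, constant_reference):
        res = result_with(make_bins(n=1, coverage=0.0), constant_reference)
        assert res.bin_cn() == pytest.approx([0.0])

    def test_masked_gc_excluded(self, constant_reference):
        res = result_with(make_bins(n=1, gc=-1.0, coverage=45.0),
                          constant_reference)
        assert np.isnan(res.bin_cn()).all()

    def test_rejected_stratum_excluded(self, constant_reference):
        res = result_with(make_bins(n=1, gc=0.70, coverage=45.0),
                          constant_reference)
        assert np.isnan(res.bin_cn()).all()

    def test_ploidy_scales_linearly(self, constant_reference):
        res = result_with(make_bins(n=1, coverage=45.0), constant_reference,
                          ploidy=4)
        assert res.bin_cn() == pytest.approx([6.0])

    def test_nonpositive_ploidy_rejected(self):
        with pytest.raises(ValueError, match="ploidy"):
            CopyNumberModel(make_bins(n=1), ploidy=0)


class TestRegionCN:
    def test_constant_region_has_degenerate_ci(self, constant_reference):
        res = result_with(make_bins(n=4, coverage=30.0), constant_reference)
        est = res.region_cn("1", 0, 400)
        assert est.cn_mean == 2.0
        assert (est.ci_low, est.ci_high) == (2.0, 2.0)
        assert est.n_used == 4 and est.fraction_used == 1.0

    def test_hand_computed_ci_population_sd(self, constant_reference):
        # CN values {1, 3}: mean 2, population sd 1 (sample sd would be
        # sqrt(2)); half-width = 1.96 * 1 / sqrt(2)
        bins = make_bins(n=2)
        bins.loc[0, "coverage"] = 15.0
        bins.loc[1, "coverage"] = 45.0
        est = result_with(bins, constant_reference).region_cn("1", 0, 200)
        half = 1.96 / math.sqrt(2)
        assert est.cn_mean == pytest.approx(2.0)
        assert est.ci_low == pytest.approx(2.0 - half)
        assert est.ci_high == pytest.approx(2.0 + half)

    def test_sample_sd_convention_is_switchable(self, constant_reference):
        bins = make_bins(n=2)
        bins.loc[0, "coverage"] = 15.0
        bins.loc[1, "coverage"] = 45.0
        est = result_with(bins, constant_reference, sd_ddof=1).region_cn("1", 0, 200)
        assert est.ci_high - est.cn_mean == pytest.approx(1.96 * math.sqrt(2) / math.sqrt(2))

    def test_three_bin_hand_example(self, constant_reference):
        # coverages 30, 45, 15 -> CN {2, 3, 1}; mean 2; pop sd sqrt(2/3)
        bins = make_bins(n=3)
        bins["coverage"] = [30.0, 45.0, 15.0]
        est = result_with(bins, constant_reference).region_cn("1", 0, 300)
        assert est.cn_mean == pytest.approx(2.0)
        assert est.ci_high - est.cn_mean == pytest.approx(
            1.96 * math.sqrt(2 / 3) / math.sqrt(3))
        assert est.cn_rounded == 2

    def test_half_excluded_region(self, constant_reference):
        bins = make_bins(n=4, coverage=30.0)
        bins.loc[2:, "gc"] = -1.0
        est = result_with(bins, constant_reference).region_cn("1", 0, 400)
        assert est.fraction_used == 0.5 and est.n_used == 2

    def test_fully_excluded_region_is_a_no_call(self, constant_reference):
        bins = make_bins(n=4, coverage=30.0, gc=-1.0)
        est = result_with(bins, constant_reference).region_cn("1", 0, 400)
        assert not est.is_call
        assert est.n_used == 0 and math.isnan(est.cn_mean)

    def test_partial_overlap_counts_bins(self, constant_reference):
        res = result_with(make_bins(n=10, coverage=30.0), constant_reference)
        # region clips into bins 1..3 by at least 1 bp each
        est = res.region_cn("1", 150, 350)
        assert est.n_used == 3


class TestCompositeCN:
    def test_sum_of_three_diploid_loci_is_six(self, constant_reference):
        res = result_with(make_bins(n=100, coverage=30.0), constant_reference)
        spec = parse_region("sum(1:1-2000|1:3001-5000|1:6001-8000)")
        est = res.composite_cn(spec)
        assert est.cn_mean == pytest.approx(6.0)
        assert est.cn_rounded == 6

    def test_avg_pools_subregion_bins(self, constant_reference):
        res = result_with(make_bins(n=100, coverage=30.0), constant_reference)
        est = res.composite_cn(parse_region("avg(1:1-2000|1:5001-8000)"))
        assert est.cn_mean == pytest.approx(2.0)
        assert est.n_used == 50

    def test_sum_over_one_subregion_is_region_cn(self, constant_reference):
        res = result_with(make_bins(n=100, coverage=30.0), constant_reference)
        one = res.composite_cn(parse_region("sum(1:1-2000)"))
        plain = res.region_cn("1", 0, 2000)
        assert one.cn_mean == plain.cn_mean
        assert (one.ci_low, one.ci_high) == (plain.ci_low, plain.ci_high)

    def test_sum_equals_m_times_avg_and_ci_scales(self, diploid_result):
        res, _ = diploid_result
        subs = "1:1-30000|1:50001-80000|1:100001-130000"
        s = res.composite_cn(parse_region(f"sum({subs})"))
        a = res.composite_cn(parse_region(f"avg({subs})"))
        assert s.cn_mean == pytest.approx(3 * a.cn_mean)
        assert s.ci_length == pytest.approx(3 * a.ci_length)


class TestRegionFileParsing:
    def test_sum_line_with_three_subregions(self):
        spec = parse_region(
            "sum(chr1:104198141-104207173|chr1:104230039-104239075"
            "|chr1:104292276-104301311)")
        assert spec.operation == "sum" and len(spec.subregions) == 3
        # samtools-style 1-based inclusive -> 0-based half-open
        assert spec.subregions[0].start == 104198140
        assert spec.subregions[0].end == 104207173

    def test_avg_line(self):
        spec = parse_region("avg(chr2:1-1000)")
        assert spec.operation == "avg"
        assert spec.subregions[0] == cq.Subregion("2", 0, 1000)

    @pytest.mark.parametrize("line", [
        "mul(chr1:1-10)",
        "sum(chr1:10-1)",
        "sum(chr1:1)",
        "sum()",
    ])
    def test_malformed_lines_rejected(self, line):
        with pytest.raises(ValueError):
            parse_region(line)

    def test_file_errors_carry_line_numbers(self):
        text = "avg(chr2:1-1000)\nmul(chr1:1-10)\n"
        with pytest.raises(ValueError, match="line 2"):
            parse_region_file(text)

    def test_file_order_and_comments(self):
        text = "# targets\nsum(1:1-100|2:1-100)\n\navg(3:1-100)\n"
        specs = parse_region_file(text)
        assert [s.operation for s in specs] == ["sum", "avg"]


class TestEstimatorProperties:
    def test_scale_equivariance(self):
        bins, _ = cq.simulate_genome_bins(n_chroms=2, chrom_length=300_000, seed=3)
        res = CopyNumberModel(bins).fit()
        scaled = bins.copy()
        scaled["coverage"] *= 1.7
        res2 = CopyNumberModel(scaled).fit()
        a = res.region_cn("1", 10_000, 60_000)
        b = res2.region_cn("1", 10_000, 60_000)
        assert b.cn_mean == pytest.approx(a.cn_mean)
        assert b.ci_length == pytest.approx(a.ci_length)

    def test_ci_shrinks_as_root_n(self, diploid_result):
        res, _ = diploid_result
        short = res.region_cn("1", 0, 40_000)
        long = res.region_cn("1", 0, 160_000)
        ratio = short.ci_length / long.ci_length
        assert ratio == pytest.approx(2.0, rel=0.25)

    @pytest.mark.parametrize("x,expected", [
        (2.5, 3), (1.5, 2), (0.5, 1), (2.49, 2), (-1.5, -2), (0.0, 0),
    ])
    def test_rounding_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected

    def test_genotype_table_shape(self, diploid_result):
        res, _ = diploid_result
        specs = parse_region_file("sum(1:1-20000|2:1-20000)\navg(2:1-50000)\n")
        table = res.genotype(specs)
        assert list(table.columns) == [
            "region", "cn_mean", "cn_rounded", "ci_low", "ci_high",
            "n_used", "fraction_used"]
        assert len(table) == 2
        assert table.cn_rounded.tolist() == [4, 2]
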