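"""Copy-number annotation of structural-variant VCF and BED files, and
copy-number-consistency filtering of deletion calls.

Split-read / discordant-pair SV callers ignore read depth; annotating
their output with a depth-based copy-number estimate lets copy-neutral
false positives be filtered out.  Every intrachromosomal record gains
namespaced INFO tags (interchromosomal breakends pass through untouched):

========== =====================================================
CNQ_RD     mean copy number over the variant interval
CNQ_CN     rounded copy number
CNQ_CI_LO  lower 95% confidence bound
CNQ_CI_HI  upper 95% confidence bound
CNQ_BINS   number of informative bins used
CNQ_USED   fraction of overlapping bins that were informative
========== =====================================================

The deletion filter retains calls that are at least ``min_size`` bp long
(500 by default — read-depth evidence is uninformative below that scale
with 100 bp bins) and whose estimated copy number is consistent with a
loss (``CNQ_RD < ploidy - margin``, i.e. rounding below the ploidy).  It
can additionally require the caller's own PASS status; the combined
filter is strictly more stringent than either alone.
"""

from __future__ import annotations

import warnings
from typing import TYPE_CHECKING

import pysam

if TYPE_CHECKING:  # pragma: no cover
    from .model import CopyNumberResult

__all__ = ["INFO_TAGS", "annotate_vcf", "annotate_bed", "filter_deletions"]

INFO_TAGS = {
    "CNQ_RD": ("1", "Float", "Mean copy number over the variant interval"),
    "CNQ_CN": ("1", "Integer", "Rounded copy number over the variant interval"),
    "CNQ_CI_LO": ("1", "Float", "Lower 95% confidence bound of the copy number"),
    "CNQ_CI_HI": ("1", "Float", "Upper 95% confidence bound of the copy number"),
    "CNQ_BINS": ("1", "Integer", "Number of informative bins in the interval"),
    "CNQ_USED": ("1", "Float", "Fraction of overlapping bins that were informative"),
}

_BREAKEND_TYPES = {"BND", "TRA"}


def _is_breakend(record: pysam.VariantRecord) -> bool:
    svtype = record.info.get("SVTYPE")
    if isinstance(svtype, tuple):
        svtype = svtype[0]
    if svtype in _BREAKEND_TYPES:
        return True
    for alt in record.alts or ():
        if "[" in alt or "]" in alt:
            return True
    return False


def _has_usable_end(record: pysam.VariantRecord) -> bool:
    # pysam resolves INFO/END into record.stop; without it a symbolic
    # allele's stop collapses to the (1 bp) REF span
    alts = record.alts or ()
    symbolic = any(a.startswith("<") for a in alts)
    if symbolic:
        return record.stop > record.start + 1
    # precise alleles encode the interval in the REF allele length
    return record.stop > record.start


def _add_header_tags(header: pysam.VariantHeader) -> None:
    for tag, (number, vtype, descr) in INFO_TAGS.items():
        if tag not in header.info:
            header.info.add(tag, number, vtype, descr)


def annotate_vcf(vcf_in: str, result: "CopyNumberResult", vcf_out: str) -> int:
    """Annotate every intrachromosomal record of a structural-variant VCF
    with copy-number INFO tags; returns the number of records annotated.

    Record order and existing fields are preserved; breakend records and
    symbolic records with no usable END are passed through untagged (the
    latter with a warning).  Re-annotation overwrites the tags, so the
    operation is idempotent.
    """
    with pysam.VariantFile(vcf_in) as reader:
        header = reader.header.copy()
        _add_header_tags(header)
        n_annotated = 0
        with pysam.VariantFile(vcf_out, "w", header=header) as writer:
            for record in reader:
                record.translate(header)
                if _is_breakend(record):
                    writer.write(record)
                    continue
                if not _has_usable_end(record):
                    warnings.warn(
                        f"record {record.chrom}:{record.pos} has no usable END; "
                        "passed through untagged"
                    )
                    writer.write(record)
                    continue
                est = result.region_cn(record.chrom, record.start, record.stop)
                record.info["CNQ_BINS"] = est.n_used
                record.info["CNQ_USED"] = round(est.fraction_used, 4)
                if est.is_call:
                    record.info["CNQ_RD"] = round(est.cn_mean, 4)
                    record.info["CNQ_CN"] = est.cn_rounded
                    record.info["CNQ_CI_LO"] = round(est.ci_low, 4)
                    record.info["CNQ_CI_HI"] = round(est.ci_high, 4)
                n_annotated += 1
                writer.write(record)
    return n_annotated


def filter_deletions(
    vcf_in: str,
    vcf_out: str,
    ploidy: int = 2,
    loss_margin: float = 0.5,
    min_size: int = 500,
    require_pass: bool = False,
) -> tuple[int, int]:
    """Filter an annotated VCF's deletion records by copy-number
    consistency; returns (records kept, records removed).

    A deletion is retained when its length (END - POS) is at least
    ``min_size`` and its mean copy number is below ``ploidy -
    loss_margin`` (with the default margin 0.5, calls rounding to the
    ploidy or above are removed).  Annotated no-call deletions carry no
    depth support and are removed.  With ``require_pass`` the record must
    also carry the caller's PASS status.  Non-deletion records pass
    through unchanged.
    """
    kept = removed = 0
    with pysam.VariantFile(vcf_in) as reader:
        with pysam.VariantFile(vcf_out, "w", header=reader.header) as writer:
            for record in reader:
                svtype = record.info.get("SVTYPE")
                if isinstance(svtype, tuple):
                    svtype = svtype[0]
                is_del = svtype == "DEL" or "<DEL>" in (record.alts or ())
                if not is_del:
                    writer.write(record)
                    continue
                if "CNQ_BINS" not in record.info:
                    raise ValueError(
                        f"record {record.chrom}:{record.pos} lacks copy-number "
                        "tags; run annotate_vcf before filtering"
                    )
                size = record.stop - record.start
                cn = record.info.get("CNQ_RD")
                consistent = cn is not None and float(cn) < ploidy - loss_margin
                passes = ("PASS" in record.filter or len(record.filter) == 0
                          ) if require_pass else True
                if size >= min_size and consistent and passes:
                    kept += 1
                    writer.write(record)
                else:
                    removed += 1
    return kept, removed


def annotate_bed(bed_in: str, result: "CopyNumberResult", bed_out: str) -> int:
    """Append copy-number columns (cn_mean, cn_rounded, ci_low, ci_high,
    n_used, fraction_used) to every row of a BED file; no-call rows get
    ``.`` placeholders.  Existing columns are preserved verbatim."""
    n = 0
    with open(bed_in) as reader, open(bed_out, "w") as writer:
        for lineno, line in enumerate(reader, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith(("#", "track", "browser")):
                writer.write(line)
                continue
            fields = stripped.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{bed_in}:{lineno}: expected at least 3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{bed_in}:{lineno}: malformed interval: {exc}") from exc
            est = result.region_cn(chrom, start, end)
            if est.is_call:
                extra = [f"{est.cn_mean:.4f}", str(est.cn_rounded),
                         f"{est.ci_low:.4f}", f"{est.ci_high:.4f}",
                         str(est.n_used), f"{est.fraction_used:.4f}"]
            else:
                extra = ["."] * 6
            writer.write("\t".join(fields + extra) + "\n")
            n += 1
    return n
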