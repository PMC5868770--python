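"""Reading, validating and joining coverage and GC bin files.

Both inputs are tab-separated BED-like text with 0-based half-open
coordinates: the GC file has four columns (chrom, start, end, gc with a
``-1`` sentinel for masked bins) and the coverage file four or five
(chrom, start, end, mean coverage[, mean mapping quality]).  The two files
must describe the identical binning; they are joined on exact intervals
into a single bin table — the per-bin 5-tuple (chrom, start, end, GC,
coverage) plus the optional mapping quality — that every downstream
computation consumes.

Chromosome names are normalised by stripping a leading ``chr`` prefix so
that files from different reference dialects join cleanly.
"""

from __future__ import annotations

import gzip
from typing import IO

import pandas as pd

__all__ = [
    "normalize_chrom",
    "read_gc_bed",
    "read_coverage_bed",
    "read_bins",
    "write_bins",
]

BIN_COLUMNS = ["chrom", "start", "end", "gc", "coverage"]


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr``/``Chr``/``CHR`` prefix from a chromosome name."""
    if name[:3].lower() == "chr":
        return name[3:]
    return name


def _open_text(path: str) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_bed(path: str, value_cols: list[str]) -> pd.DataFrame:
    """Read a BED-like file with 3 fixed columns plus ``value_cols``; the
    last value column may be absent on every line."""
    rows = []
    n_required = 3 + len(value_cols) - 1
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < n_required:
                raise ValueError(
                    f"{path}:{lineno}: expected at least {n_required} columns, "
                    f"got {len(fields)}"
                )
            try:
                parsed = [fields[0], int(fields[1]), int(fields[2])]
                for i in range(len(value_cols)):
                    if 3 + i < len(fields):
                        parsed.append(float(fields[3 + i]))
                    else:
                        parsed.append(None)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line: {exc}") from exc
            if parsed[1] >= parsed[2]:
                raise ValueError(
                    f"{path}:{lineno}: empty or inverted interval "
                    f"{parsed[0]}:{parsed[1]}-{parsed[2]}"
                )
            rows.append(parsed)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", *value_cols])
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def read_gc_bed(path: str) -> pd.DataFrame:
    """Read a 4-column GC profile (chrom, start, end, gc)."""
    df = _read_bed(path, ["gc", "_extra"])
    return df.drop(columns="_extra")


def read_coverage_bed(path: str) -> pd.DataFrame:
    """Read a coverage profile; the 5th (mapping quality) column is optional."""
    df = _read_bed(path, ["coverage", "mapq"])
    if df["mapq"].isna().all():
        df = df.drop(columns="mapq")
    elif df["mapq"].isna().any():
        bad = df.index[df["mapq"].isna()][0]
        raise ValueError(
            f"{path}: mapping-quality column present on some lines but missing "
            f"near {df.loc[bad, 'chrom']}:{df.loc[bad, 'start']}"
        )
    if (df["coverage"] < 0).any():
        bad = df[df["coverage"] < 0].iloc[0]
        raise ValueError(
            f"{path}: negative coverage at {bad['chrom']}:{bad['start']}"
        )
    return df


def read_bins(gc_bed: str, coverage_bed: str) -> pd.DataFrame:
    """Join a GC profile and a coverage profile on exact intervals.

    Every bin must appear in both files; a bin present in only one of them
    is an error (silent drops would bias the reference), reported with the
    first discordant interval.
    """
    gc = read_gc_bed(gc_bed)
    cov = read_coverage_bed(coverage_bed)
    merged = gc.merge(cov, on=["chrom", "start", "end"], how="outer",
                      indicator=True, sort=True)
    discordant = merged[merged["_merge"] != "both"]
    if len(discordant):
        row = discordant.iloc[0]
        side = "GC" if row["_merge"] == "left_only" else "coverage"
        raise ValueError(
            f"bin {row['chrom']}:{int(row['start'])}-{int(row['end'])} is present "
            f"only in the {side} file; the two files must share an identical binning"
        )
    merged = merged.drop(columns="_merge")
    return merged.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_bins(bins: pd.DataFrame, path: str) -> None:
    """Write a bin table back to coverage-BED text (4 or 5 columns).

    Round-trips with :func:`read_coverage_bed` exactly for finite values.
    """
    cols = ["chrom", "start", "end", "coverage"]
    if "mapq" in bins.columns:
        cols.append("mapq")
    bins.to_csv(path, sep="\t", header=False, index=False, columns=cols)
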