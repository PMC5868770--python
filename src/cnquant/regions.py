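"""Target-region specifications and the region-file syntax.

A target is an operation — ``sum`` or ``avg`` — over one or more
sub-regions, one target per line::

    sum(chr1:104198141-104207173|chr1:104230039-104239075|chr1:104292276-104301311)
    avg(chr2:1-1000)

``sum`` genotypes a locus represented as several near-identical reference
copies (the amylase *AMY1A/B/C* pattern): each per-bin copy number is
multiplied by the number of sub-regions before averaging, so the estimate
is the total copy count across all copies.  ``avg`` pools the bins of all
sub-regions and reports their average copy number, which is useful for
skipping low-mappability stretches of a single locus.

Coordinates in the ``chrom:start-end`` syntax are 1-based inclusive
(samtools convention) and converted internally to 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

from .io import normalize_chrom

__all__ = ["Subregion", "RegionSpec", "parse_region", "parse_region_file"]

_LINE_RE = re.compile(r"^\s*(?P<op>\w+)\s*\(\s*(?P<body>[^()]+?)\s*\)\s*$")
_SUBREGION_RE = re.compile(r"^\s*(?P<chrom>[\w.]+)\s*:\s*(?P<start>[\d,]+)\s*-\s*(?P<end>[\d,]+)\s*$")


@dataclass(frozen=True)
class Subregion:
    """Half-open 0-based interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")


@dataclass(frozen=True)
class RegionSpec:
    """A parsed target: ``sum`` or ``avg`` over ordered sub-regions."""

    operation: str
    subregions: tuple[Subregion, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if self.operation not in ("sum", "avg"):
            raise ValueError(f"unknown operation {self.operation!r}; expected sum or avg")
        if not self.subregions:
            raise ValueError("a region spec needs at least one sub-region")


def _parse_subregion(text: str) -> Subregion:
    m = _SUBREGION_RE.match(text)
    if m is None:
        raise ValueError(f"malformed sub-region {text!r}; expected chrom:start-end")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    if end < start:
        raise ValueError(f"sub-region end before start in {text!r}")
    # 1-based inclusive -> 0-based half-open
    return Subregion(normalize_chrom(m.group("chrom")), start - 1, end)


def parse_region(line: str) -> RegionSpec:
    """Parse one ``op(chrom:start-end|...)`` line into a :class:`RegionSpec`."""
    m = _LINE_RE.match(line)
    if m is None:
        raise ValueError(f"malformed region line {line!r}")
    op = m.group("op").lower()
    if op not in ("sum", "avg"):
        raise ValueError(f"unknown operation {m.group('op')!r}; expected sum or avg")
    subs = tuple(_parse_subregion(part) for part in m.group("body").split("|"))
    return RegionSpec(op, subs, label=line.strip())


def parse_region_file(text_or_path) -> list[RegionSpec]:
    """Parse a region file (a path or its text) into specs in file order.

    Blank lines and ``#`` comments are ignored.  Errors carry the 1-based
    line number of the offending line.
    """
    if hasattr(text_or_path, "read"):
        text = text_or_path.read()
    else:
        text = str(text_or_path)
        if "\n" not in text and "(" not in text:
            with open(text_or_path) as handle:
                text = handle.read()
    specs = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        try:
            specs.append(parse_region(stripped))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
    return specs
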