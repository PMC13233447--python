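"""Genomic intervals, coordinate conventions, and BED I/O.

All coordinates inside the package are 0-based half-open ``[start, end)``.
Conversion to and from the 1-based inclusive convention used by GWAS/QTL
summary-statistic tables happens only here, at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

VALID_STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Malformed BED line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name.
    start, end : int
        0-based half-open bounds; ``start < end`` is enforced.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    name : str, optional
        Free-text label (BED name column, variant id, ...).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """Half-open membership test for a single 0-based position."""
        return self.start <= pos < self.end


def convert_coords(start_1based: int, end_1based: int, chrom: str = ".",
                   strand: str = ".") -> GenomicInterval:
    """Convert a 1-based inclusive span to a 0-based half-open interval.

    ``[s, e]`` (1-based, inclusive) maps to ``[s - 1, e)``; a single base
    ``[5, 5]`` becomes the length-1 interval ``[4, 5)``.
    """
    if start_1based < 1:
        raise ValueError(f"1-based start must be >= 1, got {start_1based}")
    if end_1based < start_1based:
        raise ValueError(
            f"1-based end {end_1based} precedes start {start_1based}"
        )
    return GenomicInterval(chrom, start_1based - 1, end_1based, strand)


def to_1based(interval: GenomicInterval) -> tuple[int, int]:
    """Inverse of :func:`convert_coords`; exact round-trip."""
    return interval.start + 1, interval.end


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+name file into a list of intervals.

    BED start/end are taken verbatim as 0-based half-open.  The optional
    fourth column is retained as the interval name.  Malformed lines
    (non-integer bounds, ``end <= start``, fewer than 3 columns) raise
    :class:`BedParseError` with the offending line number; there is no
    silent coercion.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(lineno, f"expected >= 3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    lineno, f"non-integer coordinates {fields[1]!r}/{fields[2]!r}"
                ) from None
            if start < 0:
                raise BedParseError(lineno, f"negative start {start}")
            if end <= start:
                raise BedParseError(lineno, f"end {end} <= start {start}")
            name = fields[3] if len(fields) > 3 and fields[3] != "" else None
            intervals.append(GenomicInterval(chrom, start, end, name=name))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED3+name (name column only when present)."""
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None:
                cols.append(iv.name)
            fh.write("\t".join(cols) + "\n")
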