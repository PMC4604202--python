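"""Genome-coverage breadth and mean depth from bedgraph intervals.

Consumes the 4-column bedgraph produced by ``bedtools genomecov -bga``
(chrom, 0-based start, exclusive end, depth; zero-depth intervals included,
so the intervals tile the genome) and summarizes per-base read depth as
breadth of coverage — the percentage of genome positions with depth at or
above each threshold — plus the mean depth over all positions, zeros
included.  Default thresholds are 1, 2, 5, 10 and 15 fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "DEFAULT_THRESHOLDS",
    "CoverageInterval",
    "CoverageSummary",
    "BedgraphParseError",
    "parse_bedgraph",
    "summarize_coverage",
    "validate_bga_cover",
]

DEFAULT_THRESHOLDS: tuple[int, ...] = (1, 2, 5, 10, 15)


class BedgraphParseError(ValueError):
    """A bedgraph line is malformed (wrong column count, non-integer
    coordinates/depth, or an empty interval)."""


@dataclass(frozen=True)
class CoverageInterval:
    """One bedgraph interval: 0-based half-open [start, end) at a uniform depth."""

    chrom: str
    start: int
    end: int
    depth: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start {self.start} must be < end {self.end}"
            )
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class CoverageSummary:
    """Breadth-at-threshold and mean depth over a genome of known size."""

    genome_size: int
    mean_depth: float
    breadth: dict[int, float] = field(default_factory=dict)


def parse_bedgraph(path: str | Path) -> list[CoverageInterval]:
    """Parse a 4-column bedgraph file into intervals, in file order.

    Raises :class:`BedgraphParseError` with the 1-based line number on a
    malformed line; blank lines are skipped.
    """
    intervals: list[CoverageInterval] = []
    with open(path, "r", encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise BedgraphParseError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, start_s, end_s, depth_s = fields
            try:
                start, end, depth = int(start_s), int(end_s), int(depth_s)
            except ValueError as exc:
                raise BedgraphParseError(
                    f"{path}:{lineno}: non-integer coordinate or depth: {exc}"
                ) from None
            try:
                intervals.append(CoverageInterval(chrom, start, end, depth))
            except ValueError as exc:
                raise BedgraphParseError(f"{path}:{lineno}: {exc}") from None
    return intervals


def summarize_coverage(
    intervals: Iterable[CoverageInterval],
    genome_size: int | None = None,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
) -> CoverageSummary:
    """Summarize intervals into breadth percentages and mean depth.

    breadth[t] = 100 * (bases with depth >= t) / genome_size;
    mean_depth  = sum(length * depth) / genome_size.

    ``genome_size`` defaults to the total interval length, which is the
    genome size exactly when the input is zero-inclusive (``-bga``) and
    tiles the genome (see :func:`validate_bga_cover`).
    """
    thresholds = tuple(thresholds)
    if not thresholds or list(thresholds) != sorted(set(thresholds)):
        raise ValueError("thresholds must be positive, ascending and unique")
    if thresholds[0] < 1:
        raise ValueError("thresholds must be >= 1")

    covered = {t: 0 for t in thresholds}
    depth_sum = 0
    total_len = 0
    for iv in intervals:
        length = len(iv)
        total_len += length
        depth_sum += length * iv.depth
        for t in thresholds:
            if iv.depth >= t:
                covered[t] += length
            else:
                break  # thresholds ascending
    if genome_size is None:
        genome_size = total_len
    if genome_size <= 0:
        raise ValueError(f"genome size must be positive, got {genome_size}")
    return CoverageSummary(
        genome_size=genome_size,
        mean_depth=depth_sum / genome_size,
        breadth={t: 100.0 * covered[t] / genome_size for t in thresholds},
    )


def validate_bga_cover(
    intervals: Iterable[CoverageInterval], genome_size: int
) -> bool:
    """True iff the intervals look like ``genomecov -bga`` output for a genome
    of the given size: per-chromosome non-overlapping, sorted, and the total
    interval length equals the genome size."""
    last_end: dict[str, int] = {}
    seen_order: list[str] = []
    total = 0
    for iv in intervals:
        if iv.chrom not in last_end:
            last_end[iv.chrom] = 0
            seen_order.append(iv.chrom)
        elif seen_order[-1] != iv.chrom:
            return False  # chromosome blocks must be contiguous
        if iv.start < last_end[iv.chrom]:
            return False
        last_end[iv.chrom] = iv.end
        total += len(iv)
    return total == genome_size
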