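"""Streaming read/base statistics for FASTQ data.

Accumulates, in one pass and one record at a time: read and base counts,
Q20/Q30 base counts (phred >= 20 / >= 30), read-length range and mean,
quality range both as raw ASCII characters and as decoded phred scores,
A/C/G/T/N composition, GC content, and the read-length distribution.

GC content is computed over all bases including N, so the GC, AT and N
fractions sum to 100%.  Any character outside {A, C, G, T} counts toward the
N bucket.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .fastq_io import PHRED33, QualityEncoding, ReadRecord, decode_qualities

__all__ = [
    "ReadSetStats",
    "LengthHistogram",
    "update_stats",
    "compute_stats",
    "merge_stats",
    "write_length_distribution",
    "format_stats_report",
]

BASES = ("A", "C", "G", "T", "N")


@dataclass
class ReadSetStats:
    """Accumulator for read/base-level metrics over a set of reads.

    Range fields (``min_len`` .. ``max_qchar``) are ``None`` until the first
    read is seen; reports render them as ``NA`` for an empty read set.
    """

    n_reads: int = 0
    n_bases: int = 0
    q20_bases: int = 0
    q30_bases: int = 0
    sum_len: int = 0
    min_len: int | None = None
    max_len: int | None = None
    min_q: int | None = None
    max_q: int | None = None
    min_qchar: str | None = None
    max_qchar: str | None = None
    base_counts: dict[str, int] = field(
        default_factory=lambda: {b: 0 for b in BASES}
    )

    @property
    def gc_percent(self) -> float:
        """GC content as a percentage of all bases (N included); 0 when empty."""
        if self.n_bases == 0:
            return 0.0
        return 100.0 * (self.base_counts["G"] + self.base_counts["C"]) / self.n_bases

    @property
    def mean_length(self) -> float:
        return self.sum_len / self.n_reads if self.n_reads else 0.0


@dataclass
class LengthHistogram:
    """Read count per read length."""

    counts: dict[int, int] = field(default_factory=dict)

    def add(self, length: int) -> None:
        self.counts[length] = self.counts.get(length, 0) + 1

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())


def update_stats(
    stats: ReadSetStats,
    hist: LengthHistogram,
    rec: ReadRecord,
    enc: QualityEncoding = PHRED33,
) -> tuple[ReadSetStats, LengthHistogram]:
    """Advance the accumulator by one read's contribution (in place)."""
    seq = rec.sequence
    length = len(seq)
    stats.n_reads += 1
    stats.n_bases += length
    stats.sum_len += length
    stats.min_len = length if stats.min_len is None else min(stats.min_len, length)
    stats.max_len = length if stats.max_len is None else max(stats.max_len, length)
    hist.add(length)

    counts = stats.base_counts
    acgt = 0
    for base in "ACGT":
        c = seq.count(base)
        counts[base] += c
        acgt += c
    counts["N"] += length - acgt  # every non-ACGT character

    scores = decode_qualities(rec.quality, enc)
    lo, hi = min(scores), max(scores)
    stats.min_q = lo if stats.min_q is None else min(stats.min_q, lo)
    stats.max_q = hi if stats.max_q is None else max(stats.max_q, hi)
    qlo, qhi = min(rec.quality), max(rec.quality)
    stats.min_qchar = qlo if stats.min_qchar is None else min(stats.min_qchar, qlo)
    stats.max_qchar = qhi if stats.max_qchar is None else max(stats.max_qchar, qhi)
    stats.q20_bases += sum(1 for s in scores if s >= 20)
    stats.q30_bases += sum(1 for s in scores if s >= 30)
    return stats, hist


def compute_stats(
    stream: Iterable[ReadRecord], enc: QualityEncoding = PHRED33
) -> tuple[ReadSetStats, LengthHistogram]:
    """Fold :func:`update_stats` over a read stream (streaming; one record
    resident at a time when given a lazy stream)."""
    stats = ReadSetStats()
    hist = LengthHistogram()
    for rec in stream:
        update_stats(stats, hist, rec, enc)
    return stats, hist


def _merge_extreme(a, b, fn):
    if a is None:
        return b
    if b is None:
        return a
    return fn(a, b)


def merge_stats(a: ReadSetStats, b: ReadSetStats) -> ReadSetStats:
    """Combine two accumulators: additive fields sum, ranges combine by
    min/max.  Merging with an empty accumulator is the identity, so per-worker
    partial statistics reduce to the single-pass result."""
    merged = ReadSetStats(
        n_reads=a.n_reads + b.n_reads,
        n_bases=a.n_bases + b.n_bases,
        q20_bases=a.q20_bases + b.q20_bases,
        q30_bases=a.q30_bases + b.q30_bases,
        sum_len=a.sum_len + b.sum_len,
        min_len=_merge_extreme(a.min_len, b.min_len, min),
        max_len=_merge_extreme(a.max_len, b.max_len, max),
        min_q=_merge_extreme(a.min_q, b.min_q, min),
        max_q=_merge_extreme(a.max_q, b.max_q, max),
        min_qchar=_merge_extreme(a.min_qchar, b.min_qchar, min),
        max_qchar=_merge_extreme(a.max_qchar, b.max_qchar, max),
    )
    merged.base_counts = {
        base: a.base_counts[base] + b.base_counts[base] for base in BASES
    }
    return merged


def write_length_distribution(hist: LengthHistogram, path: str | Path) -> None:
    """Write the read-length distribution as ``length<TAB>count`` lines,
    ascending by length (empty histogram -> empty file)."""
    with open(path, "w", encoding="ascii") as fh:
        for length in sorted(hist.counts):
            fh.write(f"{length}\t{hist.counts[length]}\n")


def _na(value, fmt: str = "{}") -> str:
    return "NA" if value is None else fmt.format(value)


def format_stats_report(stats: ReadSetStats, label: str | None = None) -> str:
    """Human-readable ``key: value`` report of one read set's metrics.

    Averages and percentages are printed to 2 decimal places; range fields of
    an empty read set print as NA.
    """
    lines = []
    if label is not None:
        lines.append(f"sample: {label}")
    bc = stats.base_counts
    lines += [
        f"reads: {stats.n_reads}",
        f"bases: {stats.n_bases}",
        f"q20_bases: {stats.q20_bases}",
        f"q30_bases: {stats.q30_bases}",
        f"read_length_min: {_na(stats.min_len)}",
        f"read_length_max: {_na(stats.max_len)}",
        f"read_length_mean: {stats.mean_length:.2f}",
        f"quality_char_min: {_na(stats.min_qchar)}",
        f"quality_char_max: {_na(stats.max_qchar)}",
        f"phred_min: {_na(stats.min_q)}",
        f"phred_max: {_na(stats.max_q)}",
        f"A: {bc['A']}",
        f"C: {bc['C']}",
        f"G: {bc['G']}",
        f"T: {bc['T']}",
        f"N: {bc['N']}",
        f"gc_percent: {stats.gc_percent:.2f}",
    ]
    return "\n".join(lines) + "\n"
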