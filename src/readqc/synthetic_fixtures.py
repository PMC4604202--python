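"""Deterministic synthetic-data generators for QC testing.

Produces random reference sequences, paired-end Illumina-like FASTQ at a
target fold-coverage, and bedgraph coverage fixtures.  The paired-read
simulator emulates, at kilobase scale, the standard benchmarking setup for
short-read QC tools: 100 bp paired-end reads at 10-fold genome coverage.

No substitution-error model is applied beyond optional N injection: the QC
stages under test consume base qualities and composition, not alignment
truth, so positional quality profiles are what matters.  The default quality
profile is a constant high mean with a linearly decaying 3' tail, mimicking
the 3' quality degradation of Illumina runs that window trimming targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .fastq_io import PHRED33, QualityEncoding, ReadRecord, write_fastq
from .coverage_summary import CoverageInterval, validate_bga_cover

__all__ = [
    "QualityProfile",
    "SimParams",
    "generate_reference",
    "simulate_paired_reads",
    "generate_bedgraph_fixture",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Illumina phred scores are bounded; 41 is the usual HiSeq ceiling.
MAX_PHRED = 41
MIN_PHRED = 2


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class QualityProfile:
    """Per-position phred quality model: mean ``mean_q`` over the 5' portion
    of the read, decaying linearly from ``tail_start`` (fraction of read
    length) down to ``tail_end_q`` at the last base, plus uniform integer
    noise of +/- ``spread``."""

    mean_q: int = 38
    spread: int = 3
    tail_start: float = 0.6
    tail_end_q: int = 22

    def position_means(self, read_len: int) -> np.ndarray:
        pos = np.arange(read_len, dtype=float)
        means = np.full(read_len, float(self.mean_q))
        knee = self.tail_start * (read_len - 1)
        if read_len > 1 and knee < read_len - 1:
            tail = pos >= knee
            frac = (pos[tail] - knee) / ((read_len - 1) - knee)
            means[tail] = self.mean_q + frac * (self.tail_end_q - self.mean_q)
        return means

    def sample(self, read_len: int, rng: np.random.Generator) -> np.ndarray:
        q = np.rint(self.position_means(read_len)).astype(int)
        if self.spread > 0:
            q = q + rng.integers(-self.spread, self.spread + 1, size=read_len)
        return np.clip(q, MIN_PHRED, MAX_PHRED)


PERFECT_QUALITY = QualityProfile(mean_q=40, spread=0, tail_start=1.0, tail_end_q=40)


@dataclass(frozen=True)
class SimParams:
    """Paired-end simulation parameters.

    Defaults follow the common short-read benchmarking setup: 100 bp
    paired-end reads at 10-fold coverage with a 300 +/- 30 bp insert.
    """

    ref_len: int = 10_000
    gc_target: float = 0.5
    coverage: float = 10.0
    read_len: int = 100
    insert_mean: int = 300
    insert_sd: int = 30
    qual_profile: QualityProfile = QualityProfile()
    n_rate: float = 0.0
    encoding: QualityEncoding = PHRED33
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_target <= 1.0:
            raise ValueError("gc_target must be in [0, 1]")
        if not 0.0 <= self.n_rate <= 1.0:
            raise ValueError("n_rate must be in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_len > self.insert_mean:
            raise ValueError("read_len must not exceed insert_mean")

    @property
    def n_pairs(self) -> int:
        """Pair count targeting ``coverage`` fold: coverage * ref_len /
        (2 * read_len), rounded."""
        return round(self.coverage * self.ref_len / (2 * self.read_len))


def generate_reference(ref_len: int, gc_target: float = 0.5, seed: int = 0) -> str:
    """I.i.d. random reference sequence with P(G or C) = ``gc_target``;
    the same seed always yields the same sequence."""
    if ref_len < 1:
        raise ValueError("ref_len must be >= 1")
    if not 0.0 <= gc_target <= 1.0:
        raise ValueError("gc_target must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [
        (1 - gc_target) / 2,
        gc_target / 2,
        gc_target / 2,
        (1 - gc_target) / 2,
    ]
    bases = rng.choice(np.array(list("ACGT")), size=ref_len, p=probs)
    return "".join(bases)


def simulate_paired_reads(
    reference: str,
    p: SimParams,
    out_r1: str | Path,
    out_r2: str | Path,
    compress: bool = False,
) -> int:
    """Simulate paired-end reads from ``reference`` and write two FASTQ files.

    Fragments are placed uniformly; read 1 is the 5' end of the fragment,
    read 2 the reverse complement of its 3' end.  Insert sizes are normal
    (mean/sd from ``p``), clipped to [read_len, len(reference)].  Qualities
    come from ``p.qual_profile``; a fraction ``n_rate`` of bases is replaced
    by N.  Fully reproducible from ``p.seed``.  Returns the pair count.
    """
    ref_len = len(reference)
    if ref_len < p.insert_mean:
        raise ValueError(
            f"reference length {ref_len} shorter than mean insert {p.insert_mean}"
        )
    rng = np.random.default_rng(p.seed)
    n_pairs = p.n_pairs
    offset = p.encoding.offset

    def make_records():
        for i in range(n_pairs):
            insert = int(
                np.clip(
                    round(rng.normal(p.insert_mean, p.insert_sd)),
                    p.read_len,
                    ref_len,
                )
            )
            start = int(rng.integers(0, ref_len - insert + 1))
            fragment = reference[start : start + insert]
            seq1 = fragment[: p.read_len]
            seq2 = _revcomp(fragment[-p.read_len :])
            pair = []
            for mate, seq in ((1, seq1), (2, seq2)):
                if p.n_rate > 0:
                    mask = rng.random(p.read_len) < p.n_rate
                    if mask.any():
                        arr = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()
                        arr[mask] = b"N"
                        seq = arr.tobytes().decode("ascii")
                quals = p.qual_profile.sample(p.read_len, rng)
                qual = "".join(chr(q + offset) for q in quals)
                pair.append(ReadRecord(f"sim_{i}/{mate}", seq, qual))
            yield pair

    r1_records: list[ReadRecord] = []
    r2_records: list[ReadRecord] = []
    for rec1, rec2 in make_records():
        r1_records.append(rec1)
        r2_records.append(rec2)
    write_fastq(r1_records, out_r1, compress=compress)
    write_fastq(r2_records, out_r2, compress=compress)
    return n_pairs


def generate_bedgraph_fixture(
    genome_size: int,
    segments: Sequence[tuple[int, int]],
    path: str | Path,
    chrom: str = "chr1",
) -> None:
    """Write contiguous (length, depth) segments as a single-chromosome
    bedgraph that tiles a genome of ``genome_size`` bases, in the
    zero-inclusive dialect of ``bedtools genomecov -bga``."""
    total = sum(length for length, _ in segments)
    if total != genome_size:
        raise ValueError(
            f"segment lengths sum to {total}, expected genome size {genome_size}"
        )
    intervals = []
    pos = 0
    for length, depth in segments:
        intervals.append(CoverageInterval(chrom, pos, pos + length, depth))
        pos += length
    assert validate_bga_cover(intervals, genome_size)
    with open(path, "w", encoding="ascii") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.depth}\n")
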