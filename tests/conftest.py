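"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (whole-file-in-memory, per-character,
per-base-array) so they stay independent of the streaming implementations
they check.
"""

from __future__ import annotations

import random

import numpy as np
import pytest

from readqc.fastq_io import ReadRecord

QUAL_ALPHABET_33 = [chr(33 + q) for q in range(42)]  # phred 0..41


def random_record(rng: random.Random, *, min_len=1, max_len=150,
                  n_rate=0.0, offset=33, rid=None) -> ReadRecord:
    length = rng.randint(min_len, max_len)
    seq = "".join(
        "N" if rng.random() < n_rate else rng.choice("ACGT")
        for _ in range(length)
    )
    qual = "".join(chr(offset + rng.randint(0, 41)) for _ in range(length))
    return ReadRecord(rid or f"r{rng.randrange(10**9)}", seq, qual)


def random_records(seed: int, n: int, **kw) -> list[ReadRecord]:
    rng = random.Random(seed)
    return [random_record(rng, rid=f"r{i}", **kw) for i in range(n)]


def naive_stats(records, offset=33):
    """Whole-set per-character statistics oracle (dict of plain values)."""
    out = {
        "n_reads": 0, "n_bases": 0, "q20_bases": 0, "q30_bases": 0,
        "sum_len": 0, "min_len": None, "max_len": None,
        "min_q": None, "max_q": None, "min_qchar": None, "max_qchar": None,
        "base_counts": {b: 0 for b in "ACGTN"},
        "hist": {},
    }
    for rec in records:
        out["n_reads"] += 1
        L = len(rec.sequence)
        out["n_bases"] += L
        out["sum_len"] += L
        out["hist"][L] = out["hist"].get(L, 0) + 1
        for bound, fn in (("min_len", min), ("max_len", max)):
            out[bound] = L if out[bound] is None else fn(out[bound], L)
        for ch in rec.sequence:
            out["base_counts"][ch if ch in "ACGT" else "N"] += 1
        for ch in rec.quality:
            q = ord(ch) - offset
            if q >= 20:
                out["q20_bases"] += 1
            if q >= 30:
                out["q30_bases"] += 1
            out["min_q"] = q if out["min_q"] is None else min(out["min_q"], q)
            out["max_q"] = q if out["max_q"] is None else max(out["max_q"], q)
            for bound, fn in (("min_qchar", min), ("max_qchar", max)):
                out[bound] = ch if out[bound] is None else fn(out[bound], ch)
    return out


def assert_stats_equal(stats, hist, oracle):
    assert stats.n_reads == oracle["n_reads"]
    assert stats.n_bases == oracle["n_bases"]
    assert stats.q20_bases == oracle["q20_bases"]
    assert stats.q30_bases == oracle["q30_bases"]
    assert stats.sum_len == oracle["sum_len"]
    assert stats.min_len == oracle["min_len"]
    assert stats.max_len == oracle["max_len"]
    assert stats.min_q == oracle["min_q"]
    assert stats.max_q == oracle["max_q"]
    assert stats.min_qchar == oracle["min_qchar"]
    assert stats.max_qchar == oracle["max_qchar"]
    assert stats.base_counts == oracle["base_counts"]
    if hist is not None:
        assert hist.counts == oracle["hist"]


def expand_per_base(intervals) -> dict[str, np.ndarray]:
    """Per-base depth arrays, the brute-force coverage oracle (small genomes)."""
    arrays: dict[str, np.ndarray] = {}
    for iv in intervals:
        arr = arrays.setdefault(iv.chrom, np.zeros(0, dtype=int))
        if iv.end > len(arr):
            arr = np.concatenate([arr, np.zeros(iv.end - len(arr), dtype=int)])
            arrays[iv.chrom] = arr
        arr[iv.start:iv.end] = iv.depth
    return arrays


@pytest.fixture
def fastq_file(tmp_path):
    """Factory writing records as a plain 4-line FASTQ file."""
    def write(records, name="reads.fastq"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rec in records:
                fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")
        return path
    return write
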