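"""Sliding-window quality trimming of paired-end reads with singleton routing.

A window of 10% of the read length (at least 1 base) slides along the read.
The 5' cut is the start of the first window whose mean phred score reaches
the threshold; the 3' cut is the start of the first later window whose mean
falls below it (end of read if none).  Optionally the retained segment is
further truncated before its first N.  Reads shorter than the minimum length
after trimming are discarded.  The scan is iterated to a fixed point, so
trimming already-trimmed reads is the identity.

Window means are compared as exact integer inequalities
(``sum >= q * window``), never as floats, so results are bit-stable.

Defaults follow the standard Illumina QC parameterization: phred threshold
30, minimum retained length 50, N-truncation on, sanger (phred+33) encoding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .fastq_io import PHRED33, QualityEncoding, ReadRecord, decode_qualities

__all__ = [
    "TrimParams",
    "TrimOutcome",
    "window_size",
    "trim_read",
    "trim_pair_stream",
    "trim_pairs",
]


@dataclass(frozen=True)
class TrimParams:
    """Trimming configuration.

    q: minimum mean window phred score (default 30).
    min_len: minimum retained read length in bases (default 50).
    truncate_at_n: cut the retained segment before its first N (default on).
    encoding: phred offset of the input (default phred+33, i.e. sanger).
    """

    q: int = 30
    min_len: int = 50
    truncate_at_n: bool = True
    encoding: QualityEncoding = PHRED33

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("quality threshold q must be >= 0")
        if self.min_len < 1:
            raise ValueError("minimum retained length must be >= 1")


@dataclass
class TrimOutcome:
    """Pair/singleton accounting for one trimming run.

    Conservation: ``2 * pairs_in == 2 * pairs_kept + singletons +
    reads_discarded`` holds exactly on every input.
    """

    pairs_in: int = 0
    pairs_kept: int = 0
    singletons: int = 0
    reads_discarded: int = 0
    bases_before: int = 0
    bases_after: int = 0


def window_size(read_len: int) -> int:
    """Sliding-window width: 10% of the read length, at least 1 base."""
    if read_len < 1:
        raise ValueError("read length must be >= 1")
    return max(1, round(0.1 * read_len))


def _scan(scores: list[int], q: int) -> tuple[int, int] | None:
    """One window pass: return (5' cut, 3' cut) as a half-open slice of the
    read, or None if no window reaches the threshold."""
    n = len(scores)
    w = window_size(n)
    total = sum(scores[:w])
    target = q * w  # mean >= q  <=>  sum >= q*w, exactly in integers
    five = None
    i = 0
    while True:
        if five is None:
            if total >= target:
                five = i
        elif total < target:
            return five, i
        if i + w >= n:
            break
        total += scores[i + w] - scores[i]
        i += 1
    if five is None:
        return None
    return five, n


def trim_read(rec: ReadRecord, p: TrimParams = TrimParams()) -> ReadRecord | None:
    """Trim one read; returns the trimmed record or None for a discard.

    The window scan (and N-truncation, when enabled) is applied repeatedly
    until the read no longer changes, so the operation is idempotent: every
    window of an emitted read passes the threshold at that read's own window
    size.
    """
    seq, qual = rec.sequence, rec.quality
    scores = decode_qualities(qual, p.encoding)
    while True:
        cuts = _scan(scores, p.q)
        if cuts is None:
            return None
        five, three = cuts
        if p.truncate_at_n:
            n_pos = seq.find("N", five, three)
            if n_pos != -1:
                three = n_pos
        if three - five < p.min_len:
            return None
        unchanged = five == 0 and three == len(seq)
        seq, qual, scores = seq[five:three], qual[five:three], scores[five:three]
        if unchanged:
            break
    if seq == rec.sequence:
        return rec
    return ReadRecord(rec.read_id, seq, qual)


def trim_pair_stream(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    p: TrimParams = TrimParams(),
) -> tuple[Iterator[tuple[str, tuple]], TrimOutcome]:
    """Streaming pair trimmer.

    Returns a lazy event stream and a :class:`TrimOutcome` that is updated as
    the stream is consumed (final once exhausted).  Events are
    ``("pair", (r1, r2))`` when both mates survive and ``("single", (rec,))``
    when exactly one does; pairs where neither mate survives emit nothing and
    count as two discarded reads.
    """
    outcome = TrimOutcome()

    def events() -> Iterator[tuple[str, tuple]]:
        for r1, r2 in pairs:
            outcome.pairs_in += 1
            outcome.bases_before += len(r1) + len(r2)
            t1 = trim_read(r1, p)
            t2 = trim_read(r2, p)
            outcome.bases_after += (len(t1) if t1 else 0) + (len(t2) if t2 else 0)
            if t1 is not None and t2 is not None:
                outcome.pairs_kept += 1
                yield "pair", (t1, t2)
            elif t1 is not None or t2 is not None:
                outcome.singletons += 1
                outcome.reads_discarded += 1
                yield "single", ((t1 if t1 is not None else t2),)
            else:
                outcome.reads_discarded += 2

    return events(), outcome


def trim_pairs(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    p: TrimParams = TrimParams(),
) -> tuple[list[tuple[ReadRecord, ReadRecord]], list[ReadRecord], TrimOutcome]:
    """Eager convenience wrapper around :func:`trim_pair_stream`: returns
    (kept pairs, singletons, outcome)."""
    stream, outcome = trim_pair_stream(pairs, p)
    kept: list[tuple[ReadRecord, ReadRecord]] = []
    singles: list[ReadRecord] = []
    for kind, payload in stream:
        if kind == "pair":
            kept.append(payload)  # type: ignore[arg-type]
        else:
            singles.append(payload[0])
    return kept, singles, outcome
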