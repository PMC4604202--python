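"""Streaming FASTQ input/output with phred decoding and mate-pair synchronization.

FASTQ is read strictly as 4-line records (header, sequence, ``+`` separator,
quality string); wrapped multi-line sequences are rejected.  Plain and
gzip-compressed files are handled transparently, with compression detected
from the gzip magic bytes.  Parsing is streaming: one record is resident in
memory per open stream, regardless of file size.
"""

from __future__ import annotations

import gzip
import io
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

GZIP_MAGIC = b"\x1f\x8b"

__all__ = [
    "ReadRecord",
    "QualityEncoding",
    "PHRED33",
    "PHRED64",
    "FastqFormatError",
    "PairSyncError",
    "QualityDecodeError",
    "open_fastq_stream",
    "read_pairs",
    "write_fastq",
    "decode_quality",
    "decode_qualities",
]


class FastqFormatError(ValueError):
    """A FASTQ record violates the 4-line format contract."""


class PairSyncError(ValueError):
    """Mate streams are desynchronized (count or identifier mismatch)."""


class QualityDecodeError(ValueError):
    """A quality character falls below the phred offset (wrong offset choice)."""


@dataclass(frozen=True)
class QualityEncoding:
    """ASCII offset for phred quality characters: 33 (HiSeq/MiSeq, 'sanger')
    or 64 (legacy GAIIx)."""

    offset: int = 33

    def __post_init__(self) -> None:
        if self.offset not in (33, 64):
            raise ValueError(f"phred offset must be 33 or 64, got {self.offset}")


PHRED33 = QualityEncoding(33)
PHRED64 = QualityEncoding(64)


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: identifier (without the leading ``@``), uppercased
    base sequence, and the raw encoded quality string of equal length."""

    read_id: str
    sequence: str
    quality: str

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def canonical_id(self) -> str:
        """Identifier with the mate suffix removed: anything after the first
        whitespace is dropped (Casava 1.8+ comments), then a trailing ``/1``
        or ``/2`` is stripped (pre-1.8 mate tags)."""
        base = self.read_id.split(None, 1)[0] if self.read_id else ""
        if base.endswith(("/1", "/2")):
            base = base[:-2]
        return base


def decode_quality(ch: str, enc: QualityEncoding = PHRED33) -> int:
    """Decode a single quality character to its integer phred score.

    Raises :class:`QualityDecodeError` if the character ordinal is below the
    offset, which almost always signals the wrong offset choice (e.g. decoding
    phred+33 data as phred+64).
    """
    score = ord(ch) - enc.offset
    if score < 0:
        raise QualityDecodeError(
            f"quality character {ch!r} (ordinal {ord(ch)}) below phred offset "
            f"{enc.offset}; wrong --phred setting?"
        )
    return score


def decode_qualities(quality: str, enc: QualityEncoding = PHRED33) -> list[int]:
    """Decode a whole quality string to phred scores (see :func:`decode_quality`)."""
    offset = enc.offset
    scores = [b - offset for b in quality.encode("ascii")]
    if scores and min(scores) < 0:
        bad = quality[scores.index(min(scores))]
        raise QualityDecodeError(
            f"quality character {bad!r} below phred offset {offset}; "
            f"wrong --phred setting?"
        )
    return scores


def _is_gzip(path: Path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == GZIP_MAGIC


def _open_text(path: Path, mode: str) -> IO[str]:
    if mode == "auto":
        mode = "gzip" if _is_gzip(path) else "plain"
    if mode == "gzip":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    if mode == "plain":
        return open(path, "r", encoding="ascii")
    raise ValueError(f"unknown mode {mode!r}; expected auto, plain or gzip")


def open_fastq_stream(
    path: str | Path, mode: str = "auto"
) -> Iterator[ReadRecord]:
    """Lazily yield :class:`ReadRecord` objects from a FASTQ file.

    Parameters
    ----------
    path:
        Plain or gzip-compressed FASTQ file.
    mode:
        ``auto`` (default) sniffs the gzip magic bytes; ``plain`` / ``gzip``
        force the container format.

    Raises
    ------
    FastqFormatError
        On a malformed record (missing ``@`` or ``+``, sequence/quality length
        mismatch, truncated final record), naming the 1-based record index.
    """
    path = Path(path)
    with _open_text(path, mode) as fh:
        index = 0
        while True:
            header = fh.readline()
            if header == "":
                return
            index += 1
            seq_line = fh.readline()
            plus_line = fh.readline()
            qual_line = fh.readline()
            if qual_line == "":
                raise FastqFormatError(
                    f"{path}: truncated FASTQ record {index} (fewer than 4 lines)"
                )
            header = header.rstrip("\r\n")
            sequence = seq_line.rstrip("\r\n").upper()
            plus = plus_line.rstrip("\r\n")
            quality = qual_line.rstrip("\r\n")
            if not header.startswith("@"):
                raise FastqFormatError(
                    f"{path}: record {index} header does not start with '@': "
                    f"{header[:40]!r}"
                )
            if not plus.startswith("+"):
                raise FastqFormatError(
                    f"{path}: record {index} separator line does not start "
                    f"with '+': {plus[:40]!r}"
                )
            if not sequence or not quality:
                raise FastqFormatError(
                    f"{path}: record {index} has an empty sequence or quality line"
                )
            if len(sequence) != len(quality):
                raise FastqFormatError(
                    f"{path}: record {index} sequence length {len(sequence)} != "
                    f"quality length {len(quality)}"
                )
            yield ReadRecord(header[1:], sequence, quality)


def read_pairs(
    path_r1: str | Path, path_r2: str | Path
) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    """Lazily yield synchronized mate pairs from two FASTQ files.

    Mate identity is checked on the canonical read identifier (mate suffix
    ``/1``/``/2`` and whitespace comments stripped).  Raises
    :class:`PairSyncError` on unequal record counts or a mismatched pair,
    naming the 1-based pair index.
    """
    stream1 = open_fastq_stream(path_r1)
    stream2 = open_fastq_stream(path_r2)
    for index, (r1, r2) in enumerate(
        itertools.zip_longest(stream1, stream2), start=1
    ):
        if r1 is None or r2 is None:
            short = path_r1 if r1 is None else path_r2
            raise PairSyncError(
                f"mate files desynchronized at pair {index}: {short} has "
                f"fewer records"
            )
        if r1.canonical_id != r2.canonical_id:
            raise PairSyncError(
                f"mate identifiers differ at pair {index}: "
                f"{r1.read_id!r} vs {r2.read_id!r}"
            )
        yield r1, r2


def write_fastq(
    records: Iterable[ReadRecord], path: str | Path, compress: bool = False
) -> int:
    """Write records as 4-line FASTQ, returning the number written.

    With ``compress=True`` the output is gzip with a zeroed timestamp and no
    embedded filename, so identical record sequences produce byte-identical
    files.
    """
    path = Path(path)
    if compress:
        raw = open(path, "wb")
        fh: IO[str] = io.TextIOWrapper(
            gzip.GzipFile(fileobj=raw, mode="wb", filename="", mtime=0),
            encoding="ascii",
        )
    else:
        raw = None
        fh = open(path, "w", encoding="ascii")
    count = 0
    try:
        for rec in records:
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")
            count += 1
    finally:
        fh.close()
        if raw is not None:
            raw.close()
    return count
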