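"""Quick-QC orchestration over many samples.

Quick QC is, per sample: read/base statistics on the raw paired FASTQ,
sliding-window quality trimming to kept-pair and singleton files, and
statistics again on the trimmed output — so the report shows the metrics
both before and after trimming.  Samples are consumed from a manifest in
consecutive batches of at most ``workers`` samples; samples within a batch
run concurrently (separate processes), batches sequentially.  The report is
assembled in manifest order, so its bytes are identical for any worker
count.  One sample's failure is recorded in its own row and never aborts the
others.

A coverage stage can be attached afterwards: per-sample bedgraph files
(``bedtools genomecov -bga`` output) are summarized into mean depth and
breadth at 1/2/5/10/15-fold.
"""

from __future__ import annotations

import os
import sys
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .coverage_summary import (
    DEFAULT_THRESHOLDS,
    CoverageSummary,
    parse_bedgraph,
    summarize_coverage,
    validate_bga_cover,
)
from .fastq_io import read_pairs, write_fastq
from .quality_trim import TrimOutcome, TrimParams, trim_pair_stream
from .read_stats import (
    LengthHistogram,
    ReadSetStats,
    compute_stats,
    update_stats,
    write_length_distribution,
)

__all__ = [
    "SampleEntry",
    "SampleManifest",
    "BatchPlan",
    "QCReportRow",
    "read_manifest",
    "plan_batches",
    "run_quick_qc",
    "attach_coverage",
    "write_report",
    "REPORT_COLUMNS",
]


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    r1: str
    r2: str


@dataclass
class SampleManifest:
    """Ordered list of (sample_id, read-1 path, read-2 path) entries with
    unique sample identifiers."""

    entries: list[SampleEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids in manifest: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class BatchPlan:
    """Samples grouped into consecutive batches of at most ``workers``."""

    batches: list[list[str]]
    workers: int


@dataclass
class QCReportRow:
    """One sample's before/after metrics, trimming outcome and optional
    coverage summary; ``status`` is OK, FAILED, or for the coverage columns
    alone, COVERAGE_FAILED."""

    sample_id: str
    status: str = "OK"
    error: str = ""
    before: ReadSetStats | None = None
    trim: TrimOutcome | None = None
    after: ReadSetStats | None = None
    coverage: CoverageSummary | None = None
    coverage_error: str = ""


def read_manifest(path: str | Path) -> SampleManifest:
    """Load a 3-column TSV manifest (sample_id, r1_path, r2_path); ``#``
    comment lines and blank lines are skipped."""
    entries = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns "
                    f"(sample_id, r1, r2), got {len(fields)}"
                )
            entries.append(SampleEntry(*fields))
    return SampleManifest(entries)


def plan_batches(manifest: SampleManifest, workers: int | None = None) -> BatchPlan:
    """Assign samples, in manifest order, to consecutive batches of size at
    most ``workers`` (default: all available processors)."""
    if workers is None:
        workers = os.cpu_count() or 1
    if workers < 1:
        raise ValueError(f"workers must be >= 1, got {workers}")
    ids = [e.sample_id for e in manifest.entries]
    batches = [ids[i : i + workers] for i in range(0, len(ids), workers)]
    return BatchPlan(batches=batches, workers=workers)


def _qc_one_sample(
    entry: SampleEntry, trim: TrimParams, outdir: str
) -> QCReportRow:
    """Worker: stats -> trim -> stats for one sample, writing trimmed FASTQ
    and length-distribution files.  Runs in a separate process; any failure
    is captured in the returned row."""
    out = Path(outdir)
    try:
        for p in (entry.r1, entry.r2):
            if not Path(p).exists():
                raise FileNotFoundError(f"input FASTQ not found: {p}")

        before = ReadSetStats()
        before_hist = LengthHistogram()

        def counted_pairs():
            for r1, r2 in read_pairs(entry.r1, entry.r2):
                update_stats(before, before_hist, r1, trim.encoding)
                update_stats(before, before_hist, r2, trim.encoding)
                yield r1, r2

        events, outcome = trim_pair_stream(counted_pairs(), trim)
        after = ReadSetStats()
        after_hist = LengthHistogram()

        r1_path = out / f"{entry.sample_id}_R1.trimmed.fastq"
        r2_path = out / f"{entry.sample_id}_R2.trimmed.fastq"
        singles_path = out / f"{entry.sample_id}_singles.trimmed.fastq"
        with open(r1_path, "w") as f1, open(r2_path, "w") as f2, open(
            singles_path, "w"
        ) as fs:
            for kind, payload in events:
                for rec in payload:
                    update_stats(after, after_hist, rec, trim.encoding)
                if kind == "pair":
                    t1, t2 = payload
                    f1.write(f"@{t1.read_id}\n{t1.sequence}\n+\n{t1.quality}\n")
                    f2.write(f"@{t2.read_id}\n{t2.sequence}\n+\n{t2.quality}\n")
                else:
                    (rec,) = payload
                    fs.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")

        write_length_distribution(before_hist, out / f"{entry.sample_id}.raw.lengths.tsv")
        write_length_distribution(after_hist, out / f"{entry.sample_id}.trimmed.lengths.tsv")
        return QCReportRow(
            entry.sample_id, status="OK", before=before, trim=outcome, after=after
        )
    except Exception as exc:  # per-sample isolation: never abort the batch
        return QCReportRow(
            entry.sample_id, status="FAILED", error=f"{type(exc).__name__}: {exc}"
        )


def run_quick_qc(
    manifest: SampleManifest,
    trim: TrimParams = TrimParams(),
    workers: int | None = None,
    outdir: str | Path = ".",
    log=sys.stderr,
) -> list[QCReportRow]:
    """Run quick QC over every manifest sample and return one report row per
    sample, in manifest order.

    ``workers`` bounds the number of samples processed concurrently (one
    sample per worker process); the report content is independent of it.
    The consolidated report is also written to ``<outdir>/qc_report.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plan = plan_batches(manifest, workers)
    by_id = {e.sample_id: e for e in manifest.entries}
    rows: list[QCReportRow] = []
    for batch in plan.batches:
        entries = [by_id[sid] for sid in batch]
        for e in entries:
            print(f"[qc] start {e.sample_id}", file=log)
        if plan.workers == 1 or len(entries) == 1:
            results = [_qc_one_sample(e, trim, str(outdir)) for e in entries]
        else:
            with ProcessPoolExecutor(max_workers=plan.workers) as pool:
                results = list(
                    pool.map(
                        _qc_one_sample,
                        entries,
                        [trim] * len(entries),
                        [str(outdir)] * len(entries),
                    )
                )
        for row in results:
            if row.status == "OK":
                assert row.before is not None and row.trim is not None
                print(
                    f"[qc] done {row.sample_id}: reads {row.before.n_reads} -> "
                    f"{row.after.n_reads}, pairs kept {row.trim.pairs_kept}, "
                    f"singletons {row.trim.singletons}",
                    file=log,
                )
            else:
                print(f"[qc] FAILED {row.sample_id}: {row.error}", file=log)
        rows.extend(results)
    write_report(rows, outdir / "qc_report.tsv")
    return rows


def attach_coverage(
    report: Sequence[QCReportRow],
    bedgraph_by_sample: Mapping[str, str | Path],
    genome_size: int | None = None,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
) -> list[QCReportRow]:
    """Attach coverage summaries to report rows in place (and return them).

    Samples without a bedgraph keep blank coverage columns; an unparseable
    bedgraph or one failing the -bga tiling validation flags only that
    sample's coverage, leaving its stats columns intact.
    """
    for row in report:
        path = bedgraph_by_sample.get(row.sample_id)
        if path is None:
            continue
        try:
            intervals = parse_bedgraph(path)
            size = genome_size
            if size is None:
                size = sum(len(iv) for iv in intervals)
            if not validate_bga_cover(intervals, size):
                raise ValueError(
                    f"bedgraph does not tile a genome of {size} bases "
                    "(-bga convention)"
                )
            row.coverage = summarize_coverage(intervals, size, thresholds)
        except Exception as exc:
            row.coverage = None
            row.coverage_error = f"{type(exc).__name__}: {exc}"
    return list(report)


_STAT_FIELDS = (
    "reads",
    "bases",
    "q20_bases",
    "q30_bases",
    "gc_pct",
    "len_mean",
    "len_min",
    "len_max",
    "phred_min",
    "phred_max",
)

REPORT_COLUMNS: tuple[str, ...] = (
    ("sample", "status")
    + tuple(f"raw_{f}" for f in _STAT_FIELDS)
    + ("pairs_in", "pairs_kept", "singletons", "reads_discarded")
    + tuple(f"trimmed_{f}" for f in _STAT_FIELDS)
    + ("mean_depth",)
    + tuple(f"breadth_{t}x" for t in DEFAULT_THRESHOLDS)
    + ("error",)
)


def _stat_cells(stats: ReadSetStats | None) -> list[str]:
    if stats is None:
        return ["NA"] * len(_STAT_FIELDS)
    na = lambda v: "NA" if v is None else str(v)
    return [
        str(stats.n_reads),
        str(stats.n_bases),
        str(stats.q20_bases),
        str(stats.q30_bases),
        f"{stats.gc_percent:.2f}",
        f"{stats.mean_length:.2f}",
        na(stats.min_len),
        na(stats.max_len),
        na(stats.min_q),
        na(stats.max_q),
    ]


def _row_cells(row: QCReportRow) -> list[str]:
    cells = [row.sample_id, row.status]
    cells += _stat_cells(row.before)
    if row.trim is None:
        cells += ["NA"] * 4
    else:
        cells += [
            str(row.trim.pairs_in),
            str(row.trim.pairs_kept),
            str(row.trim.singletons),
            str(row.trim.reads_discarded),
        ]
    cells += _stat_cells(row.after)
    if row.coverage_error:
        cells += ["FAILED"] * (1 + len(DEFAULT_THRESHOLDS))
    elif row.coverage is None:
        cells += [""] * (1 + len(DEFAULT_THRESHOLDS))
    else:
        cells.append(f"{row.coverage.mean_depth:.2f}")
        cells += [
            f"{row.coverage.breadth[t]:.2f}" for t in sorted(row.coverage.breadth)
        ]
    cells.append(row.error or row.coverage_error)
    return cells


def write_report(rows: Sequence[QCReportRow], path: str | Path) -> None:
    """Write the consolidated QC report as a fixed-column TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(_row_cells(row)) + "\n")
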