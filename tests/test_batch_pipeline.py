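"""Batch quick-QC: planning, determinism under parallelism, isolation,
before/after conservation, coverage attachment."""

import io

import pytest

from readqc.batch_pipeline import (
    QCReportRow,
    SampleEntry,
    SampleManifest,
    attach_coverage,
    plan_batches,
    read_manifest,
    run_quick_qc,
    write_report,
)
from readqc.quality_trim import TrimParams
from readqc.synthetic_fixtures import (
    PERFECT_QUALITY,
    SimParams,
    generate_bedgraph_fixture,
    generate_reference,
    simulate_paired_reads,
)


def _simulate_samples(tmp_path, n_samples, **sim_kw):
    entries = []
    for i in range(n_samples):
        params = SimParams(ref_len=1000, seed=100 + i, **sim_kw)
        ref = generate_reference(1000, 0.45, seed=100 + i)
        r1 = tmp_path / f"s{i}_R1.fastq"
        r2 = tmp_path / f"s{i}_R2.fastq"
        simulate_paired_reads(ref, params, r1, r2)
        entries.append(SampleEntry(f"s{i}", str(r1), str(r2)))
    return SampleManifest(entries)


class TestPlanning:
    def test_five_samples_two_workers(self):
        m = SampleManifest([SampleEntry(f"s{i}", "a", "b") for i in range(5)])
        plan = plan_batches(m, 2)
        assert [len(b) for b in plan.batches] == [2, 2, 1]
        assert [s for batch in plan.batches for s in batch] == [e.sample_id for e in m.entries]

    def test_more_workers_than_samples(self):
        m = SampleManifest([SampleEntry("only", "a", "b")])
        assert plan_batches(m, 20).batches == [["only"]]

    def test_empty_manifest(self):
        assert plan_batches(SampleManifest([]), 4).batches == []

    def test_invalid_workers(self):
        with pytest.raises(ValueError):
            plan_batches(SampleManifest([]), 0)

    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SampleManifest([SampleEntry("a", "x", "y"), SampleEntry("a", "z", "w")])


def test_manifest_parsing(tmp_path):
    path = tmp_path / "manifest.tsv"
    path.write_text("# comment\ns1\tr1.fq\tr2.fq\n\ns2\ta.fq\tb.fq\n")
    m = read_manifest(path)
    assert [e.sample_id for e in m.entries] == ["s1", "s2"]
    path.write_text("s1\tonly_two_columns\n")
    with pytest.raises(ValueError, match=":1:"):
        read_manifest(path)


def test_perfect_quality_sample_unchanged_by_trimming(tmp_path):
    """With every base at phred 40 and no Ns, trimming at q=30 removes
    nothing: after-trim stats equal before-trim stats on all counters."""
    manifest = _simulate_samples(tmp_path, 1, qual_profile=PERFECT_QUALITY, n_rate=0.0)
    (row,) = run_quick_qc(manifest, TrimParams(), workers=1,
                          outdir=tmp_path / "out", log=io.StringIO())
    assert row.status == "OK"
    assert row.trim.pairs_kept == row.trim.pairs_in == 50
    assert row.trim.singletons == row.trim.reads_discarded == 0
    assert row.after.n_reads == row.before.n_reads
    assert row.after.n_bases == row.before.n_bases
    assert row.after.base_counts == row.before.base_counts
    assert row.after.q30_bases == row.before.q30_bases


def test_report_bytes_identical_for_any_worker_count(tmp_path):
    """The consolidated report is byte-identical whether samples run
    serially or four at a time."""
    manifest = _simulate_samples(tmp_path, 6, n_rate=0.01)
    reports = {}
    for workers in (1, 4):
        outdir = tmp_path / f"out_w{workers}"
        run_quick_qc(manifest, TrimParams(), workers=workers, outdir=outdir,
                     log=io.StringIO())
        reports[workers] = (outdir / "qc_report.tsv").read_bytes()
    assert reports[1] == reports[4]
    assert len(reports[1].splitlines()) == 7  # header + 6 samples


def test_failing_sample_is_isolated(tmp_path):
    manifest = _simulate_samples(tmp_path, 2)
    entries = list(manifest.entries)
    entries.insert(1, SampleEntry("broken", str(tmp_path / "missing_R1.fastq"),
                                  str(tmp_path / "missing_R2.fastq")))
    rows = run_quick_qc(SampleManifest(entries), TrimParams(), workers=3,
                        outdir=tmp_path / "out", log=io.StringIO())
    assert [r.sample_id for r in rows] == ["s0", "broken", "s1"]
    assert [r.status for r in rows] == ["OK", "FAILED", "OK"]
    assert "missing_R1" in rows[1].error
    assert rows[0].before.n_reads == rows[2].before.n_reads == 100


def test_report_conservation_and_outputs_on_disk(tmp_path):
    manifest = _simulate_samples(tmp_path, 2, n_rate=0.02)
    outdir = tmp_path / "out"
    rows = run_quick_qc(manifest, TrimParams(), workers=1, outdir=outdir,
                        log=io.StringIO())
    for row in rows:
        assert row.status == "OK"
        out = row.trim
        assert 2 * out.pairs_in == 2 * out.pairs_kept + out.singletons + out.reads_discarded
        # bases removed by trimming exactly account for the before/after gap
        assert row.after.n_bases == out.bases_after
        assert row.before.n_bases == out.bases_before
        assert row.after.n_bases + (out.bases_before - out.bases_after) == row.before.n_bases
        for suffix in ("_R1.trimmed.fastq", "_R2.trimmed.fastq",
                       "_singles.trimmed.fastq", ".raw.lengths.tsv",
                       ".trimmed.lengths.tsv"):
            assert (outdir / f"{row.sample_id}{suffix}").exists()


class TestAttachCoverage:
    def _rows(self):
        return [QCReportRow("s0"), QCReportRow("s1")]

    def test_coverage_columns_appended(self, tmp_path):
        bg = tmp_path / "s0.bedgraph"
        generate_bedgraph_fixture(100, [(50, 0), (30, 5), (20, 20)], bg)
        rows = attach_coverage(self._rows(), {"s0": bg}, genome_size=100)
        assert rows[0].coverage.mean_depth == pytest.approx(5.5)
        assert rows[0].coverage.breadth[1] == 50.0
        assert rows[1].coverage is None and rows[1].coverage_error == ""

    def test_empty_mapping_is_noop(self):
        rows = attach_coverage(self._rows(), {})
        assert all(r.coverage is None for r in rows)

    def test_invalid_bedgraph_flags_only_coverage(self, tmp_path):
        bg = tmp_path / "bad.bedgraph"
        bg.write_text("chr1\t0\t60\t1\nchr1\t50\t100\t2\n")  # overlap
        rows = attach_coverage(self._rows(), {"s0": bg}, genome_size=100)
        assert rows[0].coverage is None
        assert "tile" in rows[0].coverage_error
        assert rows[0].status == "OK"  # stats columns untouched

    def test_failed_coverage_rendered_in_report(self, tmp_path):
        rows = self._rows()
        rows[0].coverage_error = "ValueError: boom"
        path = tmp_path / "report.tsv"
        write_report(rows, path)
        line = path.read_text().splitlines()[1]
        assert "FAILED" in line
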