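# Methods

`readqc` implements the quality-control stage of a short-read resequencing
workflow: per-sample read/base statistics, paired-end quality trimming, and
genome-coverage breadth summarization, orchestrated over many samples in
parallel batches. This note records the models, parameters and numerical
choices behind each stage, and what the synthetic-data generator does and
does not emulate.

## FASTQ model and phred decoding

A read is a strict 4-line FASTQ record: `@`-header, base sequence, `+`
separator, quality string of equal length. Wrapped (multi-line) sequences
are rejected by design — the strict form permits true streaming with one
record resident per open stream, and every parse error can name the 1-based
record index. Lowercase bases are uppercased on input; trailing `\r` is
stripped so CRLF files parse; the optional repeated identifier on the `+`
line is ignored. Gzip containers are detected from the magic bytes
`1f 8b`, never from the filename.

A quality character `c` decodes to the phred score `ord(c) − offset` with
offset 33 (HiSeq/MiSeq "sanger", the default) or 64 (legacy GAIIx). A
negative decoded score raises immediately rather than clamping, because it
almost always means the wrong offset was chosen for the file. There is no
offset auto-detection: guessing between overlapping ASCII ranges is
unreliable, and the platform is always known in practice.

Mate pairing is validated positionally on the canonical read identifier:
everything after the first whitespace is dropped (Casava ≥1.8 comment
style), then a trailing `/1` or `/2` is stripped (older mate tags). This
covers both common header dialects; a count or identifier mismatch raises
with the 1-based pair index.

## Read/base statistics

The statistics engine accumulates, in a single streaming pass: read and
base counts, Q20/Q30 base counts (phred ≥ 20 / ≥ 30), read-length min, max
and mean, the quality range both as raw ASCII characters and as decoded
phred integers (two distinct reports, since both views are useful when
diagnosing offset problems), A/C/G/T/N composition, GC percentage, and the
read-length histogram.

Choices that were genuinely open:

- **GC denominator includes N**: `gc% = 100·(G+C)/all bases`, so the GC, AT
  and N fractions sum to 100%. The alternative (ACGT-only denominator)
  inflates GC on N-rich data.
- **Non-ACGT characters count as N**: ambiguity codes (R, Y, …) are rare in
  Illumina output and are not informative for composition QC.
- **Empty read set**: range fields are reported as `NA` rather than
  fabricating 0 as a minimum quality; means are 0.
- Averages and percentages print with 2 decimals for stable report files.

The accumulator merges associatively and commutatively (sums for counters,
min/max for ranges, `None` as the identity), so per-worker partial results
reduce exactly to the single-pass answer; tests verify this against a naive
whole-file-in-memory per-character oracle, exactly, on every field.

## Sliding-window quality trimming

Parameters (defaults are the standard Illumina resequencing QC settings):
threshold `q = 30` (mean window phred), minimum retained length
`min_len = 50` bases, N-truncation on, phred+33 encoding.

One scan pass over a read of length `L` uses a window of
`w = max(1, round(0.1·L))` bases. The 5' cut is the start of the first
window whose mean phred reaches `q`; from there, the 3' cut is the start of
the first window whose mean falls below `q` (read end if none). Window
means are compared as exact integer inequalities (`sum ≥ q·w`), never as
floats, so ties are deterministic and results bit-stable. When N-truncation
is on, the retained segment is then cut before its first N. If no window
passes, or the retained length is below `min_len`, the read is discarded.

Because `w` is recomputed from the read's own length, a single pass is not
automatically a fixed point: the shorter trimmed read has a smaller window,
and a window that passed on average inside a larger one can fail on its
own. The trimmer therefore **iterates the scan to a fixed point** (each
pass returns a substring, so iteration terminates). This makes trimming
idempotent by construction — every window of an emitted read passes the
threshold at that read's own window size — which is the property the rest
of the pipeline relies on (re-QC of trimmed data changes nothing). This is
a deliberate design of this package, not a claim about any particular
external trimmer's edge behavior.

Pair routing: both mates survive → kept pair; exactly one survives →
singleton (retained, as singletons remain useful downstream); neither →
both discarded. The accounting identity
`2·pairs_in = 2·pairs_kept + singletons + reads_discarded` holds exactly on
every input and is property-tested over random streams.

## Coverage breadth summarization

Input is the 4-column bedgraph of `bedtools genomecov -bga`: 0-based
half-open intervals with integer depth, zero-depth intervals included, so
the intervals tile the genome. A validator checks exactly that
(per-chromosome sorted, non-overlapping, total length equal to the genome
size) before a file is trusted as `-bga` output.

For thresholds `t ∈ {1, 2, 5, 10, 15}` (the conventional fold-coverage
grid; other grids can be passed):

    breadth[t] = 100 · (bases with depth ≥ t) / genome_size
    mean_depth = Σ (interval length · depth) / genome_size

The mean is over **all** genome positions, zeros included — breadth and
mean then describe the same denominator. `genome_size` is user-supplied;
when omitted it falls back to the total interval length, which equals the
genome size precisely when the input is valid `-bga`. Interval arithmetic
is exact integer work; tests check it against brute-force per-base array
expansion on genomes up to 10 kb, exactly.

## Batch quick-QC pipeline

Quick QC per sample: statistics on the raw pairs → trimming into
`<sample>_R1.trimmed.fastq`, `_R2.trimmed.fastq`, `_singles.trimmed.fastq`
→ statistics on the trimmed pairs **plus singletons**, with raw and trimmed
read-length distribution files. All three steps share one streaming pass
over the input pair stream.

Samples are assigned in manifest order to consecutive batches of at most
`workers` samples (default: all processors); batches run sequentially,
samples within a batch in separate worker processes. Worker results are
collected in submission order and the consolidated TSV report is assembled
in manifest order, so report bytes are independent of the worker count —
parallelism is a throughput knob, never a result knob. A failing sample
(missing file, malformed FASTQ, desynchronized mates) produces a `FAILED`
row carrying its error and never disturbs other samples; the CLI exits 1
if any row failed.

Coverage attachment is a separate, optional stage (`attach_coverage`):
depth generation from alignments is the aligner/bedtools side of the
workflow and is out of scope here; this package starts at the bedgraph. An
invalid bedgraph flags only that sample's coverage columns.

## Synthetic-data generator

The generator emulates, at kilobase scale, the standard benchmarking setup
for Illumina QC tools: 100 bp paired-end reads at 10-fold genome coverage.
Defaults: `ref_len = 10 000`, `gc_target = 0.5`, `coverage = 10`,
`read_len = 100`, insert 300 ± 30 bp (a typical paired-end library),
`n_rate = 0`, phred+33.

- Reference: i.i.d. bases with `P(G or C) = gc_target`.
- Pair count `N = round(coverage · ref_len / (2 · read_len))`, fragments
  placed uniformly; read 1 is the fragment's 5' end, read 2 the reverse
  complement of its 3' end; insert lengths are normal, clipped to
  `[read_len, ref_len]`.
- Qualities: per-position mean `mean_q = 38` up to 60% of the read, then a
  linear decay to 22 at the last base, plus uniform ±3 integer noise,
  clipped to [2, 41]. The decaying 3' tail mimics Illumina 3' degradation
  and guarantees the trimmer is exercised non-trivially at `q = 30`.
- N injection replaces a fraction `n_rate` of read bases with N.

Everything is reproducible from a single integer seed (NumPy `default_rng`);
identical parameters give byte-identical FASTQ (gzip output is written with
a zeroed timestamp for the same reason).

What the generator does **not** emulate: substitution/indel sequencing
errors, platform-calibrated quality distributions, adapter read-through,
optical duplicates, or GC-dependent coverage bias. The QC stages under test
consume qualities, lengths and composition — not alignment truth — so
positional quality structure is the feature that matters; passing tests
demonstrate correctness of the accounting and trimming logic, not
robustness to every artifact of real flowcells.

## Problem sizes in the tests

The test and acceptance runs use kilobase references (0.8–10 kb), tens to
hundreds of reads per file, 100-file oracle sweeps, 1 000-read trimmer
sweeps, 200 random pair streams, 100 random coverage fixtures and 12-sample
parallel runs. These sizes exercise every code path (both phred offsets,
N handling, empty inputs, failure isolation, parallel merge) while keeping
the whole suite in the seconds range; all per-read/per-base logic is
scale-free, so nothing about correctness depends on file size.

## Known limitations

- Single-end trimming exists only at the library level (`trim_read`); the
  pipeline assumes paired input.
- No quality-offset auto-detection (deliberate, above).
- Interleaved FASTQ, SAM/BAM/CRAM input, adapter clipping and per-position
  quality curves are out of scope.
- The batch report's coverage columns use the default five-threshold grid;
  custom grids are available through `summarize_coverage` / `qc covsum`.
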