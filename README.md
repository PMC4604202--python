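# readqc

Batch-parallel quality control for Illumina FASTQ data.

Labs running whole-genome or targeted resequencing routinely face hundreds
of paired-end samples that need the same first look: *how much data is
there, how good is it, what survives quality trimming, and is the genome
covered deeply enough?* `readqc` answers those questions as a library and a
small CLI (`qc`), built around four pieces:

- **Statistics engine** — one streaming pass per FASTQ file (plain or gzip,
  phred+33 or phred+64) accumulating reads, bases, Q20/Q30 bases
  (phred ≥ 20 / ≥ 30, i.e. ≥ 99% / 99.9% base accuracy), read-length range
  and mean, quality range (raw ASCII and decoded phred), A/C/G/T/N
  composition, GC%, and the read-length distribution.
- **Sliding-window trimmer** — a window of 10% of the read length slides
  along each read; the retained segment runs from the first window whose
  mean phred reaches the threshold *q* to the first later window whose mean
  drops below it, optionally truncated before the first N, and is discarded
  under a minimum length *l*. Defaults `q = 30`, `l = 50`. Mates are routed
  to kept-pair files, singletons (one surviving mate), or discarded, with
  exact accounting: `2·pairs_in = 2·pairs_kept + singletons + discarded`.
- **Coverage summarizer** — turns `bedtools genomecov -bga` bedgraph into
  breadth of coverage, `breadth[t] = 100·(bases with depth ≥ t)/genome size`
  at 1/2/5/10/15-fold, plus mean depth over all positions.
- **Quick-QC pipeline** — per sample: stats → trim → stats again, so the
  report shows metrics before and after trimming. Samples run in batches of
  at most `--workers` concurrent processes; the report is byte-identical
  for any worker count, and one sample's failure never disturbs another's
  row.

A seeded simulator (`qc simulate`) generates references and paired reads
with a decaying 3' quality tail for testing and demonstration.

## Worked example

Simulate two 5 kb samples at 10-fold coverage with 1% N bases, then run
quick QC over both with two workers:

```sh
qc simulate -o sampleA --ref-len 5000 --seed 42 --n-rate 0.01
qc simulate -o sampleB --ref-len 5000 --seed 43 --n-rate 0.01
printf 'sampleA\tsampleA_R1.fastq\tsampleA_R2.fastq\n' >  manifest.tsv
printf 'sampleB\tsampleB_R1.fastq\tsampleB_R2.fastq\n' >> manifest.tsv
qc quick -m manifest.tsv -d qc_out -w 2
```

which logs per-sample progress to stderr and writes `qc_out/qc_report.tsv`;
the leading columns:

```
sample   status  raw_reads  raw_bases  raw_q20_bases  raw_q30_bases  raw_gc_pct  raw_len_mean  pairs_in  pairs_kept  singletons  reads_discarded
sampleA  OK      500        50000      49865          40423          48.82       100.00        250       84          130         202
sampleB  OK      500        50000      49860          40448          48.06       100.00        250       95          112         198
```

Each sample starts as 250 simulated 100 bp pairs (50 000 bases, GC near the
50% target). At `q = 30` the simulated 3' quality decay cuts most reads
back to roughly their first 75 bases, and the 1% N rate — combined with
N-truncation and the 50 bp length floor — discards about 40% of reads, so
sampleA keeps 84 intact pairs plus 130 singletons whose mates failed. The
conservation identity holds exactly: 2·250 = 2·84 + 130 + 202. Trimmed
FASTQ (`sampleA_R1.trimmed.fastq`, `_R2`, `_singles`) and length
distributions land next to the report.

Single-file statistics and coverage summaries:

```sh
$ qc stats sampleA_R1.fastq
reads: 250
bases: 25000
q20_bases: 24930
q30_bases: 20247
...
gc_percent: 48.73

$ qc covsum -b toy.bedgraph -g 100       # 50 bases @0x, 30 @5x, 20 @20x
sample  genome_size  mean_depth  breadth_1x  breadth_2x  breadth_5x  breadth_10x  breadth_15x
toy     100          5.50        50.00       50.00       50.00       20.00        20.00
```

Half the toy genome has any coverage at all (breadth ≥1x = 50%), only the
20-base segment at 20-fold reaches 10x, and the mean depth is
(30·5 + 20·20)/100 = 5.5.

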