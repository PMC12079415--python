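# modfreq

Real-time base-modification frequencies from nanopore modBAM streams.

Nanopore sequencers expose data while a run is still in progress, and live
basecallers (Dorado/Guppy-style, or f5c) already emit per-read base
modification calls as SAM **MM/ML** tags in aligned BAM files ("modBAM").
What is usually left to post-hoc analysis is the *aggregation* step: turning
those per-read calls into per-site modification frequencies (for example,
5mC levels at CpG sites, or m6A levels on direct RNA). `modfreq` performs
that aggregation continuously, as alignment batches appear on disk, so that
methylation frequencies are available *during* the run — for live dashboards,
for clinical turnaround, or for adaptive-sampling controllers that want to
stop sequencing a region once it has enough high-confidence coverage.

## What it computes

For every reference site, strand and modification code, the engine maintains
a cell of counters updated from each read that covers the site:

- each ML byte *b* is decoded to a call probability *p* = (*b* + 0.5)/256,
  the midpoint of the interval [*b*/256, (*b*+1)/256) the tag encodes;
- a call is **modified** if *p* ≥ `t_mod` (default 0.8), **canonical** if
  *p* ≤ `t_can` (default 0.2), and **ambiguous** otherwise — ambiguous calls
  are excluded from coverage but counted separately;
- the reported modification frequency at a site is
  *f* = n_mod / n_called over the confident calls.

MM deltas are walked over the read in its original (basecalled) orientation,
reverse-strand alignments are re-oriented, and each call is projected onto
the reference through the alignment CIGAR (calls in insertions and soft
clips are discarded). Counter updates are serialized through a single
writer, so the final table is exactly the sequential sum regardless of file
order or decoding parallelism. The table is periodically written to disk
(TSV by default, bedMethyl with `-b`) together with a binary checkpoint and
a processed-file log, from which an interrupted run resumes bit-exactly.

## Worked example

Generate a small synthetic run with known ground truth (five batch BAMs,
eight sites with modification levels on a grid), process it, and query the
result — no downloads needed:

```python
from modfreq import Engine, EngineConfig, SiteKey, dump_tsv
from modfreq.synth import default_truth_grid, generate_run

truth = default_truth_grid(n_sites=8, depth=30, seed=31)
paths, truth_tsv = generate_run(truth, n_files=5, out_dir="scratch/demo")

engine = Engine(EngineConfig())
engine.run_paths(paths)
dump_tsv(engine.table, "scratch/demo/freq.tsv")

for site in truth.sites[:4]:
    cell = engine.table.get(SiteKey(site.contig, site.ref_pos, site.strand, site.code))
    print(site.ref_pos, site.strand, site.true_p, cell.n_called, f"{cell.frequency:.3f}")
```

which prints:

```
500 + 0.0 30 0.000
800 - 0.1 30 0.067
1100 + 0.2 30 0.267
1400 - 0.3 30 0.300
```

Each line is a truth site: reference position, strand, the true
modification probability the generator used, the confident coverage the
engine accumulated (all 30 simulated reads), and the estimated frequency —
exact at the degenerate site, within binomial noise of truth elsewhere. The
first lines of `freq.tsv` hold the same numbers in the dump format:

```
contig	start	end	strand	n_called	n_mod	freq	mod_code
synthetic1	500	501	+	30	0	0.000000	m
synthetic1	800	801	-	30	2	0.066667	m
```

## Command line

`modfreq` reads newline-separated modBAM paths from stdin (terminating at
EOF), or watches a directory with `-m DIR` as a sequencer fills it:

```sh
ls batches/*.bam | modfreq -o freq.tsv --checkpoint run.ckpt
modfreq -m /data/exp_id -a bam -c 8765 -o freq.tsv       # watch + live TCP server
modfreq -r -o freq.tsv --checkpoint run.ckpt             # resume after a crash
```

Key flags: `-a bam|pod5` (watch modBAMs directly, or hand raw-signal files
to an external `--pipeline-cmd` that basecalls and aligns them), `-w SECS`
(dump/checkpoint on a wall-clock interval instead of after every file),
`-b` (bedMethyl output), `-c PORT` (serve live frequencies over TCP),
`--t-mod/--t-can` (confidence thresholds), `--threads` (concurrent file
decoders). The TCP protocol is line-oriented: `GET_CONTIG`, `GET_RANGE`,
`GET_COVERED` and `HELP`, each response ending with an `END` line — see
`docs/methods.md`.

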