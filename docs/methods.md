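# Methods

## The problem

Live nanopore basecalling emits per-read base-modification calls as SAM
MM/ML tags inside aligned BAM files, one file per sequencing batch.
`modfreq` streams those batches into per-reference-site modification
frequencies while the run is in progress: it decodes the tags, projects
calls onto the reference, maintains an in-memory hash table of per-site
counters under a single serialized writer, periodically dumps the table and
a checkpoint to disk, and serves the current state over TCP. The design
goal is exactness under streaming conditions: the result must be
independent of batch arrival order, of decoding parallelism, and of
crash/resume cycles.

## Tag decoding

An MM item names a canonical base, a strand relative to the read, one or
more modification codes (one-letter codes like `m`/`h`/`a`, or a numeric
ChEBI identifier carried verbatim), a skip mode, and a list of deltas. The
deltas are walked over occurrences of the canonical base in the read's
*original* orientation; for reverse-aligned records the stored sequence is
the reverse complement of the original read, so a selected original index
`i` becomes stored index `L − 1 − i`. `N` as canonical base matches every
position. A delta walk that exhausts the matching bases before consuming
all deltas is a decode error for that record (counted, not fatal to the
run).

ML bytes are consumed item-major, then position, then code. Byte `b` maps
to probability `(b + 0.5)/256` — the midpoint of the encoded interval
`[b/256, (b+1)/256)`, the unbiased representative — so all decoded
probabilities lie in `[1/512, 511/512]`.

Policy choices (all surfaced as configuration):

- **Implicit (`.`) skip mode**: fill-in of skipped occurrences as
  probability-0 canonical calls is *off* by default, because nanopore
  modification callers emit explicit calls for every context base and
  fill-in mainly inflates counts. `--implicit-fill` turns it on.
- **Minus-strand items** (`C-m…`, calls on the opposite strand of the
  read): parsed but dropped with a counted warning; their reference
  projection is ambiguous without a duplex policy, and this engine targets
  single-strand workflows.
- Records lacking MM or ML are skipped and counted.
- All modification codes present in the input are aggregated; selecting a
  code of interest is an output-side filter, not a decode-side one.

## Reference projection

Calls carry stored-sequence indices and are mapped through the CIGAR:
M/=/X consume read and reference, I and S consume read only (calls there
produce no site), D and N consume reference only, H and P consume neither.
The site strand is the read's alignment strand. Coordinates are 0-based
half-open internally and in both output formats (bedMethyl is natively
0-based, so nothing shifts at output). Records that are unmapped,
secondary, supplementary or QC-fail are dropped with counted reasons;
the mapping-quality floor defaults to 0 (no filter) and is configurable,
since common practice varies. CpG calls on the two strands are *not*
collapsed onto one strand; consumers who want strand-combined CpG levels
can sum the `+` row at position `p` with the `-` row at `p+1` from the TSV.

## Aggregation

The table maps (contig, position, strand, code) → (n_called, n_mod,
n_skipped). Classification thresholds default to `t_mod = 0.8`,
`t_can = 0.2` — the conventional high-confidence banding used by modBAM
pileup tools — with boundaries inclusive on both sides (`p == t_mod` is
modified, `p == t_can` is canonical). Ambiguous-band calls increment only
`n_skipped`, so either coverage convention (with or without ambiguous
calls) can be reported downstream. Frequency is `n_mod / n_called`,
defined only at positive coverage; zero-coverage rows are never printed.

Per-file decoding and projection may run on several worker threads
(`--threads`), each producing a private partial table; absorption into the
main table happens on one thread under the table lock. Because merging is
pure integer addition (commutative and associative), the final counts are
exactly the sequential sum for any order, batching or parallelism — this
is a tested invariant, not a best-effort property.

## Persistence and crash recovery

After every input file (or on a wall-clock interval via `-w`, which also
paces the output dump) the engine writes:

- a binary checkpoint: magic bytes, format version, entry count, then
  little-endian, length-prefixed entries — self-describing and versioned so
  the layout can evolve;
- a plain-text log of processed input paths, one absolute path per line.

Both are written to temporary names and renamed into place, so a crash
mid-write leaves the previous checkpoint intact. On `-r` the engine
reloads the table and the watcher/stdin loop skips logged paths; the
kill-and-resume run is byte-identical to an uninterrupted one at any split
point (tested).

## Outputs and the query server

The TSV dump has a fixed header (`contig start end strand n_called n_mod
freq mod_code`, frequency to 6 decimals); bedMethyl is the 11-column ENCODE
dialect (score = coverage capped at 1000, last columns coverage and percent
modified to 2 decimals). Rows are sorted by (contig, start, strand, code)
and files are replaced atomically, so identical tables give byte-identical
files and a third-party poller never reads a torn dump. `min_called`
(default 1) suppresses shallow rows.

The TCP server (`-c PORT`) speaks a line-oriented plain-text protocol so
any client — including an adaptive-sampling controller — can query without
a library: `GET_CONTIG <contig>`, `GET_RANGE <contig> <start> <end>`
(half-open), `GET_COVERED <contig> <start> <end> <min_called>` (the count
of sites in the range whose confident coverage has reached the threshold),
and `HELP`; every successful response ends with an `END` line, errors are a
single `ERR <message>` line. Query handling takes the same lock as table
mutation, trading a little latency for snapshot consistency: a response
never interleaves a half-applied file.

## Directory watching

The watcher recursively scans the experiment directory and emits each
matching file exactly once, only after its size has been stable for a
configurable interval (default 2 s) — file-completeness is not signalled
by sequencers, so stability is the heuristic. Paths listed in a resume log
are never re-emitted. The implementation polls at a configurable interval;
the exactly-once/complete-only/dedupe contract is what the tests assert,
deliberately independent of the notification mechanism. In raw-signal mode
(`-a pod5`) each new file is handed to a user-supplied shell template
(`--pipeline-cmd`, `{path}` substituted) that runs the external
conversion/basecalling/alignment pipeline and prints the resulting modBAM
path; the pipeline's internals are entirely outside this package.

## Synthetic data

The generator emulates what the live pipeline writes: coordinate-sorted,
indexed BAM batches over one synthetic contig, with truth sites spaced
300 bp apart and per-site modification probability on a configurable grid.
Each read covers one truth site and carries one MM/ML call whose modified
state is Bernoulli(true_p); ML bytes are drawn uniformly from [210, 255]
(modified) or [0, 45] (canonical) so that every generated probability falls
strictly outside the default ambiguous band and recovery tests are
decoupled from the threshold choice; a `noisy` mode draws Beta-shaped bytes
instead to exercise the band. Truth-site strands alternate, and reads for a
minus-strand site align reverse with MM positions re-oriented, so both
decode paths are exercised while each site maps to exactly one table key.
Reads optionally carry small indels and soft clips (default rates 0.25 and
0.2 per read) so projection is exercised; the call position is always kept
inside an aligned segment. All randomness flows from one seed.

What this does *not* emulate: basecalling errors correlated with signal,
reference mismatches, multi-site reads with correlated methylation,
duplex reads, or realistic genome composition. Passing the recovery tests
therefore demonstrates that the *engine* is exact and unbiased given the
tags, not that upstream modification calling is accurate.

Default study conditions used by the tests and the acceptance script:
truth grid {0.0, 0.1, …, 1.0} over 50 sites at depth 200 for recovery
(binomial 3-SE criterion, ≥95% of sites; degenerate sites exact); a
12-site, depth-60, 10-file run for invariance checks; an 8-site, depth-30,
5-file run for timed playback (0.25 s interval against a 0.15 s stability
window). These sizes make each check a few seconds while keeping binomial
standard errors small relative to the grid spacing.

## Numerical and degenerate-input notes

- Counters are exact integers; frequency is computed only at output time.
- Ties at the classification boundaries are resolved by the inclusive rule
  above and covered by tests.
- An empty MM tag, an item with no deltas, and an empty table are all
  valid and yield empty output rather than errors.
- Checkpoint loading validates magic, version and exact length; a
  truncated or trailing-garbage file is a corruption error, never a
  silently partial state.

## Known limitations

- One process, one host: the table is in-memory and single-writer by
  design; sharding across hosts is out of scope.
- No haplotype-resolved or per-read output.
- Duplex minus-strand MM items are dropped rather than reconciled.
- The watcher's stability heuristic can delay emission by one interval on
  slow filesystems; lower `--stability-interval` for fast local disks.
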