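"""Streaming orchestration: files in, frequency table out, continuously.

The engine consumes modBAM paths (from stdin or a directory watcher),
decodes MM/ML tags and projects calls for each file — possibly several
files concurrently — and folds the resulting per-file partial tables into
the main table through the single serialized writer.  Because per-file
tables are merged by pure integer addition, the final table is exactly the
sequential sum whatever the file order or parallelism.

After each file (or on a wall-clock interval when one is configured) the
engine rewrites the frequency dump and the checkpoint, so results are
available throughout the run and the run can resume after a crash.
"""

from __future__ import annotations

import logging
import os
import time
from concurrent.futures import ThreadPoolExecutor, as_completed
from dataclasses import dataclass, field

import pysam

from . import persistence, writers
from .freqstore import DEFAULT_T_CAN, DEFAULT_T_MOD, FrequencyTable
from .modtag import DecodeStats, ModTagError, decode_read_calls, pair_probabilities, parse_mm
from .refproject import AlignedRecord, FilterCounts, FilterPolicy, accept_record, project

logger = logging.getLogger(__name__)

__all__ = ["EngineConfig", "FileStats", "Engine", "decode_file"]


@dataclass
class EngineConfig:
    t_mod: float = DEFAULT_T_MOD
    t_can: float = DEFAULT_T_CAN
    min_mapq: int = 0
    implicit_fill: bool = False
    threads: int = 1
    min_called: int = 1
    bedmethyl: bool = False
    output_path: str | None = None
    checkpoint_path: str | None = None
    dump_interval: float | None = None  # None: dump after every file


@dataclass
class FileStats:
    path: str = ""
    records_read: int = 0
    records_dropped: int = 0
    records_missing_tags: int = 0
    calls_decoded: int = 0
    calls_projected: int = 0
    calls_ambiguous: int = 0
    decode_errors: int = 0

    def log(self) -> None:
        logger.info(
            "file=%s records=%d dropped=%d no_tags=%d decoded=%d "
            "projected=%d ambiguous=%d decode_errors=%d",
            self.path,
            self.records_read,
            self.records_dropped,
            self.records_missing_tags,
            self.calls_decoded,
            self.calls_projected,
            self.calls_ambiguous,
            self.decode_errors,
        )


def decode_file(
    path: str,
    config: EngineConfig,
) -> tuple[FrequencyTable, FileStats]:
    """Decode and project one modBAM into a fresh partial table.

    Pure with respect to shared state, so calls for distinct files can run
    on worker threads; the caller merges results under the writer lock.
    """
    partial = FrequencyTable(config.t_mod, config.t_can)
    stats = FileStats(path=path)
    policy = FilterPolicy(min_mapq=config.min_mapq)
    filter_counts = FilterCounts()
    decode_stats = DecodeStats()
    with pysam.AlignmentFile(path, "rb", check_sq=False) as bam:
        for seg in bam.fetch(until_eof=True):
            stats.records_read += 1
            rec = AlignedRecord.from_pysam(seg)
            if not accept_record(rec, policy, filter_counts):
                continue
            if rec.mm_raw is None or rec.ml_bytes is None:
                stats.records_missing_tags += 1
                continue
            try:
                items = parse_mm(rec.mm_raw)
                probs = pair_probabilities(items, rec.ml_bytes)
                calls = decode_read_calls(
                    rec.seq_stored,
                    rec.is_reverse,
                    items,
                    probs,
                    implicit_fill=config.implicit_fill,
                    stats=decode_stats,
                )
            except ModTagError as exc:
                stats.decode_errors += 1
                logger.warning("decode error in %s (%s): %s", rec.qname, path, exc)
                continue
            stats.calls_decoded += len(calls)
            site_calls = project(rec, calls)
            stats.calls_projected += len(site_calls)
            partial.update(site_calls)
    stats.records_dropped = filter_counts.total
    before = stats.calls_projected
    stats.calls_ambiguous = before - sum(
        s.n_called for _, s in partial.items()
    )
    return partial, stats


class Engine:
    """Drive the decode → aggregate → dump/checkpoint loop over a path stream."""

    def __init__(self, config: EngineConfig | None = None) -> None:
        self.config = config or EngineConfig()
        self.table = FrequencyTable(self.config.t_mod, self.config.t_can)
        self.processed_paths: list[str] = []
        self.failed_paths: list[str] = []
        self.file_stats: list[FileStats] = []
        self._last_dump = 0.0

    # -- resume -------------------------------------------------------------

    def resume(self) -> set[str]:
        """Load the checkpoint (if any) and return the processed-path set."""
        cp = self.config.checkpoint_path
        if not cp or not os.path.exists(cp):
            return set()
        state = persistence.load_checkpoint(cp)
        self.table = state.to_table(self.config.t_mod, self.config.t_can)
        self.processed_paths = list(state.processed_paths)
        logger.info(
            "resumed from %s: %d sites, %d processed files",
            cp,
            len(self.table),
            len(self.processed_paths),
        )
        return set(self.processed_paths)

    # -- processing ---------------------------------------------------------

    def _absorb(self, partial: FrequencyTable, stats: FileStats) -> None:
        self.table.merge(partial)
        self.processed_paths.append(os.path.abspath(stats.path))
        self.file_stats.append(stats)
        stats.log()
        self._maybe_flush()

    def _maybe_flush(self, force: bool = False) -> None:
        now = time.monotonic()
        interval = self.config.dump_interval
        if not force and interval is not None and now - self._last_dump < interval:
            return
        self._last_dump = now
        if self.config.output_path:
            self.dump(self.config.output_path)
        if self.config.checkpoint_path:
            persistence.save_checkpoint(
                self.table, self.processed_paths, self.config.checkpoint_path
            )

    def dump(self, out_path: str) -> None:
        if self.config.bedmethyl:
            writers.dump_bedmethyl(self.table, out_path, self.config.min_called)
        else:
            writers.dump_tsv(self.table, out_path, self.config.min_called)

    def process_path(self, path: str) -> bool:
        """Process a single file; returns False (and counts) on failure."""
        if not os.path.exists(path):
            logger.error("input path unreadable, skipping: %s", path)
            self.failed_paths.append(path)
            return False
        try:
            partial, stats = decode_file(path, self.config)
        except Exception as exc:  # unreadable/corrupt BAM
            logger.error("failed to process %s: %s", path, exc)
            self.failed_paths.append(path)
            return False
        self._absorb(partial, stats)
        return True

    def run_paths(self, paths) -> None:
        """Process a (possibly lazy) stream of paths, honoring --threads.

        Decoding runs on worker threads; absorption into the main table is
        serialized on this thread, so results are order-exact.
        """
        threads = max(1, self.config.threads)
        if threads == 1:
            for path in paths:
                self.process_path(path.strip() if isinstance(path, str) else path)
            return
        with ThreadPoolExecutor(max_workers=threads) as pool:
            futures = {}
            for path in paths:
                path = path.strip() if isinstance(path, str) else path
                if not path:
                    continue
                if not os.path.exists(path):
                    logger.error("input path unreadable, skipping: %s", path)
                    self.failed_paths.append(path)
                    continue
                futures[pool.submit(decode_file, path, self.config)] = path
            for fut in as_completed(futures):
                path = futures[fut]
                try:
                    partial, stats = fut.result()
                except Exception as exc:
                    logger.error("failed to process %s: %s", path, exc)
                    self.failed_paths.append(path)
                    continue
                self._absorb(partial, stats)

    def finalize(self) -> None:
        """Final dump + checkpoint at end of input."""
        self._maybe_flush(force=True)
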