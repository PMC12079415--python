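"""Checkpointing of the frequency table and processed-file registry.

A checkpoint is a pair of files written atomically (temp name + rename):

* ``<path>`` — a self-describing little-endian binary: magic bytes,
  format version, entry count, then length-prefixed entries; and
* ``<path>.log`` — a plain-text log of processed input paths, one absolute
  path per line.

Atomic replacement guarantees a crash mid-write never corrupts the previous
checkpoint, which is the whole point of being able to resume.
"""

from __future__ import annotations

import os
import struct
import time
from dataclasses import dataclass, field

from .freqstore import FrequencyTable, SiteKey, SiteStats

__all__ = [
    "CheckpointState",
    "CheckpointError",
    "CheckpointVersionError",
    "CheckpointCorruptError",
    "save_checkpoint",
    "load_checkpoint",
    "log_path_for",
]

MAGIC = b"MODFREQC"
FORMAT_VERSION = 1

_HEADER = struct.Struct("<8sId Q")  # magic, version, created_at, n_entries
_ENTRY_FIXED = struct.Struct("<qcQQQ")  # ref_pos, strand, n_called, n_mod, n_skipped


class CheckpointError(IOError):
    pass


class CheckpointVersionError(CheckpointError):
    pass


class CheckpointCorruptError(CheckpointError):
    pass


@dataclass
class CheckpointState:
    format_version: int
    created_at: float
    entries: list[tuple[SiteKey, SiteStats]]
    processed_paths: list[str] = field(default_factory=list)

    def to_table(self, t_mod: float | None = None, t_can: float | None = None) -> FrequencyTable:
        kwargs = {}
        if t_mod is not None:
            kwargs["t_mod"] = t_mod
        if t_can is not None:
            kwargs["t_can"] = t_can
        table = FrequencyTable(**kwargs)
        with table.lock:
            for key, stats in self.entries:
                table._cells[key] = stats.copy()
        return table


def log_path_for(dump_path: str | os.PathLike) -> str:
    return str(dump_path) + ".log"


def _pack_str(s: str) -> bytes:
    raw = s.encode("utf-8")
    return struct.pack("<H", len(raw)) + raw


def _read_exact(fh, n: int) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise CheckpointCorruptError(
            f"truncated checkpoint: wanted {n} bytes, got {len(data)}"
        )
    return data


def _unpack_str(fh) -> str:
    (n,) = struct.unpack("<H", _read_exact(fh, 2))
    return _read_exact(fh, n).decode("utf-8")


def save_checkpoint(
    table: FrequencyTable,
    processed_paths: list[str],
    dump_path: str | os.PathLike,
) -> None:
    """Write binary table snapshot and processed-path log, atomically.

    The in-memory table is read under its lock and never modified.
    """
    dump_path = str(dump_path)
    entries = table.sorted_items()
    tmp_bin = dump_path + ".tmp"
    with open(tmp_bin, "wb") as fh:
        fh.write(_HEADER.pack(MAGIC, FORMAT_VERSION, time.time(), len(entries)))
        for key, stats in entries:
            fh.write(_pack_str(key.contig))
            fh.write(
                _ENTRY_FIXED.pack(
                    key.ref_pos,
                    key.strand.encode("ascii"),
                    stats.n_called,
                    stats.n_mod,
                    stats.n_skipped,
                )
            )
            fh.write(_pack_str(key.code))
        fh.flush()
        os.fsync(fh.fileno())
    os.replace(tmp_bin, dump_path)

    log_path = log_path_for(dump_path)
    tmp_log = log_path + ".tmp"
    with open(tmp_log, "w", encoding="utf-8") as fh:
        for p in processed_paths:
            fh.write(os.path.abspath(p) + "\n")
        fh.flush()
        os.fsync(fh.fileno())
    os.replace(tmp_log, log_path)


def load_checkpoint(dump_path: str | os.PathLike) -> CheckpointState:
    """Read a checkpoint pair back into a :class:`CheckpointState`."""
    dump_path = str(dump_path)
    with open(dump_path, "rb") as fh:
        header = fh.read(_HEADER.size)
        if len(header) < _HEADER.size:
            raise CheckpointCorruptError("checkpoint shorter than its header")
        magic, version, created_at, n_entries = _HEADER.unpack(header)
        if magic != MAGIC:
            raise CheckpointVersionError(
                f"bad magic {magic!r}: not a modfreq checkpoint"
            )
        if version != FORMAT_VERSION:
            raise CheckpointVersionError(
                f"unsupported checkpoint format version {version} "
                f"(this build reads version {FORMAT_VERSION})"
            )
        entries: list[tuple[SiteKey, SiteStats]] = []
        for _ in range(n_entries):
            contig = _unpack_str(fh)
            ref_pos, strand, n_called, n_mod, n_skipped = _ENTRY_FIXED.unpack(
                _read_exact(fh, _ENTRY_FIXED.size)
            )
            code = _unpack_str(fh)
            entries.append(
                (
                    SiteKey(contig, ref_pos, strand.decode("ascii"), code),
                    SiteStats(n_called, n_mod, n_skipped),
                )
            )
        if fh.read(1):
            raise CheckpointCorruptError("trailing bytes after final entry")

    processed: list[str] = []
    log_path = log_path_for(dump_path)
    if os.path.exists(log_path):
        with open(log_path, encoding="utf-8") as fh:
            processed = [line.rstrip("\n") for line in fh if line.strip()]
    return CheckpointState(version, created_at, entries, processed)
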