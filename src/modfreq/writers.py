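"""Deterministic serialization of the frequency table (TSV and bedMethyl).

Both writers sort rows by (contig, start, strand, code), suppress sites
whose coverage is below ``min_called`` (and always those at zero coverage,
whose frequency is undefined), and replace the output file atomically so a
poller never reads a torn file.  Identical tables yield byte-identical
output.  Coordinates are 0-based half-open, matching BED natively.
"""

from __future__ import annotations

import os
from typing import Iterable

from .freqstore import FrequencyTable, SiteKey, SiteStats

__all__ = ["TSV_HEADER", "dump_tsv", "dump_bedmethyl", "load_tsv", "format_tsv_row"]

TSV_COLUMNS = (
    "contig",
    "start",
    "end",
    "strand",
    "n_called",
    "n_mod",
    "freq",
    "mod_code",
)
TSV_HEADER = "\t".join(TSV_COLUMNS)


def _selected_rows(
    table: FrequencyTable, min_called: int
) -> list[tuple[SiteKey, SiteStats]]:
    floor = max(min_called, 1)  # zero-coverage rows have no defined frequency
    return [(k, s) for k, s in table.sorted_items() if s.n_called >= floor]


def _atomic_write(out_path: str | os.PathLike, lines: Iterable[str]) -> None:
    out_path = str(out_path)
    tmp = out_path + ".tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        for line in lines:
            fh.write(line)
            fh.write("\n")
        fh.flush()
        os.fsync(fh.fileno())
    os.replace(tmp, out_path)


def format_tsv_row(key: SiteKey, stats: SiteStats) -> str:
    return "\t".join(
        (
            key.contig,
            str(key.ref_pos),
            str(key.ref_pos + 1),
            key.strand,
            str(stats.n_called),
            str(stats.n_mod),
            f"{stats.n_mod / stats.n_called:.6f}",
            key.code,
        )
    )


def dump_tsv(
    table: FrequencyTable, out_path: str | os.PathLike, min_called: int = 1
) -> None:
    rows = _selected_rows(table, min_called)
    _atomic_write(
        out_path, [TSV_HEADER] + [format_tsv_row(k, s) for k, s in rows]
    )


def dump_bedmethyl(
    table: FrequencyTable, out_path: str | os.PathLike, min_called: int = 1
) -> None:
    """ENCODE-style 11-column bedMethyl (BED9+2).

    score is coverage capped at 1000; the last two columns are coverage and
    percent modified to two decimals.
    """
    lines = []
    for key, stats in _selected_rows(table, min_called):
        lines.append(
            "\t".join(
                (
                    key.contig,
                    str(key.ref_pos),
                    str(key.ref_pos + 1),
                    key.code,
                    str(min(stats.n_called, 1000)),
                    key.strand,
                    str(key.ref_pos),
                    str(key.ref_pos + 1),
                    "0,0,0",
                    str(stats.n_called),
                    f"{100.0 * stats.n_mod / stats.n_called:.2f}",
                )
            )
        )
    _atomic_write(out_path, lines)


def load_tsv(path: str | os.PathLike) -> dict[SiteKey, tuple[int, int]]:
    """Re-parse a dumped TSV into the (key → (n_called, n_mod)) map."""
    out: dict[SiteKey, tuple[int, int]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != TSV_HEADER:
            raise ValueError(f"unexpected TSV header: {header!r}")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(TSV_COLUMNS):
                raise ValueError(f"bad TSV row: {line!r}")
            contig, start, _end, strand, n_called, n_mod, _freq, code = fields
            out[SiteKey(contig, int(start), strand, code)] = (
                int(n_called),
                int(n_mod),
            )
    return out
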