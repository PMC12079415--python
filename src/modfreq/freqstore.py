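"""In-memory per-site modification frequency table.

Each cell is keyed by (contig, position, strand, modification code) and
counts confidently-classified calls.  A call with probability >= t_mod is
modified, <= t_can canonical; the band in between is ambiguous and excluded
from coverage but kept as a separate counter so either coverage convention
can be reported downstream.

The table carries a lock implementing the single-writer contract: decoding
and projection of several input files may run concurrently, but counter
mutation (update/merge) and snapshot reads are serialized, so final counts
equal the sequential sum regardless of scheduling.
"""

from __future__ import annotations

import threading
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple

from .refproject import SiteCall

__all__ = [
    "SiteKey",
    "SiteStats",
    "FrequencyTable",
    "classify",
    "DEFAULT_T_MOD",
    "DEFAULT_T_CAN",
]

DEFAULT_T_MOD = 0.8
DEFAULT_T_CAN = 0.2


class SiteKey(NamedTuple):
    contig: str
    ref_pos: int
    strand: str
    code: str


@dataclass
class SiteStats:
    n_called: int = 0
    n_mod: int = 0
    n_skipped: int = 0

    @property
    def frequency(self) -> float:
        if self.n_called == 0:
            raise ZeroDivisionError("frequency undefined at zero coverage")
        return self.n_mod / self.n_called

    def copy(self) -> "SiteStats":
        return SiteStats(self.n_called, self.n_mod, self.n_skipped)


def classify(
    p: float, t_mod: float = DEFAULT_T_MOD, t_can: float = DEFAULT_T_CAN
) -> str:
    """Band a call probability: boundaries are inclusive on both sides."""
    if not 0 <= t_can <= t_mod <= 1:
        raise ValueError(f"require 0 <= t_can <= t_mod <= 1, got {t_can}, {t_mod}")
    if p >= t_mod:
        return "modified"
    if p <= t_can:
        return "canonical"
    return "ambiguous"


class FrequencyTable:
    """Hash table of per-site modification counts with a single-writer lock."""

    def __init__(
        self, t_mod: float = DEFAULT_T_MOD, t_can: float = DEFAULT_T_CAN
    ) -> None:
        if not 0 <= t_can <= t_mod <= 1:
            raise ValueError(f"require 0 <= t_can <= t_mod <= 1, got {t_can}, {t_mod}")
        self.t_mod = t_mod
        self.t_can = t_can
        self._cells: dict[SiteKey, SiteStats] = {}
        self.lock = threading.RLock()

    def __len__(self) -> int:
        return len(self._cells)

    def __contains__(self, key: SiteKey) -> bool:
        return key in self._cells

    def get(self, key: SiteKey) -> SiteStats | None:
        return self._cells.get(key)

    def update(self, site_calls: Iterable[SiteCall]) -> None:
        """Fold a stream of projected calls into the table (serialized)."""
        with self.lock:
            for call in site_calls:
                key = SiteKey(call.contig, call.ref_pos, call.strand, call.code)
                cell = self._cells.get(key)
                if cell is None:
                    cell = self._cells[key] = SiteStats()
                band = classify(call.probability, self.t_mod, self.t_can)
                if band == "ambiguous":
                    cell.n_skipped += 1
                else:
                    cell.n_called += 1
                    if band == "modified":
                        cell.n_mod += 1

    def merge(self, other: "FrequencyTable") -> None:
        """Add another table's counters into this one (commutative)."""
        with self.lock, other.lock:
            for key, stats in other._cells.items():
                cell = self._cells.get(key)
                if cell is None:
                    self._cells[key] = stats.copy()
                else:
                    cell.n_called += stats.n_called
                    cell.n_mod += stats.n_mod
                    cell.n_skipped += stats.n_skipped

    def items(self) -> Iterator[tuple[SiteKey, SiteStats]]:
        return iter(self._cells.items())

    def sorted_items(self) -> list[tuple[SiteKey, SiteStats]]:
        """Deterministic order: contig, position, strand, code."""
        with self.lock:
            return sorted(self._cells.items(), key=lambda kv: kv[0])

    def snapshot(self) -> dict[SiteKey, SiteStats]:
        with self.lock:
            return {k: v.copy() for k, v in self._cells.items()}

    def total_classified(self) -> int:
        """Σ (n_called + n_skipped) — equals the number of projected calls."""
        with self.lock:
            return sum(s.n_called + s.n_skipped for s in self._cells.values())
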