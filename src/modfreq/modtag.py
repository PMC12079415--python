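"""Parsing and decoding of SAM/BAM base-modification tags (MM/ML).

The MM tag lists, per canonical base and modification code, delta-encoded
counts of skipped matching bases between successive modification calls along
the read in its *original* (basecalled) orientation.  The ML tag carries one
byte per call per code; byte ``b`` encodes the probability interval
``[b/256, (b+1)/256)``.  This module turns the two tags into per-read
modification calls expressed as indices into the *stored* sequence, which is
what the CIGAR-based reference projection consumes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "ModItem",
    "ModCall",
    "DecodeStats",
    "ModTagError",
    "parse_mm",
    "pair_probabilities",
    "decode_read_calls",
    "byte_to_probability",
    "reverse_complement",
]


class ModTagError(ValueError):
    """Raised for malformed MM/ML tags or an impossible delta walk."""


# SAM optional-fields grammar for one MM item:
#   base [ACGTUN], strand [+-], codes ([a-z]+ one-letter codes, or a ChEBI
#   integer), optional skip-mode marker [.?], then comma-separated deltas.
_ITEM_RE = re.compile(
    r"^(?P<base>[ACGTUN])"
    r"(?P<strand>[-+])"
    r"(?P<codes>[a-z]+|[0-9]+)"
    r"(?P<mode>[.?]?)"
    r"(?P<deltas>(?:,[0-9]+)*)$"
)

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def byte_to_probability(b: int) -> float:
    """Midpoint of the probability interval an ML byte encodes.

    Byte ``b`` stands for ``[b/256, (b+1)/256)``; the midpoint is the
    unbiased representative, so values always lie in ``[1/512, 511/512]``.
    """
    if not 0 <= b <= 255:
        raise ModTagError(f"ML byte {b} outside [0, 255]")
    return (b + 0.5) / 256.0


@dataclass(frozen=True)
class ModItem:
    """One parsed MM-tag item (one base/strand/code-set group)."""

    canonical_base: str
    item_strand: str  # '+' or '-' relative to the read as written in MM
    codes: tuple[str, ...]  # one-character codes or a ChEBI id as a string
    skip_mode: str  # 'explicit' ('?') or 'implicit' ('.' or absent)
    deltas: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.codes:
            raise ModTagError("ModItem requires at least one modification code")
        if any(d < 0 for d in self.deltas):
            raise ModTagError("MM deltas must be non-negative")

    @property
    def n_calls(self) -> int:
        return len(self.deltas)


@dataclass(frozen=True)
class ModCall:
    """One per-read modification call in stored-sequence coordinates."""

    read_pos: int
    code: str
    probability: float
    implicit: bool = False


@dataclass
class DecodeStats:
    """Counters for conditions that are tolerated rather than fatal."""

    minus_strand_items_dropped: int = 0
    records_missing_tags: int = 0
    details: list[str] = field(default_factory=list)


def parse_mm(mm_string: str) -> list[ModItem]:
    """Parse an MM tag value into ordered :class:`ModItem` objects.

    A multi-code item such as ``C+mh`` yields one item with
    ``codes == ('m', 'h')``.  An absent ``?``/``.`` marker maps to implicit
    skip mode.  Malformed items raise :class:`ModTagError` naming the item.
    """
    if mm_string is None:
        raise ModTagError("MM tag value is None")
    mm_string = mm_string.strip()
    if not mm_string:
        return []
    chunks = mm_string.split(";")
    # the grammar terminates every item with ';' — a single trailing empty
    # chunk is the expected artefact of split(); anything else is garbage
    if chunks and chunks[-1] == "":
        chunks = chunks[:-1]
    items: list[ModItem] = []
    for chunk in chunks:
        m = _ITEM_RE.match(chunk)
        if m is None:
            raise ModTagError(f"malformed MM item: {chunk!r}")
        codes_field = m.group("codes")
        if codes_field.isdigit():
            codes: tuple[str, ...] = (codes_field,)  # ChEBI id, verbatim
        else:
            codes = tuple(codes_field)
        mode = "explicit" if m.group("mode") == "?" else "implicit"
        deltas_field = m.group("deltas")
        deltas = (
            tuple(int(d) for d in deltas_field[1:].split(","))
            if deltas_field
            else ()
        )
        items.append(
            ModItem(
                canonical_base=m.group("base"),
                item_strand=m.group("strand"),
                codes=codes,
                skip_mode=mode,
                deltas=deltas,
            )
        )
    return items


def expected_ml_length(items: Iterable[ModItem]) -> int:
    return sum(item.n_calls * len(item.codes) for item in items)


def pair_probabilities(
    items: Sequence[ModItem], ml_bytes: Sequence[int]
) -> list[list[list[float]]]:
    """Pair ML bytes with MM items.

    Returns, per item, one probability row per delta position; within a row
    probabilities follow the item's code order.  Consumption is item-major,
    then position, then code — the SAM interleaving.
    """
    expected = expected_ml_length(items)
    if len(ml_bytes) != expected:
        raise ModTagError(
            f"ML length mismatch: expected {expected} bytes for MM items, "
            f"got {len(ml_bytes)}"
        )
    out: list[list[list[float]]] = []
    i = 0
    for item in items:
        rows: list[list[float]] = []
        for _ in range(item.n_calls):
            row = [byte_to_probability(b) for b in ml_bytes[i : i + len(item.codes)]]
            i += len(item.codes)
            rows.append(row)
        out.append(rows)
    return out


def _occurrences(seq: str, base: str) -> list[int]:
    if base == "N":  # N matches every position per the SAM spec
        return list(range(len(seq)))
    return [i for i, ch in enumerate(seq) if ch == base]


def decode_read_calls(
    seq_as_stored: str,
    is_reverse: bool,
    items: Sequence[ModItem],
    probabilities: Sequence[Sequence[Sequence[float]]],
    *,
    implicit_fill: bool = False,
    stats: DecodeStats | None = None,
) -> list[ModCall]:
    """Walk MM deltas over the read and emit stored-coordinate calls.

    The delta walk runs over occurrences of the item's canonical base in the
    read's ORIGINAL orientation (the reverse complement of the stored
    sequence when ``is_reverse``); each selected original-orientation index
    is converted to a stored-sequence index before emission.  Items written
    on the opposite strand of the read ('-') are dropped with a counted
    warning.  When ``implicit_fill`` is on, skipped occurrences of
    implicit-mode items are emitted as probability-0 calls.
    """
    seq = seq_as_stored.upper()
    original = reverse_complement(seq) if is_reverse else seq
    length = len(original)

    def to_stored(orig_idx: int) -> int:
        return length - 1 - orig_idx if is_reverse else orig_idx

    calls: list[ModCall] = []
    occ_cache: dict[str, list[int]] = {}
    for item, rows in zip(items, probabilities):
        if item.item_strand == "-":
            if stats is not None:
                stats.minus_strand_items_dropped += 1
            logger.warning(
                "dropping minus-strand MM item %s%s%s (reference projection "
                "for opposite-strand calls is not defined here)",
                item.canonical_base,
                item.item_strand,
                "".join(item.codes),
            )
            continue
        base = item.canonical_base
        if base not in occ_cache:
            occ_cache[base] = _occurrences(original, base)
        occ = occ_cache[base]
        ptr = 0
        for delta, row in zip(item.deltas, rows):
            if implicit_fill and item.skip_mode == "implicit":
                for skipped in occ[ptr : ptr + delta]:
                    for code in item.codes:
                        calls.append(
                            ModCall(to_stored(skipped), code, 0.0, implicit=True)
                        )
            ptr += delta
            if ptr >= len(occ):
                raise ModTagError(
                    f"MM delta walk overran the read for item "
                    f"{base}{item.item_strand}{''.join(item.codes)}: needed "
                    f"occurrence {ptr} of {base!r} but only {len(occ)} exist"
                )
            orig_idx = occ[ptr]
            for code, p in zip(item.codes, row):
                calls.append(ModCall(to_stored(orig_idx), code, p, implicit=False))
            ptr += 1
    return calls
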