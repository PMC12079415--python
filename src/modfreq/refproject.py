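"""Projection of read-space modification calls onto reference coordinates.

A call carries a stored-sequence index; the record's CIGAR decides where (or
whether) that index lands on the reference.  M/=/X consume read and
reference, I and S consume read only (calls there are discarded), D and N
consume reference only, H consumes neither.  Coordinates are 0-based
half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .modtag import ModCall

__all__ = [
    "AlignedRecord",
    "SiteCall",
    "FilterPolicy",
    "FilterCounts",
    "accept_record",
    "project",
    "CIGAR_OPS",
]

CIGAR_OPS = "MIDNSHP=X"

FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_QCFAIL = 0x200
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800

_READ_CONSUMING = frozenset("MIS=X")
_REF_CONSUMING = frozenset("MDN=X")


@dataclass
class AlignedRecord:
    """The slice of a BAM record the engine needs, format-agnostic."""

    qname: str
    flags: int
    contig: str
    ref_start: int
    cigar: list[tuple[str, int]]
    seq_stored: str
    mm_raw: str | None
    ml_bytes: list[int] | None
    mapq: int = 60

    @property
    def is_reverse(self) -> bool:
        return bool(self.flags & FLAG_REVERSE)

    @classmethod
    def from_pysam(cls, seg) -> "AlignedRecord":
        """Build from a :class:`pysam.AlignedSegment`.

        Accepts both canonical (MM/ML) and legacy (Mm/Ml) tag spellings.
        """
        mm = None
        ml = None
        for tag in ("MM", "Mm"):
            if seg.has_tag(tag):
                mm = seg.get_tag(tag)
                break
        for tag in ("ML", "Ml"):
            if seg.has_tag(tag):
                ml = list(seg.get_tag(tag))
                break
        cigar = (
            [(CIGAR_OPS[op], length) for op, length in seg.cigartuples]
            if seg.cigartuples
            else []
        )
        return cls(
            qname=seg.query_name or "",
            flags=seg.flag,
            contig=seg.reference_name or "",
            ref_start=seg.reference_start if seg.reference_start is not None else -1,
            cigar=cigar,
            seq_stored=seg.query_sequence or "",
            mm_raw=mm,
            ml_bytes=ml,
            mapq=seg.mapping_quality,
        )


@dataclass(frozen=True)
class SiteCall:
    """One modification call placed on the reference."""

    contig: str
    ref_pos: int
    strand: str  # read alignment strand
    code: str
    probability: float


@dataclass(frozen=True)
class FilterPolicy:
    min_mapq: int = 0


@dataclass
class FilterCounts:
    unmapped: int = 0
    secondary: int = 0
    supplementary: int = 0
    qcfail: int = 0
    low_mapq: int = 0

    @property
    def total(self) -> int:
        return (
            self.unmapped
            + self.secondary
            + self.supplementary
            + self.qcfail
            + self.low_mapq
        )


def accept_record(
    rec: AlignedRecord,
    policy: FilterPolicy = FilterPolicy(),
    counts: FilterCounts | None = None,
) -> bool:
    """Drop unmapped/secondary/supplementary/QC-fail and low-MAPQ records."""
    if rec.flags & FLAG_UNMAPPED:
        if counts:
            counts.unmapped += 1
        return False
    if rec.flags & FLAG_SECONDARY:
        if counts:
            counts.secondary += 1
        return False
    if rec.flags & FLAG_SUPPLEMENTARY:
        if counts:
            counts.supplementary += 1
        return False
    if rec.flags & FLAG_QCFAIL:
        if counts:
            counts.qcfail += 1
        return False
    if rec.mapq < policy.min_mapq:
        if counts:
            counts.low_mapq += 1
        return False
    return True


def read_to_ref_map(
    cigar: Sequence[tuple[str, int]], ref_start: int
) -> list[int]:
    """Stored-index → reference-position array; -1 where no reference base.

    Insertions and soft clips consume the read without a reference
    counterpart; hard clips are absent from the stored sequence entirely.
    """
    mapping: list[int] = []
    ref = ref_start
    for op, length in cigar:
        if op in ("M", "=", "X"):
            mapping.extend(range(ref, ref + length))
            ref += length
        elif op in ("I", "S"):
            mapping.extend([-1] * length)
        elif op in ("D", "N"):
            ref += length
        elif op in ("H", "P"):
            continue
        else:
            raise ValueError(f"unknown CIGAR op {op!r}")
    return mapping


def project(rec: AlignedRecord, calls: Sequence[ModCall]) -> list[SiteCall]:
    """Map stored-sequence call indices to reference sites through the CIGAR.

    Calls landing in insertions or soft clips vanish; the output never
    exceeds the input in length.
    """
    mapping = read_to_ref_map(rec.cigar, rec.ref_start)
    strand = "-" if rec.is_reverse else "+"
    out: list[SiteCall] = []
    for call in calls:
        if not 0 <= call.read_pos < len(mapping):
            raise IndexError(
                f"call read_pos {call.read_pos} outside read of length "
                f"{len(mapping)} in {rec.qname!r} (decoder bug)"
            )
        ref_pos = mapping[call.read_pos]
        if ref_pos < 0:
            continue
        out.append(SiteCall(rec.contig, ref_pos, strand, call.code, call.probability))
    return out
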