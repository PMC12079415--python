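"""Independent brute-force oracles used to cross-check the engine.

Deliberately written in a different style from the package: the MM parser
is a regex-free character walk, the decoder re-scans the sequence per item,
and the projection oracle steps the CIGAR one base at a time per query.
They are slow and simple on purpose.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP.get(c, "N") for c in reversed(seq))


def oracle_parse_mm(mm: str):
    """Character-walk MM parser; returns (base, strand, codes, mode, deltas)."""
    items = []
    i, n = 0, len(mm)
    while i < n:
        base = mm[i]
        assert base in "ACGTUN", f"bad base at {i}"
        i += 1
        strand = mm[i]
        assert strand in "+-"
        i += 1
        codes: list[str] = []
        if mm[i].isdigit():
            num = ""
            while i < n and mm[i].isdigit():
                num += mm[i]
                i += 1
            codes = [num]
        else:
            while i < n and mm[i].islower():
                codes.append(mm[i])
                i += 1
        assert codes
        mode = "implicit"
        if i < n and mm[i] in ".?":
            mode = "explicit" if mm[i] == "?" else "implicit"
            i += 1
        deltas: list[int] = []
        while i < n and mm[i] == ",":
            i += 1
            num = ""
            while i < n and mm[i].isdigit():
                num += mm[i]
                i += 1
            deltas.append(int(num))
        assert i < n and mm[i] == ";", "item must end with ';'"
        i += 1
        items.append((base, strand, codes, mode, deltas))
    return items


def oracle_decode(
    seq_stored: str,
    is_reverse: bool,
    mm: str,
    ml_bytes,
    implicit_fill: bool = False,
):
    """Decode MM/ML into a list of (stored_pos, code, probability, implicit)."""
    items = oracle_parse_mm(mm)
    original = revcomp(seq_stored.upper()) if is_reverse else seq_stored.upper()
    length = len(original)
    # verify total ML length first, as the engine does
    total = sum(len(deltas) * len(codes) for _, _, codes, _, deltas in items)
    assert total == len(ml_bytes), "ML length mismatch"
    calls = []
    bi = 0
    for base, strand, codes, mode, deltas in items:
        if strand == "-":
            bi += len(deltas) * len(codes)
            continue
        matched = 0  # occurrences of base seen so far
        pos = 0  # scan position in the original read
        for delta in deltas:
            skipped = 0
            while True:
                assert pos < length, "delta walk overran the read"
                hit = base == "N" or original[pos] == base
                if hit and skipped == delta:
                    break
                if hit:
                    skipped += 1
                    if implicit_fill and mode == "implicit":
                        stored = length - 1 - pos if is_reverse else pos
                        for code in codes:
                            calls.append((stored, code, 0.0, True))
                pos += 1
            stored = length - 1 - pos if is_reverse else pos
            for code in codes:
                calls.append((stored, code, (ml_bytes[bi] + 0.5) / 256.0, False))
                bi += 1
            pos += 1
    return calls


def oracle_ref_pos(cigar, ref_start: int, read_idx: int):
    """Reference position for one stored index, stepping one base at a time.

    Returns None when the index falls in an insertion or soft clip; raises
    if the index exceeds the read span of the CIGAR.
    """
    read, ref = 0, ref_start
    for op, length in cigar:
        for _ in range(length):
            if op in "M=X":
                if read == read_idx:
                    return ref
                read += 1
                ref += 1
            elif op in "IS":
                if read == read_idx:
                    return None
                read += 1
            elif op in "DN":
                ref += 1
            # H and P consume nothing
    raise IndexError(f"read index {read_idx} beyond CIGAR read span {read}")
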