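"""Synthetic modBAM generation with known ground-truth frequencies.

Emulates what a live basecalling+alignment pipeline writes during a
sequencing run: batches of aligned, coordinate-sorted BAM files whose
records carry MM/ML tags.  Each truth site has a configured modification
probability; every read covering the site carries one call whose modified
status is Bernoulli(true_p), encoded as a high ML byte for modified and a
low byte for canonical.  Reads for minus-strand truth sites align on the
reverse strand, with MM positions correctly re-oriented to the original
(basecalled) read direction.  CIGARs optionally contain insertions,
deletions and soft clips so the projection path is exercised end to end.

All randomness flows from one seed through one generator: the same seed
reproduces the same run.
"""

from __future__ import annotations

import array
import os
import shutil
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pysam

from .modtag import reverse_complement
from .refproject import read_to_ref_map

__all__ = [
    "TruthSite",
    "TruthTable",
    "default_truth_grid",
    "encode_item",
    "generate_run",
    "timed_playback",
    "load_truth_tsv",
]

CONTIG = "synthetic1"
_BASES = np.frombuffer(b"ACGT", dtype="S1")

# ML byte bands: both lie strictly outside the default ambiguous band
# (0.2, 0.8), so recovery is insensitive to the exact thresholds.
MODIFIED_BYTE_RANGE = (210, 255)
CANONICAL_BYTE_RANGE = (0, 45)


@dataclass(frozen=True)
class TruthSite:
    contig: str
    ref_pos: int
    strand: str
    code: str
    true_p: float


@dataclass
class TruthTable:
    """Ground truth for one synthetic run.

    ``p_indel``/``p_clip`` are per-read probabilities of carrying one
    small indel / soft-clipped ends; ``noisy`` switches ML bytes from the
    clean uniform bands to Beta-shaped draws that populate the ambiguous
    band.
    """

    sites: list[TruthSite]
    read_depth: int = 200
    read_length: int = 100
    p_indel: float = 0.25
    p_clip: float = 0.2
    noisy: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        for s in self.sites:
            if not 0.0 <= s.true_p <= 1.0:
                raise ValueError(f"true_p outside [0,1] at {s}")


def default_truth_grid(
    n_sites: int = 50,
    depth: int = 200,
    seed: int = 0,
    code: str = "m",
    spacing: int = 300,
    start: int = 500,
    **kwargs,
) -> TruthTable:
    """Sites with true_p cycling the grid {0.0, 0.1, ..., 1.0}.

    Strands alternate so reverse-orientation decoding is exercised on half
    the sites.
    """
    grid = [round(0.1 * i, 1) for i in range(11)]
    sites = [
        TruthSite(
            CONTIG,
            start + spacing * i,
            "+" if i % 2 == 0 else "-",
            code,
            grid[i % len(grid)],
        )
        for i in range(n_sites)
    ]
    return TruthTable(sites=sites, read_depth=depth, seed=seed, **kwargs)


def encode_item(
    original_seq: str,
    canonical_base: str,
    codes: Sequence[str],
    calls: Sequence[tuple[int, Sequence[int]]],
    explicit: bool = True,
    item_strand: str = "+",
) -> tuple[str, list[int]]:
    """Encode calls at original-orientation positions into one MM item + ML.

    ``calls`` is a sorted list of (original index, bytes-per-code); every
    called index must hold ``canonical_base`` in ``original_seq``.  Inverse
    of the decoder for a single item; also used by tests as the round-trip
    encoder.
    """
    if canonical_base == "N":
        occ = list(range(len(original_seq)))
    else:
        occ = [i for i, ch in enumerate(original_seq) if ch == canonical_base]
    rank = {pos: r for r, pos in enumerate(occ)}
    deltas = []
    prev = -1
    for pos, byte_row in calls:
        if pos not in rank:
            raise ValueError(
                f"call position {pos} is not an occurrence of {canonical_base!r}"
            )
        if len(byte_row) != len(codes):
            raise ValueError("one ML byte per code required at each call")
        r = rank[pos]
        if r <= prev:
            raise ValueError("call positions must be strictly increasing")
        deltas.append(r - prev - 1)
        prev = r
    marker = "?" if explicit else "."
    mm = (
        canonical_base
        + item_strand
        + "".join(codes)
        + marker
        + "".join(f",{d}" for d in deltas)
        + ";"
    )
    ml = [b for _, row in calls for b in row]
    return mm, ml


def _draw_byte(rng: np.random.Generator, modified: bool, noisy: bool) -> int:
    if noisy:
        x = rng.beta(8, 2) if modified else rng.beta(2, 8)
        return int(min(255, max(0, round(x * 255))))
    lo, hi = MODIFIED_BYTE_RANGE if modified else CANONICAL_BYTE_RANGE
    return int(rng.integers(lo, hi + 1))


def _random_cigar(
    rng: np.random.Generator, read_length: int, p_indel: float, p_clip: float
) -> list[tuple[str, int]]:
    s1 = int(rng.integers(3, 9)) if rng.random() < p_clip else 0
    s2 = int(rng.integers(3, 9)) if rng.random() < p_clip else 0
    indel_op = None
    indel_len = 0
    if rng.random() < p_indel:
        indel_op = "I" if rng.random() < 0.5 else "D"
        indel_len = int(rng.integers(1, 4))
    m_total = read_length - s1 - s2 - (indel_len if indel_op == "I" else 0)
    cigar: list[tuple[str, int]] = []
    if s1:
        cigar.append(("S", s1))
    if indel_op is None or m_total < 4:
        cigar.append(("M", m_total))
    else:
        a = int(rng.integers(2, m_total - 1))
        cigar.extend([("M", a), (indel_op, indel_len), ("M", m_total - a)])
    if s2:
        cigar.append(("S", s2))
    return cigar


def _make_read(
    rng: np.random.Generator,
    truth: TruthTable,
    site: TruthSite,
    qname: str,
) -> pysam.AlignedSegment:
    L = truth.read_length
    is_reverse = site.strand == "-"
    # retry until the CIGAR leaves an aligned (M) stored index for the call
    for _ in range(50):
        cigar = _random_cigar(rng, L, truth.p_indel, truth.p_clip)
        rel = read_to_ref_map(cigar, 0)
        aligned = [i for i, r in enumerate(rel) if r >= 0 and 10 <= i < L - 10]
        if aligned:
            break
    else:  # degenerate parameters; fall back to a pure match
        cigar = [("M", L)]
        rel = read_to_ref_map(cigar, 0)
        aligned = list(range(10, L - 10))
    call_stored = int(aligned[rng.integers(len(aligned))])
    ref_start = site.ref_pos - rel[call_stored]

    stored = rng.choice(_BASES, size=L).tobytes().decode("ascii")
    # the basecalled (original) read carries the canonical base at the call
    target = "G" if is_reverse else "C"
    stored = stored[:call_stored] + target + stored[call_stored + 1 :]

    original = reverse_complement(stored) if is_reverse else stored
    orig_idx = L - 1 - call_stored if is_reverse else call_stored
    modified = rng.random() < site.true_p
    byte = _draw_byte(rng, modified, truth.noisy)
    mm, ml = encode_item(original, "C", [site.code], [(orig_idx, [byte])])

    seg = pysam.AlignedSegment()
    seg.query_name = qname
    seg.flag = 16 if is_reverse else 0
    seg.reference_id = 0
    seg.reference_start = ref_start
    seg.mapping_quality = 60
    seg.cigartuples = [("MIDNSHP=X".index(op), ln) for op, ln in cigar]
    seg.query_sequence = stored
    seg.query_qualities = pysam.qualitystring_to_array("I" * L)
    seg.set_tag("MM", mm, value_type="Z")
    seg.set_tag("ML", array.array("B", ml))
    return seg


def generate_run(
    truth: TruthTable, n_files: int, out_dir: str | os.PathLike
) -> tuple[list[str], str]:
    """Write ``n_files`` sorted+indexed modBAMs plus a truth TSV.

    The per-site depth is split as evenly as possible across files, so any
    subset of files still has well-defined expected counts.  Returns the
    BAM paths (in batch order) and the truth TSV path.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(truth.seed)
    ref_len = max(s.ref_pos for s in truth.sites) + truth.read_length + 500
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": CONTIG, "LN": int(ref_len)}],
    }

    per_file_reads: list[list[pysam.AlignedSegment]] = [[] for _ in range(n_files)]
    for si, site in enumerate(truth.sites):
        for j in range(truth.read_depth):
            seg = _make_read(rng, truth, site, qname=f"s{si}r{j}")
            per_file_reads[j % n_files].append(seg)

    paths = []
    for fi, reads in enumerate(per_file_reads):
        path = os.path.join(out_dir, f"batch_{fi}.bam")
        reads.sort(key=lambda s: (s.reference_start, s.query_name))
        with pysam.AlignmentFile(path, "wb", header=header) as bam:
            for seg in reads:
                bam.write(seg)
        pysam.index(path)
        paths.append(path)

    truth_path = os.path.join(out_dir, "truth.tsv")
    with open(truth_path, "w", encoding="utf-8") as fh:
        fh.write("contig\tref_pos\tstrand\tcode\ttrue_p\n")
        for s in truth.sites:
            fh.write(f"{s.contig}\t{s.ref_pos}\t{s.strand}\t{s.code}\t{s.true_p}\n")
    return paths, truth_path


def load_truth_tsv(path: str | os.PathLike) -> list[TruthSite]:
    sites = []
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            contig, pos, strand, code, p = line.rstrip("\n").split("\t")
            sites.append(TruthSite(contig, int(pos), strand, code, float(p)))
    return sites


def timed_playback(
    files: Sequence[str | os.PathLike],
    watch_dir: str | os.PathLike,
    interval_s: float,
) -> list[str]:
    """Copy files into a watched directory one per interval.

    Emulates a sequencer dropping batch files over time.  Each file is
    copied under a temporary name and renamed into place so a watcher never
    sees a half-written batch.  Returns the destination paths.
    """
    watch_dir = str(watch_dir)
    os.makedirs(watch_dir, exist_ok=True)
    out = []
    for i, src in enumerate(files):
        if i:
            time.sleep(interval_s)
        dest = os.path.join(watch_dir, os.path.basename(str(src)))
        tmp = dest + ".part"
        shutil.copyfile(src, tmp)
        os.replace(tmp, dest)
        out.append(dest)
    return out
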