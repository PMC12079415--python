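import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))  # make oracles importable

from modfreq.synth import encode_item  # noqa: E402

BASES = "ACGT"


def random_tag_case(rng: np.random.Generator, allow_minus_items: bool = False):
    """One random MM/ML decoding case with its expected reference encoder.

    Returns (seq_stored, is_reverse, mm, ml_bytes).  Items cover multi-code
    groups, ChEBI numeric codes, explicit/implicit skip modes and (when
    requested) minus-strand items the decoder must drop.
    """
    from oracles import revcomp

    length = int(rng.integers(20, 120))
    original = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
    is_reverse = bool(rng.random() < 0.5)
    n_items = int(rng.integers(1, 4))
    mm_parts: list[str] = []
    ml: list[int] = []
    used: set[tuple] = set()
    for _ in range(n_items):
        base = BASES[int(rng.integers(0, 4))]
        kind = rng.random()
        if kind < 0.6:
            codes = ["m", "h", "a"][: int(rng.integers(1, 3))]
        elif kind < 0.8:
            codes = [str(int(rng.integers(1, 100000)))]  # ChEBI id
        else:
            codes = ["m"]
        strand = "-" if allow_minus_items and rng.random() < 0.15 else "+"
        key = (base, strand, tuple(codes))
        if key in used:
            continue
        used.add(key)
        occ = [i for i, c in enumerate(original) if c == base]
        if not occ:
            continue
        k = int(rng.integers(0, min(len(occ), 8) + 1))
        chosen = sorted(rng.choice(len(occ), size=k, replace=False))
        calls = [
            (occ[i], [int(b) for b in rng.integers(0, 256, size=len(codes))])
            for i in chosen
        ]
        mm, bytes_ = encode_item(
            original,
            base,
            codes,
            calls,
            explicit=bool(rng.random() < 0.5),
            item_strand=strand,
        )
        mm_parts.append(mm)
        ml.extend(bytes_)
    seq_stored = revcomp(original) if is_reverse else original
    return seq_stored, is_reverse, "".join(mm_parts), ml


def random_cigar_case(rng: np.random.Generator):
    """A random valid CIGAR with its read length and a reference start."""
    ops = []
    read_len = 0
    if rng.random() < 0.3:
        ops.append(("H", int(rng.integers(1, 6))))
    if rng.random() < 0.4:
        n = int(rng.integers(1, 10))
        ops.append(("S", n))
        read_len += n
    n_blocks = int(rng.integers(1, 5))
    for b in range(n_blocks):
        n = int(rng.integers(1, 30))
        op = rng.choice(["M", "=", "X"], p=[0.7, 0.15, 0.15])
        ops.append((str(op), n))
        read_len += n
        if b < n_blocks - 1 and rng.random() < 0.6:
            kind = rng.choice(["I", "D", "N"])
            ln = int(rng.integers(1, 6))
            ops.append((str(kind), ln))
            if kind == "I":
                read_len += ln
    if rng.random() < 0.4:
        n = int(rng.integers(1, 10))
        ops.append(("S", n))
        read_len += n
    if rng.random() < 0.3:
        ops.append(("H", int(rng.integers(1, 6))))
    ref_start = int(rng.integers(0, 100000))
    return ops, read_len, ref_start


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A small synthetic run shared by read-only tests: 12 sites, 4 files."""
    from modfreq.synth import default_truth_grid, generate_run

    out = tmp_path_factory.mktemp("smallrun")
    truth = default_truth_grid(n_sites=12, depth=40, seed=11)
    paths, truth_path = generate_run(truth, 4, out)
    return truth, paths, truth_path
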