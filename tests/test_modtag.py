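"""MM/ML tag parsing and per-read decoding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_tag_case
from modfreq.modtag import (
    DecodeStats,
    ModItem,
    ModTagError,
    byte_to_probability,
    decode_read_calls,
    pair_probabilities,
    parse_mm,
)
from modfreq.synth import encode_item
from oracles import oracle_decode


class TestParseMM:
    def test_single_explicit_item(self):
        (item,) = parse_mm("C+m?,0,2,0;")
        assert item == ModItem("C", "+", ("m",), "explicit", (0, 2, 0))

    def test_empty_tag_yields_no_items(self):
        assert parse_mm("") == []

    def test_multi_code_and_default_implicit_mode(self):
        items = parse_mm("C+mh,1,0;A+a.,0;")
        assert items[0] == ModItem("C", "+", ("m", "h"), "implicit", (1, 0))
        assert items[1] == ModItem("A", "+", ("a",), "implicit", (0,))

    def test_chebi_numeric_code_kept_verbatim(self):
        (item,) = parse_mm("C+76792?,5;")
        assert item.codes == ("76792",)

    def test_item_with_no_deltas_calls_nothing(self):
        (item,) = parse_mm("C+m?;")
        assert item.deltas == ()

    @pytest.mark.parametrize(
        "bad",
        [
            "C+m,x,2;",  # non-numeric delta
            "Z+m,0;",  # bad base
            "Cm,0;",  # missing strand
            "C+,0;",  # empty code list
            "C+m,0;garbage",  # trailing garbage
            "C+m,0;;",  # stray empty item
        ],
    )
    def test_malformed_items_raise(self, bad):
        with pytest.raises(ModTagError):
            parse_mm(bad)


class TestPairProbabilities:
    def test_byte_midpoint_scaling(self):
        items = parse_mm("C+m,0,0;")
        assert pair_probabilities(items, [255, 0]) == [
            [[0.998046875], [0.001953125]]
        ]

    def test_multi_code_interleaving_within_one_position(self):
        items = parse_mm("C+mh,0;")
        assert pair_probabilities(items, [200, 10]) == [
            [[0.783203125, 0.041015625]]
        ]

    def test_length_mismatch_reports_expected_count(self):
        items = parse_mm("C+m,0,0;")
        with pytest.raises(ModTagError, match="expected 2"):
            pair_probabilities(items, [255])

    def test_byte_out_of_range_rejected(self):
        with pytest.raises(ModTagError):
            byte_to_probability(256)


class TestDecodeReadCalls:
    def _decode(self, seq, is_reverse, mm, ml, **kw):
        items = parse_mm(mm)
        return decode_read_calls(
            seq, is_reverse, items, pair_probabilities(items, ml), **kw
        )

    def test_forward_delta_walk_over_base_occurrences(self):
        calls = self._decode("ACGTCGACG", False, "C+m,0,1;", [230, 20])
        assert [(c.read_pos, round(c.probability, 9)) for c in calls] == [
            (1, 0.900390625),
            (7, 0.080078125),
        ]

    def test_reverse_record_positions_flip_to_stored_coordinates(self):
        # original read is revcomp("AACG") = "CGTT"; its first C is
        # original index 0, i.e. stored index 3
        (call,) = self._decode("AACG", True, "C+m,0;", [128])
        assert call.read_pos == 3
        assert call.probability == 0.501953125

    def test_overrun_when_base_absent(self):
        with pytest.raises(ModTagError, match="overran"):
            self._decode("AAAA", False, "C+m,0;", [10])

    def test_minus_strand_items_dropped_and_counted(self):
        stats = DecodeStats()
        calls = self._decode("ACGT", False, "G-m,0;", [99], stats=stats)
        assert calls == []
        assert stats.minus_strand_items_dropped == 1

    def test_implicit_fill_emits_probability_zero_calls(self):
        # three Cs; delta 2 skips two of them
        on = self._decode("CCC", False, "C+m.,2;", [250], implicit_fill=True)
        off = self._decode("CCC", False, "C+m.,2;", [250])
        assert [(c.read_pos, c.implicit) for c in on] == [
            (0, True),
            (1, True),
            (2, False),
        ]
        assert all(c.probability == 0.0 for c in on if c.implicit)
        assert [(c.read_pos, c.implicit) for c in off] == [(2, False)]

    def test_explicit_mode_never_fills(self):
        calls = self._decode("CCC", False, "C+m?,2;", [250], implicit_fill=True)
        assert len(calls) == 1 and not calls[0].implicit

    def test_n_base_matches_every_position(self):
        calls = self._decode("ACGT", False, "N+n,3;", [100])
        assert calls[0].read_pos == 3


def _as_tuples(calls):
    return sorted((c.read_pos, c.code, c.probability, c.implicit) for c in calls)


@pytest.mark.parametrize("implicit_fill", [False, True])
def test_decoder_agrees_with_character_walk_oracle(implicit_fill):
    rng = np.random.default_rng(7101)
    for _ in range(300):
        seq, rev, mm, ml = random_tag_case(rng, allow_minus_items=True)
        items = parse_mm(mm)
        got = decode_read_calls(
            seq, rev, items, pair_probabilities(items, ml),
            implicit_fill=implicit_fill,
        )
        want = oracle_decode(seq, rev, mm, ml, implicit_fill=implicit_fill)
        assert _as_tuples(got) == sorted(want)


def test_probabilities_lie_in_midpoint_range():
    rng = np.random.default_rng(88)
    for _ in range(200):
        seq, rev, mm, ml = random_tag_case(rng)
        items = parse_mm(mm)
        for call in decode_read_calls(seq, rev, items, pair_probabilities(items, ml)):
            assert 1 / 512 <= call.probability <= 511 / 512


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**31 - 1),
    is_reverse=st.booleans(),
    explicit=st.booleans(),
)
def test_encode_decode_round_trip(seed, is_reverse, explicit):
    """Encoding random calls into MM/ML and decoding returns them exactly."""
    from oracles import revcomp

    rng = np.random.default_rng(seed)
    length = int(rng.integers(10, 80))
    original = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    base = "ACGT"[int(rng.integers(0, 4))]
    occ = [i for i, c in enumerate(original) if c == base]
    if not occ:
        return
    codes = ["m", "h"][: int(rng.integers(1, 3))]
    k = int(rng.integers(1, len(occ) + 1))
    chosen = sorted(rng.choice(len(occ), size=k, replace=False))
    truth = [
        (occ[i], [int(b) for b in rng.integers(0, 256, size=len(codes))])
        for i in chosen
    ]
    mm, ml = encode_item(original, base, codes, truth, explicit=explicit)
    seq_stored = revcomp(original) if is_reverse else original
    items = parse_mm(mm)
    calls = decode_read_calls(
        seq_stored, is_reverse, items, pair_probabilities(items, ml)
    )
    want = sorted(
        (
            length - 1 - pos if is_reverse else pos,
            code,
            (byte + 0.5) / 256.0,
        )
        for pos, row in truth
        for code, byte in zip(codes, row)
    )
    got = sorted((c.read_pos, c.code, c.probability) for c in calls)
    assert got == want
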