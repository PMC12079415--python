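"""Synthetic run generator: validity, determinism, truth recovery, playback."""

import math
import os
import threading

import pysam
import pytest

from modfreq.engine import Engine, EngineConfig
from modfreq.freqstore import SiteKey
from modfreq.synth import (
    TruthSite,
    TruthTable,
    default_truth_grid,
    generate_run,
    load_truth_tsv,
    timed_playback,
)
from modfreq.watcher import DirectoryWatcher


class TestGeneratedFiles:
    def test_files_parse_sorted_and_indexed(self, small_run):
        truth, paths, _ = small_run
        assert len(paths) == 4
        for path in paths:
            assert os.path.exists(path + ".bai")
            with pysam.AlignmentFile(path) as bam:
                assert bam.header["HD"]["SO"] == "coordinate"
                positions = [r.reference_start for r in bam.fetch(until_eof=True)]
            assert positions == sorted(positions)

    def test_depth_is_split_across_files(self, small_run):
        truth, paths, _ = small_run
        total = 0
        for path in paths:
            with pysam.AlignmentFile(path) as bam:
                total += bam.count(until_eof=True)
        assert total == len(truth.sites) * truth.read_depth

    def test_truth_tsv_round_trips(self, small_run):
        truth, _, truth_path = small_run
        assert load_truth_tsv(truth_path) == truth.sites

    def test_same_seed_reproduces_identical_reads(self, tmp_path):
        truth = default_truth_grid(n_sites=4, depth=10, seed=42)
        p1, _ = generate_run(truth, 2, tmp_path / "a")
        p2, _ = generate_run(truth, 2, tmp_path / "b")

        def read_tuples(paths):
            out = []
            for p in paths:
                with pysam.AlignmentFile(p) as bam:
                    out += [r.to_string() for r in bam.fetch(until_eof=True)]
            return out

        assert read_tuples(p1) == read_tuples(p2)

    def test_decoder_agrees_with_pysam_modified_bases(self, small_run):
        """Independent cross-check: pysam's own MM/ML accessor sees the same
        (position, byte) calls as the package decoder on generated reads."""
        from modfreq.modtag import decode_read_calls, pair_probabilities, parse_mm

        _, paths, _ = small_run
        checked = 0
        with pysam.AlignmentFile(paths[0]) as bam:
            for rec in bam.fetch(until_eof=True):
                items = parse_mm(rec.get_tag("MM"))
                probs = pair_probabilities(items, list(rec.get_tag("ML")))
                ours = {
                    (c.read_pos, round(c.probability * 256 - 0.5))
                    for c in decode_read_calls(
                        rec.query_sequence, rec.is_reverse, items, probs
                    )
                }
                theirs = {
                    (pos, qual)
                    for calls in rec.modified_bases.values()
                    for pos, qual in calls
                }
                assert ours == theirs
                checked += 1
        assert checked > 0


class TestRecovery:
    def test_degenerate_sites_recover_exactly(self, tmp_path):
        sites = [
            TruthSite("synthetic1", 500, "+", "m", 0.0),
            TruthSite("synthetic1", 800, "-", "m", 1.0),
        ]
        truth = TruthTable(sites=sites, read_depth=50, seed=5)
        paths, _ = generate_run(truth, 2, tmp_path)
        eng = Engine(EngineConfig())
        eng.run_paths(paths)
        for site, want in zip(sites, (0.0, 1.0)):
            cell = eng.table.get(
                SiteKey(site.contig, site.ref_pos, site.strand, site.code)
            )
            assert cell.n_called == 50
            assert cell.frequency == want

    def test_intermediate_frequency_within_binomial_error(self, tmp_path):
        truth = TruthTable(
            sites=[TruthSite("synthetic1", 500, "+", "m", 0.5)],
            read_depth=200,
            seed=7,
        )
        paths, _ = generate_run(truth, 1, tmp_path)
        eng = Engine(EngineConfig())
        eng.run_paths(paths)
        cell = eng.table.get(SiteKey("synthetic1", 500, "+", "m"))
        se = math.sqrt(0.5 * 0.5 / 200)
        assert abs(cell.frequency - 0.5) <= 3 * se

    def test_noisy_mode_populates_the_ambiguous_band(self, tmp_path):
        truth = TruthTable(
            sites=[TruthSite("synthetic1", 500, "+", "m", 0.5)],
            read_depth=300,
            seed=9,
            noisy=True,
        )
        paths, _ = generate_run(truth, 1, tmp_path)
        eng = Engine(EngineConfig())
        eng.run_paths(paths)
        cell = eng.table.get(SiteKey("synthetic1", 500, "+", "m"))
        assert cell.n_skipped > 0
        assert cell.n_called + cell.n_skipped == 300


class TestPlayback:
    def test_watcher_receives_played_back_files_in_order(self, small_run, tmp_path):
        _, paths, _ = small_run
        watch_dir = tmp_path / "live"
        watch_dir.mkdir()
        w = DirectoryWatcher(
            watch_dir, ".bam", stability_interval=0.15, poll_interval=0.03
        )
        stop = threading.Event()
        got = []

        def drain():
            for p in w.watch(stop):
                got.append(os.path.basename(p))
                if len(got) == 3:
                    stop.set()

        t = threading.Thread(target=drain, daemon=True)
        t.start()
        timed_playback(paths[:3], watch_dir, interval_s=0.2)
        t.join(15)
        assert got == ["batch_0.bam", "batch_1.bam", "batch_2.bam"]

    def test_preprocessed_paths_are_skipped(self, small_run, tmp_path):
        _, paths, _ = small_run
        watch_dir = tmp_path / "live2"
        watch_dir.mkdir()
        pre = os.path.join(str(watch_dir), "batch_0.bam")
        w = DirectoryWatcher(
            watch_dir, ".bam", processed=[pre],
            stability_interval=0.15, poll_interval=0.03,
        )
        stop = threading.Event()
        got = []

        def drain():
            for p in w.watch(stop):
                got.append(os.path.basename(p))
                if len(got) == 2:
                    stop.set()

        t = threading.Thread(target=drain, daemon=True)
        t.start()
        timed_playback(paths[:3], watch_dir, interval_s=0.1)
        t.join(15)
        assert got == ["batch_1.bam", "batch_2.bam"]

    def test_zero_files_is_a_clean_noop(self, tmp_path):
        assert timed_playback([], tmp_path, 0.1) == []
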