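"""Trimming semantics, adapter fraction, and the CSV report."""

from __future__ import annotations

import csv

import pytest

from adapterid.inference import AdapterCall, STATUS_ALREADY_TRIMMED, STATUS_OK
from adapterid.sequence_io import Read
from adapterid.simulate import SimConfig, simulate_library
from adapterid.trim import (
    TrimStats,
    adapter_fraction,
    trim_3p,
    trim_5p,
    trim_library,
    write_report,
)
from conftest import random_seq

ADAPTER = "TGGAATTCTCGGGTGCCAAG"


class TestTrim3p:
    def test_exact_internal_match(self):
        insert = "ACGTACGTACGTACGTAA"
        read = Read("x", insert + ADAPTER + "CCGG", "I" * (len(insert) + len(ADAPTER) + 4))
        out = trim_3p(read, ADAPTER)
        assert out.seq == insert
        assert out.qual == "I" * len(insert)

    def test_prefix_overlap_at_read_end(self):
        insert = "ACGTACGTACGTACGTAA"
        read = Read("x", insert + ADAPTER[:3])
        assert trim_3p(read, ADAPTER, min_overlap=3).seq == insert

    def test_no_match_is_noop(self):
        read = Read("x", "ACGTACGTACGTACGTACGT")
        assert trim_3p(read, "CCCCCCCCCC") == read

    def test_error_tolerance(self):
        insert = "ACGTACGTACGTACGTAA"
        mutated = "A" + ADAPTER[1:]  # one mismatch, within floor(0.1*20)=2
        assert trim_3p(Read("x", insert + mutated), ADAPTER).seq == insert

    def test_leftmost_match_wins(self):
        read = Read("x", "AAAA" + ADAPTER + "CCCC" + ADAPTER)
        assert trim_3p(read, ADAPTER).seq == "AAAA"


class TestTrim5p:
    FIVE = "ATTGATGGTGCCTACAGA"

    def test_full_sandwich(self):
        insert = "ACGTACGTACGTACGTAA"
        read = Read("x", self.FIVE + insert + ADAPTER)
        out = trim_3p(trim_5p(read, self.FIVE), ADAPTER)
        assert out.seq == insert

    def test_degraded_suffix_at_read_start(self):
        insert = "ACGTACGTACGTACGTAA"
        read = Read("x", self.FIVE[-10:] + insert)
        assert trim_5p(read, self.FIVE).seq == insert

    def test_no_match_is_noop(self):
        read = Read("x", "ACGTACGTACGTACGTACGT")
        assert trim_5p(read, "CCCCCCCCCC") == read


class TestAdapterFraction:
    def test_every_read_carries_adapter(self):
        reads, _ = simulate_library(SimConfig(seed=50, n_reads=500))
        assert adapter_fraction(reads, "TGGAATTCTCGGGTGCCAAGG") == 100.0

    def test_half_intact(self, rng):
        reads = []
        for i in range(2000):
            insert = random_seq(rng, 20)
            if i < 1000:
                reads.append(Read(str(i), insert + ADAPTER + random_seq(rng, 5)))
            else:
                reads.append(Read(str(i), insert + random_seq(rng, 25)))
        frac = adapter_fraction(reads, ADAPTER)
        assert 48.0 <= frac <= 53.0  # binomial noise + rare chance matches

    def test_absent_adapter_near_zero(self, rng):
        reads = [Read(str(i), random_seq(rng, 45)) for i in range(500)]
        # chance end-overlap rate is ~2.1%; allow binomial noise at n=500
        assert adapter_fraction(reads, ADAPTER) <= 5.0

    def test_planted_beats_random_16mer(self, rng):
        reads, _ = simulate_library(SimConfig(seed=51, n_reads=1000))
        planted = adapter_fraction(reads, "TGGAATTCTCGGGTGCCAAGG")
        other = adapter_fraction(reads, random_seq(rng, 16))
        assert planted >= other

    def test_idempotence_chance_bound(self, rng):
        # re-trimming already-trimmed reads only fires on chance end matches;
        # end-anchored overlaps of length k >= 3 are disjoint events with
        # probability 4^-k each, so the per-read rate is ~ (4/3) * 4^-3
        reads, _ = simulate_library(SimConfig(seed=52, n_reads=4000))
        call = AdapterCall(None, "TGGAATTCTCGGGTGCCAAGG", STATUS_OK)
        once, _ = trim_library(reads, call)
        twice, stats = trim_library(once, call)
        rate = stats.n_with_3p / stats.n_reads
        bound = (4 / 3) * 4 ** -3
        assert rate <= bound + 3 * (bound / 4000) ** 0.5


class TestRoundTrip:
    def test_trimmed_reads_equal_planted_inserts(self):
        from adapterid.inference import infer_illumina

        cfg = SimConfig(seed=53, n_reads=4000)
        reads, truth = simulate_library(cfg)
        call = infer_illumina(reads)
        assert call.status == STATUS_OK
        trimmed, _ = trim_library(reads, call)
        exact = sum(
            1 for r, t in zip(trimmed, truth.reads) if r.seq == t.insert
        )
        assert exact / len(reads) >= 0.99

    def test_barcoded_round_trip_strips_prefix_only(self):
        # an anchored barcode is removed as a fixed-position prefix; internal
        # occurrences of the barcode string inside inserts must survive
        from adapterid.inference import infer_illumina

        cfg = SimConfig(seed=54, n_reads=4000, barcode="ACTA")
        reads, truth = simulate_library(cfg)
        call = infer_illumina(reads)
        assert call.five_prime == "ACTA"
        trimmed, stats = trim_library(reads, call)
        exact = sum(
            1 for r, t in zip(trimmed, truth.reads) if r.seq == t.insert
        )
        assert exact / len(reads) >= 0.99
        assert stats.n_with_5p == len(reads)


class TestReport:
    def make_entries(self):
        ok = AdapterCall("ACTA", "TCGTATG", STATUS_OK, {"n_hsps": 10})
        trimmed = AdapterCall(None, None, STATUS_ALREADY_TRIMMED)
        stats = TrimStats(100, 90, 10, 90.0, 36.0, 22.5)
        return [("a.fastq", ok, stats), ("b,comma.fastq", trimmed, None)]

    def test_rows_and_quoting(self, tmp_path):
        path = tmp_path / "report.csv"
        write_report(self.make_entries(), path)
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        assert len(rows) == 3
        header, row_a, row_b = rows
        assert header[:4] == ["filename", "status", "five_prime", "three_prime"]
        assert row_a[1] == STATUS_OK and row_a[2] == "ACTA"
        # filename with a comma survives RFC-4180 quoting
        assert row_b[0] == "b,comma.fastq"
        # already_trimmed rows leave the adapter fields empty
        assert row_b[2] == "" and row_b[3] == ""

    def test_empty_entries_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_report([], tmp_path / "x.csv")
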