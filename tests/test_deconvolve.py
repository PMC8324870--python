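import gzip

import numpy as np
import pytest

import dropscreen as ds
from dropscreen.errors import ParseError

from conftest import fastq_text, make_read


class TestSpacerFilter:
    def test_exact_spacer_passes(self):
        assert ds.match_spacer("A" * 17 + "CGAA" + "T" * 20)

    def test_one_mismatch_passes(self):
        assert ds.match_spacer("A" * 17 + "CGAT" + "T" * 20)

    def test_two_mismatches_fail(self):
        assert not ds.match_spacer("A" * 17 + "CGTT" + "T" * 20)

    def test_n_counts_as_mismatch(self):
        assert ds.match_spacer("A" * 17 + "CGAN" + "T" * 20)
        assert not ds.match_spacer("A" * 17 + "CGNN" + "T" * 20)

    def test_short_read_fails_without_exception(self):
        assert not ds.match_spacer("A" * 20)


class TestExtraction:
    def test_targeting_positions_23_to_40(self):
        barcode = "ACGTACGTACGTACGTAC"
        read = make_read(barcode)
        assert ds.extract_barcode(read, "targeting_layout") == barcode

    def test_nontargeting_positions_1_to_18(self):
        read = "TTTTGGGGCCCCAAAATT" + "G" * 30
        assert ds.extract_barcode(read, "nontargeting_layout") == "TTTTGGGGCCCCAAAATT"

    def test_39nt_targeting_read_fails(self):
        assert ds.extract_barcode("A" * 39, "targeting_layout") is None


class TestAssignment:
    def test_exact_match(self, toy_library):
        m = ds.BarcodeMatcher(toy_library)
        assert m.assign("A" * 18) == "h1"

    def test_unique_one_mismatch(self, toy_library):
        m = ds.BarcodeMatcher(toy_library)
        assert m.assign("C" + "A" * 17) == "h1"

    def test_ambiguous_distance_one_unassigned(self):
        # "TAAAA..." is at distance 1 from both library barcodes
        lib = ds.ShrnaLibrary(
            [
                ds.Hairpin("h1", "AAAAAAAAAAAAAAAAAA", "G1", "targeting"),
                ds.Hairpin("h2", "TCAAAAAAAAAAAAAAAA", "G2", "targeting"),
            ]
        )
        m = ds.BarcodeMatcher(lib)
        assert m.assign("TAAAAAAAAAAAAAAAAA") is None

    def test_distance_two_unassigned(self, toy_library):
        m = ds.BarcodeMatcher(toy_library)
        assert m.assign("CC" + "A" * 16) is None

    def test_exact_match_wins_over_neighbor(self):
        # h2's barcode is at distance 1 from h1's; each must map to itself
        lib = ds.ShrnaLibrary(
            [
                ds.Hairpin("h1", "AAAAAAAAAAAAAAAAAA", "G1", "targeting"),
                ds.Hairpin("h2", "CAAAAAAAAAAAAAAAAA", "G2", "targeting"),
            ]
        )
        m = ds.BarcodeMatcher(lib)
        assert m.assign("AAAAAAAAAAAAAAAAAA") == "h1"
        assert m.assign("CAAAAAAAAAAAAAAAAA") == "h2"


class TestCountSample:
    def test_hand_built_fastq(self, tmp_path, toy_library):
        reads = [
            make_read("A" * 18),             # h1
            make_read("A" * 18),             # h1
            make_read("C" * 18),             # h2
            make_read("A" * 18, spacer="CTTA"),  # spacer fail (2 mismatches)
        ]
        path = tmp_path / "s.fastq"
        path.write_text(fastq_text(reads))
        counts, tallies = ds.count_sample(path, toy_library)
        assert counts["h1"] == 2 and counts["h2"] == 1
        assert tallies == {
            "total_reads": 4,
            "spacer_fail": 1,
            "extraction_fail": 0,
            "unassigned": 0,
        }

    def test_empty_fastq(self, tmp_path, toy_library):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        counts, tallies = ds.count_sample(path, toy_library)
        assert counts.sum() == 0 and tallies["total_reads"] == 0

    def test_gzip_input(self, tmp_path, toy_library):
        path = tmp_path / "s.fastq.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(fastq_text([make_read("G" * 18)]))
        counts, _ = ds.count_sample(path, toy_library)
        assert counts["h3"] == 1

    def test_truncated_fastq_raises_with_location(self, tmp_path, toy_library):
        path = tmp_path / "bad.fastq"
        path.write_text("@r0\nACGT\n")  # missing plus/quality lines
        with pytest.raises(ParseError, match="read"):
            ds.count_sample(path, toy_library)

    def test_conservation(self, tmp_path, toy_library):
        reads = [
            make_read("A" * 18),
            make_read("A" * 18, spacer="GGGG"),
            make_read("ACACACACACACACACAC"),  # unassigned (far from all)
            "A" * 30,                          # passes spacer? no: spacer region AAAA
        ]
        path = tmp_path / "s.fastq"
        path.write_text(fastq_text(reads))
        counts, t = ds.count_sample(path, toy_library)
        assert (
            counts.sum() + t["spacer_fail"] + t["extraction_fail"] + t["unassigned"]
            == t["total_reads"]
        )


def test_simulated_fastq_round_trip(tmp_path, small_library, small_config):
    """Error-free simulator FASTQ deconvolves to the exact read allocation."""
    import dataclasses

    cfg = dataclasses.replace(small_config, seq_error_rate=0.0, depth=3_000)
    counts, _props = ds.simulate_reference(small_library, cfg, seed=3)
    path = tmp_path / "sim.fastq"
    ds.write_fastq(counts, small_library, path, cfg, seed=4)
    observed, tallies = ds.count_sample(path, small_library)
    assert np.array_equal(observed.to_numpy(), counts)
    assert tallies["unassigned"] == 0 and tallies["spacer_fail"] == 0


def test_assigned_fraction_decreases_with_error_rate(tmp_path, small_library, small_config):
    import dataclasses

    fractions = []
    base_counts, _ = ds.simulate_reference(
        small_library, dataclasses.replace(small_config, depth=2_000), seed=5
    )
    for err in (0.0, 0.05, 0.4):
        cfg = dataclasses.replace(small_config, seq_error_rate=err, depth=2_000)
        path = tmp_path / f"e{err}.fastq"
        ds.write_fastq(base_counts, small_library, path, cfg, seed=6)
        counts, t = ds.count_sample(path, small_library)
        fractions.append(counts.sum() / t["total_reads"])
    assert fractions[0] == 1.0
    assert fractions[0] > fractions[1] > fractions[2]


def test_count_samples_builds_matrix(tmp_path, toy_library):
    for name, bc in [("ref", "A" * 18), ("t1", "C" * 18)]:
        (tmp_path / f"{name}.fastq").write_text(fastq_text([make_read(bc)] * 3))
    sheet = ds.SampleSheet(
        [
            ds.Sample("ref", "m1", "reference", 0, "ref.fastq"),
            ds.Sample("t1", "m1", "tumor_replicate", 1, "t1.fastq"),
        ]
    )
    matrix = ds.count_samples(sheet, toy_library, fastq_dir=tmp_path)
    assert matrix.counts.loc["h1", "ref"] == 3
    assert matrix.counts.loc["h2", "t1"] == 3
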