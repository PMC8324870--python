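import dataclasses
import math

import numpy as np
import pytest

import dropscreen as ds
from dropscreen.errors import ValidationError


class TestBuildLibrary:
    def test_tiny_library(self):
        cfg = ds.SimConfig(n_genes=2, hairpins_per_gene=1, control_hairpins=2)
        lib = ds.build_library(cfg, seed=0)
        assert len(lib.genes("targeting")) == 2
        assert sum(e.klass == "targeting" for e in lib.entries) == 2

    def test_barcode_distance_at_least_three(self, small_library):
        codes = np.array([[ord(c) for c in bc] for bc in small_library.barcodes])
        n = len(codes)
        dmin = min(
            (codes[i] != codes[j]).sum() for i in range(n) for j in range(i + 1, n)
        )
        assert dmin >= 3

    def test_control_genes_present(self, small_library, small_config):
        assert small_library.klass_of_gene()["RPL30"] == "positive_control"
        assert small_library.klass_of_gene()["PSMA1"] == "positive_control"
        assert small_library.klass_of_gene()["LUC"] == "negative_control"
        for g in ("RPL30", "PSMA1", "LUC"):
            assert len(small_library.hairpins_of(g)) == small_config.control_hairpins


class TestConfig:
    def test_moi_bounds(self):
        with pytest.raises(ValidationError):
            ds.SimConfig(moi=0.0)
        with pytest.raises(ValidationError):
            ds.SimConfig(moi=2.0)

    def test_effect_bounds(self):
        with pytest.raises(ValidationError):
            ds.SimConfig(pan_essential_effect=1.5)

    def test_infected_fraction_is_metadata(self):
        assert math.isclose(ds.SimConfig().infected_fraction, 1 - math.exp(-0.3))


class TestReference:
    def test_deterministic(self, small_library, small_config):
        a, _ = ds.simulate_reference(small_library, small_config, seed=1)
        b, _ = ds.simulate_reference(small_library, small_config, seed=1)
        c, _ = ds.simulate_reference(small_library, small_config, seed=2)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_high_concentration_is_near_uniform(self, small_library, small_config):
        cfg = dataclasses.replace(small_config, library_skew_alpha=1e7, depth=1_000_000)
        counts, _ = ds.simulate_reference(small_library, cfg, seed=1)
        _, gini = ds.representation_stats(counts)
        assert gini < 0.05

    def test_zero_depth(self, small_library, small_config):
        cfg = dataclasses.replace(small_config, depth=0)
        counts, _ = ds.simulate_reference(small_library, cfg, seed=1)
        assert counts.sum() == 0


class TestTumor:
    def test_null_effects_mean_lfc_near_zero(self, small_library, small_config):
        cfg = dataclasses.replace(small_config, depth=2_000_000, cells_per_mouse=2_000_000)
        ref_counts, props = ds.simulate_reference(small_library, cfg, seed=2)
        tumor = ds.simulate_tumor(props, np.zeros(small_library.n), cfg, seed=3)
        lfc = ds.log_fold_change(
            ds.normalize_counts(tumor), ds.normalize_counts(ref_counts), 0.5
        )
        assert abs(lfc.mean()) < 0.05

    def test_planted_effect_gives_expected_depletion(self, small_library, small_config):
        """One hairpin with s*e = 0.5 and T = 10 loses ~5 log2 units."""
        cfg = dataclasses.replace(small_config, depth=5_000_000, cells_per_mouse=5_000_000)
        effect = np.zeros(small_library.n)
        effect[0] = 0.5
        _, props = ds.simulate_reference(small_library, cfg, seed=4)
        tumor = ds.simulate_tumor(props, effect, cfg, seed=5)
        ref_rpm = ds.normalize_counts(props * cfg.depth)
        lfc = ds.log_fold_change(ds.normalize_counts(tumor), ref_rpm, 0.5)
        # depleted barcode shrinks the denominator pool only slightly, so
        # the observed LFC sits near -T*s*e within sampling error
        assert -5.6 < lfc[0] < -4.4

    def test_effect_monotonically_deepens_depletion(self, small_library, small_config):
        _, props = ds.simulate_reference(small_library, small_config, seed=6)
        means = []
        for s in (0.0, 0.2, 0.5):
            effect = np.full(small_library.n, 0.0)
            effect[:5] = s
            tumor = ds.simulate_tumor(props, effect, small_config, seed=7)
            lfc = ds.log_fold_change(
                ds.normalize_counts(tumor + 1), ds.normalize_counts(props * small_config.depth), 0.5
            )
            means.append(lfc[:5].mean())
        assert means[0] > means[1] > means[2]


class TestFastq:
    def test_round_trip_exact(self, tmp_path, small_library, small_config):
        cfg = dataclasses.replace(small_config, seq_error_rate=0.0)
        counts = np.zeros(small_library.n, dtype=int)
        counts[0], counts[3] = 2, 1
        path = tmp_path / "t.fastq"
        ds.write_fastq(counts, small_library, path, cfg, seed=1)
        observed, tallies = ds.count_sample(path, small_library)
        assert tallies["total_reads"] == 3
        assert np.array_equal(observed.to_numpy(), counts)

    def test_fixed_seed_byte_identical(self, tmp_path, small_library, small_config):
        counts = np.ones(small_library.n, dtype=int)
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        ds.write_fastq(counts, small_library, p1, small_config, seed=9)
        ds.write_fastq(counts, small_library, p2, small_config, seed=9)
        assert p1.read_bytes() == p2.read_bytes()

    def test_error_rate_one_assigns_nothing(self, tmp_path, small_library, small_config):
        cfg = dataclasses.replace(small_config, seq_error_rate=1.0)
        counts = np.ones(small_library.n, dtype=int)
        path = tmp_path / "e.fastq"
        ds.write_fastq(counts, small_library, path, cfg, seed=2)
        observed, tallies = ds.count_sample(path, small_library)
        assert observed.sum() == 0
        assert tallies["total_reads"] == small_library.n

    def test_gzip_output(self, tmp_path, small_library, small_config):
        cfg = dataclasses.replace(small_config, seq_error_rate=0.0)
        counts = np.zeros(small_library.n, dtype=int)
        counts[1] = 4
        path = tmp_path / "t.fastq.gz"
        ds.write_fastq(counts, small_library, path, cfg, seed=1)
        observed, _ = ds.count_sample(path, small_library)
        assert observed.iloc[1] == 4


class TestSuite:
    def test_structure(self, small_config, small_library):
        suite = ds.make_screen_suite(small_config, seed=0, library=small_library)
        n_samples = small_config.n_models * (1 + small_config.tumor_replicates)
        assert len(suite.counts.samples) == n_samples
        assert len(suite.sheet.screens) == small_config.n_models
        suite.counts.validate_against(suite.library)

    def test_truth_ledger_lists_pan_essentials_everywhere(self, small_config, small_library):
        suite = ds.make_screen_suite(small_config, seed=0, library=small_library)
        assert len(suite.truth.pan_essential) == small_config.n_pan_essential
        for model in suite.sheet.screens:
            for gene in suite.truth.pan_essential:
                assert suite.truth.gene_effect[model][gene] == small_config.pan_essential_effect

    def test_seeds_change_counts_not_structure(self, small_config, small_library):
        a = ds.make_screen_suite(small_config, seed=0, library=small_library)
        b = ds.make_screen_suite(small_config, seed=1, library=small_library)
        assert a.counts.samples == b.counts.samples
        assert not a.counts.counts.equals(b.counts.counts)

    def test_truth_round_trip(self, tmp_path, small_config, small_library):
        suite = ds.make_screen_suite(small_config, seed=0, library=small_library)
        path = tmp_path / "truth.json"
        suite.truth.to_json(path)
        back = ds.SimTruth.from_json(path)
        assert back == suite.truth
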