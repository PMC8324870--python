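import numpy as np
import pandas as pd
import pytest

import dropscreen as ds


@pytest.fixture(scope="session")
def default_config() -> ds.SimConfig:
    return ds.SimConfig()


@pytest.fixture(scope="session")
def default_suite(default_config) -> ds.ScreenSuite:
    """The default 4-model synthetic suite at a fixed seed."""
    return ds.make_screen_suite(default_config, seed=1)


@pytest.fixture(scope="session")
def small_config() -> ds.SimConfig:
    """Desk-scale screen: 20 genes x 5 hairpins, shallow sequencing."""
    return ds.SimConfig(
        n_genes=20,
        hairpins_per_gene=5,
        control_hairpins=4,
        cells_per_mouse=100_000,
        depth=200_000,
        n_models=2,
        tumor_replicates=2,
        n_pan_essential=2,
        n_model_specific=1,
    )


@pytest.fixture(scope="session")
def small_library(small_config) -> ds.ShrnaLibrary:
    return ds.build_library(small_config, seed=7)


@pytest.fixture()
def toy_library() -> ds.ShrnaLibrary:
    """Hand-built 4-hairpin library with controlled barcode distances."""
    return ds.ShrnaLibrary(
        [
            ds.Hairpin("h1", "AAAAAAAAAAAAAAAAAA", "GENE1", "targeting"),
            ds.Hairpin("h2", "CCCCCCCCCCCCCCCCCC", "GENE1", "targeting"),
            ds.Hairpin("h3", "GGGGGGGGGGGGGGGGGG", "RPL30", "positive_control"),
            ds.Hairpin("h4", "TTTTTTTTTTTTTTTTTT", "LUC", "negative_control"),
        ]
    )


def make_read(barcode: str, spacer: str = "CGAA", length: int = 50) -> str:
    """Targeting-layout read: 17-nt stub, spacer at 18-21, barcode at 23-40."""
    seq = "G" * 17 + spacer + "A" + barcode
    return (seq + "T" * length)[:length]


def fastq_text(seqs) -> str:
    return "".join(f"@r{i}\n{s}\n+\n{'I' * len(s)}\n" for i, s in enumerate(seqs))


@pytest.fixture()
def toy_counts(toy_library) -> ds.CountMatrix:
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        rng.integers(0, 50, size=(len(toy_library), 3)),
        index=toy_library.hairpin_ids,
        columns=["s_ref", "s_t1", "s_t2"],
    )
    return ds.CountMatrix(df)
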