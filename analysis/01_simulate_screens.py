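#!/usr/bin/env python
"""Simulate the default 4-model dropout-screen suite.

Generates the shared library (237 targeting genes x 10 hairpins plus
controls), one reference pool and three bottlenecked tumor replicates
per model, and the ground-truth ledger. Bulky intermediates (counts,
manifests) go to scratch/sim/; a small summary of what was planted is
written to results/.
"""

import json
from pathlib import Path

import dropscreen as ds

SEED = 1
SCRATCH = Path("scratch/sim")
RESULTS = Path("results")


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    config = ds.SimConfig()
    suite = ds.make_screen_suite(config, seed=SEED)

    ds.write_library(suite.library, SCRATCH / "library.tsv")
    ds.write_sample_sheet(suite.sheet, SCRATCH / "samples.tsv")
    ds.write_counts(suite.counts, SCRATCH / "counts.tsv")
    suite.truth.to_json(SCRATCH / "truth.json")

    summary = {
        "seed": SEED,
        "n_hairpins": suite.library.n,
        "n_targeting_genes": len(suite.library.genes("targeting")),
        "models": suite.sheet.screens,
        "samples_per_model": 1 + config.tumor_replicates,
        "mean_cells_per_barcode": config.cells_per_mouse / suite.library.n,
        "infected_fraction_at_moi": round(config.infected_fraction, 4),
        "planted_pan_essential": sorted(suite.truth.pan_essential),
        "planted_model_specific": {
            m: sorted(g) for m, g in suite.truth.model_specific.items()
        },
    }
    (RESULTS / "sim_summary.json").write_text(json.dumps(summary, indent=1))
    print(f"library: {summary['n_targeting_genes']} targeting genes, "
          f"{summary['n_hairpins']} hairpins total")
    print(f"mean cells/barcode at transplantation: {summary['mean_cells_per_barcode']:.0f} "
          "(inside the 1000-2000 representation band)")
    print(f"planted pan-model essentials: {summary['planted_pan_essential']}")
    print(f"counts and truth written to {SCRATCH}/")


if __name__ == "__main__":
    main()
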