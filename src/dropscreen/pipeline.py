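"""End-to-end orchestration: counts -> scores -> gene stats -> hits -> QC.

`analyze_screens` is the library entry point used by the CLI, the
analysis scripts and the tests; `run_pipeline` additionally writes the
artifact set (TSV tables, JSON summaries, run manifest) to a
directory. Reruns with the same inputs and config are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .hits import FDR_THRESHOLD, LOGP_THRESHOLD, call_hits, common_hits
from .library import CountMatrix, SampleSheet, ShrnaLibrary, write_counts
from .qc import qc_screen
from .rsa import gene_results
from .scoring import ScoringConfig, score_all_screens
from .simulate import SimConfig


@dataclass
class PipelineConfig:
    """All tunables of an analysis run, serializable to/from YAML."""

    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    fdr_method: str = "bh"
    permutation_iters: int = 100
    seed: int = 0
    logp_threshold: float = LOGP_THRESHOLD
    fdr_threshold: float = FDR_THRESHOLD
    sim: SimConfig = field(default_factory=SimConfig)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scoring = ScoringConfig(**raw.pop("scoring", {}))
        sim_raw = raw.pop("sim", {})
        if "good_hairpin_beta" in sim_raw:
            sim_raw["good_hairpin_beta"] = tuple(sim_raw["good_hairpin_beta"])
        if "weak_hairpin_beta" in sim_raw:
            sim_raw["weak_hairpin_beta"] = tuple(sim_raw["weak_hairpin_beta"])
        sim = SimConfig(**sim_raw)
        return cls(scoring=scoring, sim=sim, **raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ScreenAnalysis:
    """In-memory result bundle of one multi-screen analysis."""

    score_tables: dict[str, pd.DataFrame]
    gene_tables: dict[str, pd.DataFrame]
    hit_sets: dict[str, set[str]]
    common: set[str]
    membership: pd.DataFrame | None
    venn_regions: dict[str, int]
    qc: dict[str, dict]

    def report(self) -> dict:
        """JSON-ready summary: hit counts, common hits, QC highlights."""
        return {
            "screens": {
                s: {
                    "n_hits": len(self.hit_sets[s]),
                    "hits": sorted(self.hit_sets[s]),
                    "ssmd_controls": self.qc[s]["ssmd_controls"],
                    "auc_controls": self.qc[s]["auc_controls"],
                }
                for s in self.score_tables
            },
            "common_hits": sorted(self.common),
            "venn_regions": self.venn_regions,
        }


def analyze_screens(
    matrix: CountMatrix,
    library: ShrnaLibrary,
    sheet: SampleSheet,
    config: PipelineConfig = PipelineConfig(),
) -> ScreenAnalysis:
    """Score, test and hit-call every screen in the sample sheet.

    Hit thresholds are inclusive (RSA logP <= threshold and FDR q <=
    threshold); intersection across screens is reported whenever the
    sheet holds >= 2 screens.
    """
    matrix.validate_against(library)
    score_tables = score_all_screens(matrix, library, sheet, config.scoring)
    gene_tables = {
        s: gene_results(
            tbl,
            fdr_method=config.fdr_method,
            permutation_iters=config.permutation_iters,
            seed=config.seed,
        )
        for s, tbl in score_tables.items()
    }
    hit_sets = {
        s: call_hits(tbl, config.logp_threshold, config.fdr_threshold)
        for s, tbl in gene_tables.items()
    }
    if len(hit_sets) >= 2:
        common, membership, regions = common_hits(hit_sets)
    else:
        only = next(iter(hit_sets.values()))
        common, membership, regions = set(only), None, {}
    qc = {
        s: qc_screen(
            score_tables[s],
            matrix,
            library,
            [sheet.reference(s).sample_id] + [t.sample_id for t in sheet.tumors(s)],
        )
        for s in score_tables
    }
    return ScreenAnalysis(score_tables, gene_tables, hit_sets, common, membership, regions, qc)


def run_pipeline(
    matrix: CountMatrix,
    library: ShrnaLibrary,
    sheet: SampleSheet,
    outdir: str | Path,
    config: PipelineConfig = PipelineConfig(),
) -> ScreenAnalysis:
    """`analyze_screens` plus the on-disk artifact set and run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    analysis = analyze_screens(matrix, library, sheet, config)
    write_counts(matrix, outdir / "counts.tsv")
    for screen, tbl in analysis.score_tables.items():
        tbl.to_csv(outdir / f"scores_{screen}.tsv", sep="\t")
    for screen, tbl in analysis.gene_tables.items():
        tbl.to_csv(outdir / f"genes_{screen}.tsv", sep="\t")
    if analysis.membership is not None:
        analysis.membership.to_csv(outdir / "hit_membership.tsv", sep="\t")
    (outdir / "report.json").write_text(json.dumps(analysis.report(), indent=1, sort_keys=True))
    (outdir / "qc.json").write_text(json.dumps(analysis.qc, indent=1, sort_keys=True))
    manifest = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "config": asdict(config),
        "screens": sheet.screens,
        "n_hairpins": library.n,
    }
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )
    return analysis
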