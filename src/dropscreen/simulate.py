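"""Synthetic pooled-screen generator with ground truth.

The generator emulates the structure of an in vivo epigenome dropout
screen: a 237-gene x 10-hairpin targeting library plus positive
(RPL30, PSMA1) and negative (LUC) control genes, a skewed reference
pool, a multinomial engraftment bottleneck at transplantation
(3 x 10^6 cells over ~2,400 barcodes, i.e. ~1,250 cells/barcode,
inside the 1000-2000 cells/barcode representation band), deterministic
exponential growth over T population doublings with per-barcode
fitness 1 - s_gene * e_hairpin, and multinomial read sampling at the
sequencing depth. FASTQ emission reproduces the amplicon layout the
deconvolution stage expects (17-nt vector stub, CGAA spacer at 18-21,
skipped base 22, barcode at 23-40) with optional per-base substitution
errors.

MOI is carried as metadata only: at MOI 0.3 the infected fraction is
1 - exp(-0.3) ~ 0.26 and, under the single-integration assumption,
infection does not change the relative barcode distribution.

Every stochastic stage draws from a child of one master seed, keyed by
(model, replicate, stage), so suites are exactly reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .library import (
    BARCODE_LENGTH,
    CountMatrix,
    Hairpin,
    Sample,
    SampleSheet,
    ShrnaLibrary,
)

POSITIVE_CONTROL_GENES = ("RPL30", "PSMA1")
NEGATIVE_CONTROL_GENES = ("LUC",)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_VECTOR_STUB = "GTCAGTCAGTCAGTCAG"  # fixed 17-nt stub ahead of the spacer
_SPACER = "CGAA"
_SKIP_BASE = "A"  # position 22, ignored by extraction


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic screen suite.

    Defaults mirror the screen being emulated: 237 targeting genes x
    10 hairpins, 10 hairpins per control gene, MOI 0.3, 3 x 10^6
    transplanted cells/mouse, 3 tumor replicates in each of 4 models,
    5 pan-model essential genes at effect 0.5 plus 3 model-specific
    essentials per model, positive-control effect 0.8, T = 10
    population doublings, 5 x 10^6 reads/sample, 0.1% sequencing error
    on 50-nt reads, Dirichlet concentration 50 for plasmid-pool skew.
    """

    n_genes: int = 237
    hairpins_per_gene: int = 10
    control_hairpins: int = 10
    library_skew_alpha: float = 50.0
    moi: float = 0.3
    cells_per_mouse: int = 3_000_000
    tumor_replicates: int = 3
    n_models: int = 4
    doublings: float = 10.0
    depth: int = 5_000_000
    seq_error_rate: float = 0.001
    read_length: int = 50
    n_pan_essential: int = 5
    pan_essential_effect: float = 0.5
    n_model_specific: int = 3
    model_specific_effect: float = 0.5
    positive_control_effect: float = 0.8
    good_hairpin_beta: tuple[float, float] = (5.0, 1.0)
    weak_hairpin_beta: tuple[float, float] = (1.0, 3.0)
    weak_hairpins_per_gene: int = 2

    def __post_init__(self):
        if not (0 < self.moi <= 1.5):
            raise ValidationError("moi must be in (0, 1.5]")
        for name in ("n_genes", "hairpins_per_gene", "tumor_replicates", "n_models"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        for eff in (
            self.pan_essential_effect,
            self.model_specific_effect,
            self.positive_control_effect,
        ):
            if not (0.0 <= eff <= 1.0):
                raise ValidationError("effect sizes must lie in [0, 1]")

    @property
    def infected_fraction(self) -> float:
        """Poisson infected fraction 1 - exp(-MOI); metadata only."""
        return 1.0 - math.exp(-self.moi)


@dataclass
class SimTruth:
    """Ground-truth ledger: what was planted, where.

    ``gene_effect[model][gene]`` is the essentiality effect s in
    [0, 1] (0 for neutral genes); ``efficacy[hairpin_id]`` is the
    per-hairpin knockdown efficacy e, fixed across models. The net
    per-barcode fitness is 1 - s * e.
    """

    pan_essential: list[str]
    model_specific: dict[str, list[str]]
    gene_effect: dict[str, dict[str, float]]
    efficacy: dict[str, float]

    def effect_vector(self, model: str, library: ShrnaLibrary) -> np.ndarray:
        """s_gene * e_hairpin for every library entry, in library order."""
        eff = self.gene_effect[model]
        return np.array(
            [eff.get(e.gene, 0.0) * self.efficacy[e.hairpin_id] for e in library.entries]
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        return cls(**json.loads(Path(path).read_text()))


def _random_barcodes(n: int, rng: np.random.Generator, min_distance: int = 3) -> list[str]:
    """Random 18-mers with pairwise Hamming distance >= min_distance."""
    accepted = np.empty((0, BARCODE_LENGTH), dtype=np.uint8)
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 1_000_000:
            raise ValidationError("cannot satisfy barcode distance constraint")
        cand = rng.integers(0, 4, size=BARCODE_LENGTH).astype(np.uint8)
        if accepted.size and int((accepted != cand).sum(axis=1).min()) < min_distance:
            continue
        accepted = np.vstack([accepted, cand])
        out.append(_BASES[cand].tobytes().decode())
    return out


def build_library(config: SimConfig = SimConfig(), seed: int | np.random.SeedSequence = 0) -> ShrnaLibrary:
    """Synthetic targeting-layout library with control genes.

    Genes are named G0001..G0237 (targeting) plus the fixed positive
    and negative control symbols, each with ``control_hairpins``
    hairpins; barcodes are random 18-mers kept at pairwise Hamming
    distance >= 3 so 1-mismatch assignment is unambiguous.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    plan: list[tuple[str, str, int]] = [(g, "targeting", config.hairpins_per_gene) for g in genes]
    plan += [(g, "positive_control", config.control_hairpins) for g in POSITIVE_CONTROL_GENES]
    plan += [(g, "negative_control", config.control_hairpins) for g in NEGATIVE_CONTROL_GENES]
    total = sum(k for _, _, k in plan)
    barcodes = iter(_random_barcodes(total, rng))
    entries = [
        Hairpin(f"{gene}_sh{i + 1:02d}", next(barcodes), gene, klass)
        for gene, klass, k in plan
        for i in range(k)
    ]
    return ShrnaLibrary(entries, library_type="targeting_layout")


def build_truth(
    library: ShrnaLibrary,
    config: SimConfig = SimConfig(),
    seed: int | np.random.SeedSequence = 0,
    null: bool = False,
) -> SimTruth:
    """Plant essential genes and draw per-hairpin efficacies.

    Pan-model essentials are shared by all models; model-specific
    essentials are disjoint from them and from each other so recovery
    tests can separate the two tiers. With ``null=True`` every effect
    (controls included) is zero.
    """
    rng = np.random.default_rng(seed)
    targeting = library.genes("targeting")
    need = config.n_pan_essential + config.n_model_specific * config.n_models
    if need > len(targeting):
        raise ValidationError("more planted essentials than targeting genes")
    chosen = rng.choice(len(targeting), size=need, replace=False)
    pan = [targeting[i] for i in chosen[: config.n_pan_essential]]
    models = [f"model{m + 1}" for m in range(config.n_models)]
    specific: dict[str, list[str]] = {}
    cursor = config.n_pan_essential
    for model in models:
        specific[model] = [targeting[i] for i in chosen[cursor : cursor + config.n_model_specific]]
        cursor += config.n_model_specific

    gene_effect: dict[str, dict[str, float]] = {}
    for model in models:
        eff: dict[str, float] = {}
        if not null:
            for g in pan:
                eff[g] = config.pan_essential_effect
            for g in specific[model]:
                eff[g] = config.model_specific_effect
            for g in POSITIVE_CONTROL_GENES:
                eff[g] = config.positive_control_effect
        gene_effect[model] = eff

    efficacy: dict[str, float] = {}
    a_good, b_good = config.good_hairpin_beta
    a_weak, b_weak = config.weak_hairpin_beta
    for gene in library.genes():
        hps = library.hairpins_of(gene)
        weak = set(
            rng.choice(len(hps), size=min(config.weak_hairpins_per_gene, len(hps)), replace=False)
        )
        for i, hp in enumerate(hps):
            a, b = (a_weak, b_weak) if i in weak else (a_good, b_good)
            efficacy[hp.hairpin_id] = float(rng.beta(a, b))
    return SimTruth(pan, specific, gene_effect, efficacy)


def simulate_reference(
    library: ShrnaLibrary,
    config: SimConfig = SimConfig(),
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """(read counts, pool proportions) of the pre-transplant reference.

    Pool proportions are Dirichlet(alpha) — plasmid-prep skew — and
    reads are one multinomial draw at the configured depth.
    """
    rng = np.random.default_rng(seed)
    props = rng.dirichlet(np.full(library.n, config.library_skew_alpha))
    counts = rng.multinomial(config.depth, props)
    return counts, props


def simulate_tumor(
    reference_proportions: np.ndarray,
    effect: np.ndarray,
    config: SimConfig = SimConfig(),
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Read counts of one tumor replicate.

    Engraftment: c ~ Multinomial(cells_per_mouse, reference
    proportions). Growth: weight w = c * 2^(T * f) with per-barcode
    fitness f = 1 - effect. Sequencing: reads ~ Multinomial(depth,
    w / sum w).
    """
    rng = np.random.default_rng(seed)
    props = np.asarray(reference_proportions, dtype=float)
    effect = np.asarray(effect, dtype=float)
    if props.shape != effect.shape:
        raise ValidationError("proportions and effects misaligned")
    cells = rng.multinomial(config.cells_per_mouse, props)
    weight = cells * np.exp2(config.doublings * (1.0 - effect))
    total = weight.sum()
    if total == 0:
        raise ValidationError("engraftment bottleneck lost every barcode")
    return rng.multinomial(config.depth, weight / total)


def write_fastq(
    counts: np.ndarray | pd.Series,
    library: ShrnaLibrary,
    path: str | Path,
    config: SimConfig = SimConfig(),
    seed: int | np.random.SeedSequence = 0,
    sample_id: str = "sample",
) -> None:
    """Emit one read per count unit in the targeting amplicon layout.

    Reads are stub(17) + CGAA + skipped base + barcode(18) + filler to
    ``read_length``, with i.i.d. substitution errors at
    ``seq_error_rate`` (an erroneous base is replaced by a uniformly
    random different base). With error rate 0 the file deconvolves
    back to ``counts`` exactly.
    """
    rng = np.random.default_rng(seed)
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape[0] != library.n:
        raise ValidationError("counts misaligned with library")
    length = config.read_length
    filler = "T" * max(0, length - (len(_VECTOR_STUB) + 4 + 1 + BARCODE_LENGTH))
    templates = [
        (_VECTOR_STUB + _SPACER + _SKIP_BASE + e.barcode + filler)[:length]
        for e in library.entries
    ]
    tmpl_bytes = np.frombuffer("".join(templates).encode(), dtype=np.uint8).reshape(
        library.n, length
    )
    reads = np.repeat(tmpl_bytes, counts, axis=0).copy()
    n_reads = reads.shape[0]
    if config.seq_error_rate > 0 and n_reads:
        err = rng.random(reads.shape) < config.seq_error_rate
        # shift each erroneous base by 1..3 within ACGT so it always changes
        idx = np.searchsorted(_BASES, reads[err])
        shift = rng.integers(1, 4, size=idx.shape)
        reads[err] = _BASES[(idx + shift) % 4]
    qual = "I" * length
    path = Path(path)
    import gzip

    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for i in range(n_reads):
            fh.write(
                f"@{sample_id}_{i}\n{reads[i].tobytes().decode()}\n+\n{qual}\n"
            )


@dataclass
class ScreenSuite:
    """One simulated multi-model screen: library, truth, counts, sheet."""

    library: ShrnaLibrary
    truth: SimTruth
    counts: CountMatrix
    sheet: SampleSheet
    config: SimConfig = field(default_factory=SimConfig)


def make_screen_suite(
    config: SimConfig = SimConfig(),
    seed: int = 0,
    library: ShrnaLibrary | None = None,
    null: bool = False,
) -> ScreenSuite:
    """Simulate the full multi-model suite in count-matrix mode.

    One shared library; per model, one reference pool and
    ``tumor_replicates`` bottlenecked tumors. All randomness descends
    from ``seed`` via named SeedSequence children. FASTQ emission is a
    separate step (:func:`write_fastq`) so desk-scale analyses can stay
    in count space.
    """
    root = np.random.SeedSequence(seed)
    lib_ss, truth_ss, samples_ss = root.spawn(3)
    if library is None:
        library = build_library(config, lib_ss)
    truth = build_truth(library, config, truth_ss, null=null)
    models = [f"model{m + 1}" for m in range(config.n_models)]
    model_seeds = samples_ss.spawn(config.n_models)
    cols: dict[str, np.ndarray] = {}
    samples: list[Sample] = []
    for model, mseed in zip(models, model_seeds):
        ref_ss, *tumor_ss = mseed.spawn(1 + config.tumor_replicates)
        ref_counts, props = simulate_reference(library, config, ref_ss)
        ref_id = f"{model}_ref"
        cols[ref_id] = ref_counts
        samples.append(Sample(ref_id, model, "reference", 0))
        effect = truth.effect_vector(model, library)
        for r, tss in enumerate(tumor_ss, start=1):
            tid = f"{model}_t{r}"
            cols[tid] = simulate_tumor(props, effect, config, tss)
            samples.append(Sample(tid, model, "tumor_replicate", r))
    counts = CountMatrix(pd.DataFrame(cols, index=library.hairpin_ids))
    return ScreenSuite(library, truth, counts, SampleSheet(samples), config)
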