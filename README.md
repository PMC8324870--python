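# dropscreen

Analysis of pooled in vivo shRNA dropout screens, for functional
genomics groups running barcode-based essentiality screens across
multiple tumor models (e.g. patient-derived xenografts). The package
covers the full path from raw barcode-amplicon FASTQ to cross-model
dependency calls, plus a seeded synthetic-screen simulator with ground
truth so every stage is testable at desk scale.

## What it computes

Reads are deconvolved by a spacer filter (`CGAA` at bases 18–21, one
mismatch allowed), positional barcode extraction (bases 23–40) and
exact/unique-1-mismatch matching against the library. Per-hairpin
counts are normalized to reads-per-million, turned into log2 fold
changes against the pre-transplant reference pool, and standardized as
robust z-scores

    z = (x − median(x)) / (1.4826 · MAD(x)),

averaged across tumor replicates and ranked (rank 1 = most depleted).
Gene-level evidence uses the redundant shRNA activity (RSA) statistic:
for a gene with hairpin ranks r₁ < … < rₙ among N hairpins,

    logP = log10 min_i P(X ≥ i),   X ~ Hypergeom(N, n, rᵢ),

computed in log space so values like −log₁₀ C(2370,10) ≈ −27 are
exact. Benjamini–Hochberg FDR is applied across genes within each
screen (a calibrated gene-label permutation FDR is available as an
alternative), and a gene is a hit when logP ≤ −1.5 and q ≤ 0.3;
genes hit in every screen are the common (pan-model) dependencies.
QC covers positive/negative control separation (SSMD, rank-sum AUC),
barcode representation (detected fraction, Gini), and the in vivo
study metrics TV = (L·W²)/2 and %TGI.

See `docs/methods.md` for the model, its assumptions and calibration
caveats (RSA's min-p is a ranking score, not a calibrated p-value).

## Worked example

Simulate the default 4-model suite (237 targeting genes × 10
hairpins, 3 tumor replicates per model, 5 planted pan-model essential
genes) and analyze it:

```python
import dropscreen as ds

suite = ds.make_screen_suite(ds.SimConfig(), seed=1)
analysis = ds.analyze_screens(suite.counts, suite.library, suite.sheet)
print(sorted(analysis.common))
print(sorted(suite.truth.pan_essential))
```

prints

```
['G0048', 'G0070', 'G0086', 'G0106', 'G0211']
['G0048', 'G0070', 'G0086', 'G0106', 'G0211']
```

— the five genes planted as essential in all four models are exactly
the cross-model common hits. The same run reports 29–31 hits within
each individual screen (the planted per-model essentials plus
neutral genes that pass the per-screen thresholds; single-screen
lists should be read as rankings, see the methods note) and control
separation AUC = 1.0 with median positive-control LFC ≈ −6.9 against
≈ 0.05 for the non-targeting controls.

The same pipeline is scriptable from the shell:

```bash
dropscreen simulate --seed 1 --outdir scratch/sim
dropscreen run --library scratch/sim/library.tsv \
               --samples scratch/sim/samples.tsv \
               --counts  scratch/sim/counts.tsv  --outdir scratch/out
```

and the numbered drivers under `analysis/` run the full study
narrative (simulate → deconvolve demo → score/hits → QC), writing
summary tables to `results/`.

## Layout

    src/dropscreen/   library_io, deconvolve, scoring, rsa, hits, qc,
                      simulate, pipeline, cli
    analysis/         numbered study drivers (simulate → ... → QC)
    tests/            unit, property (hypothesis) and end-to-end tests
    scripts/          acceptance.py
    docs/methods.md   model, assumptions, calibration, limitations
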