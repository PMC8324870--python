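# Methods

## The analysis problem

A pooled shRNA dropout screen infects a cell population with a
lentiviral library in which every hairpin carries a unique 18-nt
barcode, transplants the infected pool into recipient mice, lets
tumors grow, and sequences barcode amplicons from the pre-injection
reference pool and from several tumor replicates per model. Hairpins
targeting genes the tumor needs deplete relative to the reference.
The analysis must turn raw reads into per-gene essentiality calls that
are robust to two dominant noise sources: uneven hairpin efficacy
(most genes have several inert hairpins) and the stochastic
engraftment bottleneck (barcodes can be lost at transplantation for
purely demographic reasons).

## Pipeline

1. **Deconvolution** (`dropscreen.deconvolve`). Reads are kept if the
   4-bp spacer `CGAA` at 1-based positions 18–21 matches with at most
   one mismatch (`N` counts as a mismatch); the barcode is the slice
   at positions 23–40 for targeting libraries (1–18 for nontargeting
   layouts; position 22 is skipped by the amplicon design).
   Barcodes are matched to the library by exact lookup, then by unique
   Hamming-distance-1 lookup; ties at distance 1 are unassigned. All
   1-mismatch neighbors are precomputed into a dictionary, so matching
   is O(1) per read and deterministic. Per-sample tallies (total,
   spacer-fail, extraction-fail, unassigned) satisfy exact read
   conservation, which the tests assert.
2. **Scoring** (`dropscreen.scoring`). Counts are normalized to
   reads-per-million within each sample; the denominator is assigned
   reads, because spacer/assignment failures are technical artifacts
   of sequencing rather than biology. Log2 fold change against the
   screen's reference pool uses a symmetric pseudocount (default 0.5
   RPM) so that LFC(ref, ref) = 0 and true zeros (bottleneck losses)
   remain finite. Fold changes are converted to robust z-scores,
   z = (x − median)/(1.4826·MAD); the consistency constant puts z on
   the standard-deviation scale for Gaussian data and can be switched
   off (`mad_constant=1.0`) where raw median/MAD units are wanted.
   Replicate z-scores are averaged arithmetically (all provided
   replicates are used), then ranked ascending — rank 1 = most
   depleted — with stable tie-breaking by input order for determinism;
   percentile = rank/N.
3. **Gene statistics** (`dropscreen.rsa`). For a gene with hairpin
   ranks r_1 < … < r_n among N hairpins, RSA computes
   p_i = P(X ≥ i), X ~ Hypergeometric(N, n, r_i), and reports
   logP = log10 min_i p_i. The computation runs entirely in log space
   (log-gamma pmf + logsumexp), exact to ≈1e-12 against a rational-
   arithmetic oracle and free of underflow to at least N = 1e5. Only
   the depletion direction is scored, and all n hairpins participate.
   A vectorized path (`rsa_logp_matrix`) evaluates all order-statistic
   terms of many genes in one call; it is bit-compatible with the
   scalar path.
4. **FDR and hits** (`dropscreen.rsa`, `dropscreen.hits`). The default
   multiple-testing correction is Benjamini–Hochberg across genes
   within each screen. A gene is a hit when RSA logP ≤ −1.5 **and**
   q ≤ 0.3 (both inclusive); genes hit in every model are the
   pan-model dependencies. Hit calling considers targeting genes only
   by default: positive controls are essential by design and would
   otherwise trivially join every hit set — they are reported through
   QC instead. The top-3 mean z (mean of a gene's three most-depleted
   hairpin scores) is carried as the alternative per-gene summary.
5. **QC** (`dropscreen.qc`). Control separation between
   positive-control (RPL30, PSMA1) and negative-control (LUC) hairpin
   z-scores is summarized by SSMD and by rank-sum AUC; the original
   screen literature asserts "adequate separation" without naming a
   statistic, so these are this package's replacements, not
   reproductions. Representation is summarized by detected-barcode
   fraction and Gini coefficient. Animal-study arithmetic — tumor
   volume (L×W²)/2 and %TGI = 100·(1 − MTV_treated/MTV_control) — is
   included because screen campaigns report it alongside; positive
   %TGI means inhibition, and swapped calipers (width > length) are
   corrected with a warning.

## Calibration of the RSA statistic

Taking the minimum over n order-statistic tails makes rsa_p
anti-conservative: under a global null (ranks uniform without
replacement) its median is ≈0.15 and P(p ≤ 0.0316) ≈ 0.18 for
n = 10, N = 2400 — far from uniform. Two consequences, both measured
by the test suite:

* BH on rsa_p controls FDR only nominally; under a pure-null screen
  it calls ~35 spurious hits per screen at q ≤ 0.3. In a multi-model
  design this matters little for the *intersection* (spurious hits do
  not replicate across four models — the planted pan-model set is
  recovered exactly, with zero neutral genes, in 20/20 seeded suites),
  but single-screen hit lists should be read as rankings.
* A gene-label permutation FDR (`fdr_method="permutation"`), which
  shuffles gene labels over hairpins and compares observed p's to the
  regenerated null, is calibrated for the statistic and is provided
  for sensitivity analysis. Note that *any* procedure honestly
  controlling FDR at 0.3 may still reject something in up to 30% of
  null datasets; "zero hits under the null" is not a property FDR ≤
  0.3 can promise.

The tests therefore check that null-screen gene p's match the
uniform-rank permutation Monte-Carlo quantile-for-quantile, that the
anti-conservative offset is present, and that permutation-FDR null
hit counts never exceed BH's.

## What the simulator emulates

`dropscreen.simulate` generates the full study design: a library of
237 targeting genes × 10 hairpins plus 10 hairpins for each control
gene; a Dirichlet(α = 50)-skewed plasmid pool; per model, one
reference sample and three tumor replicates; four models sharing five
planted pan-model essential genes (effect s = 0.5) with three
model-specific essentials each (s = 0.5, disjoint sets); positive
controls at s = 0.8, negatives and neutral genes at s = 0.

The in vivo stage is a single multinomial engraftment bottleneck
(3×10⁶ cells over 2,400 barcodes ≈ 1,250 cells/barcode, inside the
1000–2000 cells/barcode representation band) followed by
deterministic exponential growth over T = 10 population doublings
with per-barcode fitness f = 1 − s·e, then one multinomial read draw
at 5×10⁶ reads/sample (≈2,000×/barcode, deep enough that counting
noise does not dominate planted effects). A hairpin with s·e = 0.5
therefore loses ≈ T·s·e = 5 log2 units, which the tests confirm
within sampling error. Hairpin efficacy e is heterogeneous — per
gene, 8 hairpins ~ Beta(5,1) and 2 ~ Beta(1,3), fixed across
models — so RSA's rank-redundancy logic is exercised realistically:
most genes have some inert hairpins. MOI 0.3 is carried as metadata
(infected fraction 1 − e^−0.3 ≈ 0.26); under the single-integration
assumption it does not change relative barcode abundances.

FASTQ emission reproduces the amplicon layout exactly (17-nt stub,
spacer, skipped base, barcode, filler to 50 nt) with i.i.d. per-base
substitution errors at 0.1%; with the error rate at zero,
deconvolution returns the simulated counts identically, which anchors
the round-trip tests.

What the simulator does **not** model: clonal interference, barcode
recombination, growth-rate stochasticity beyond the engraftment draw,
PCR jackpotting, position-dependent sequencing error, or
microenvironment effects. Passing recovery tests therefore show that
the statistics behave correctly under the design's sampling structure,
not that real screens of this size always separate this cleanly.

## Numerical and design choices

* All randomness descends from one master seed via named
  `SeedSequence` children per (model, replicate, stage); identical
  inputs and configs give byte-identical outputs.
* Random library barcodes are kept at pairwise Hamming distance ≥ 3
  by rejection sampling, so 1-mismatch assignment is provably
  unambiguous on simulator data.
* Degenerate inputs fail loudly: empty samples (normalization total
  0), constant score vectors (MAD = 0), zero variance in both control
  classes (SSMD undefined), duplicate barcodes/ids, mismatched matrix
  rows.
* Ranking ties are broken stably by input order (ties are measure-zero
  on continuous scores but must not introduce nondeterminism).
* Problem sizes in the tests: the default 2,400-hairpin, 16-sample
  suite is simulated in count-matrix mode (seconds); FASTQ round
  trips run at reduced depth (thousands of reads), which exercises the
  identical code path byte for byte.

## Known limitations

* RSA logP is a ranking score, not a calibrated p-value (see above);
  cross-model intersection, not single-screen FDR, carries the
  inferential weight.
* The per-screen normalization denominator (assigned reads) is a
  convention; if spacer-failed reads were biological in origin this
  would bias RPM slightly, but there is no mechanism for that in this
  amplicon design.
* The permutation FDR regenerates only gene-label exchangeability; it
  does not model inter-hairpin correlation from shared off-targets.
* No between-screen quantile normalization or batch correction is
  attempted; screens are analyzed independently and only combined at
  the hit-set level.
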