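"""Per-hairpin depletion scoring.

Counts are library-size normalized to reads-per-million within each
sample (denominator = assigned reads), log2 fold changes are taken
against the screen's reference pool with a symmetric pseudocount,
transformed into robust z-scores (median/MAD, consistency constant
1.4826 by default so the score is on the standard-deviation scale for
Gaussian data), averaged across tumor replicates, and finally ranked —
rank 1 = most depleted — with percentile rank/N feeding the gene-level
RSA statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .library import CountMatrix, SampleSheet, ShrnaLibrary

#: standard consistency constant making MAD estimate sigma under normality
MAD_CONSTANT = 1.4826


@dataclass(frozen=True)
class ScoringConfig:
    """Tunables of the hairpin scoring stage.

    pseudocount
        Reads-per-million added to both numerator and denominator of
        the fold change; in vivo bottlenecks produce true zero counts
        and the symmetric form keeps LFC(ref, ref) = 0. Default 0.5.
    mad_constant
        Scale factor applied to the MAD; set to 1.0 to report raw
        median/MAD units instead of sigma-consistent units.
    """

    pseudocount: float = 0.5
    mad_constant: float = MAD_CONSTANT

    def __post_init__(self):
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")
        if self.mad_constant <= 0:
            raise ValidationError("mad_constant must be > 0")


def normalize_counts(counts: np.ndarray | pd.Series, total: int | None = None) -> np.ndarray:
    """Library-size normalization to reads-per-million.

    ``total`` defaults to ``sum(counts)`` (assigned reads); the output
    sums to 1e6 exactly in that case.
    """
    arr = np.asarray(counts, dtype=float)
    if total is None:
        total = arr.sum()
    if total <= 0:
        raise ValidationError("empty sample: normalization total is 0")
    return arr / float(total) * 1e6


def log_fold_change(
    sample_norm: np.ndarray,
    reference_norm: np.ndarray,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """log2((sample + pc) / (reference + pc)), elementwise, in RPM units."""
    s = np.asarray(sample_norm, dtype=float)
    r = np.asarray(reference_norm, dtype=float)
    if s.shape != r.shape:
        raise ValidationError(f"length mismatch: {s.shape} vs {r.shape}")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    return np.log2((s + pseudocount) / (r + pseudocount))


def robust_z(values: np.ndarray, mad_constant: float = MAD_CONSTANT) -> np.ndarray:
    """Robust z-score: (x - median(x)) / (c * MAD(x)).

    MAD is the median absolute deviation from the median; ``c`` is the
    consistency constant (1.4826 by default). A constant input has
    MAD = 0 and raises, since the score is undefined.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("robust z needs at least 2 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise ValidationError("degenerate score distribution: MAD = 0")
    return (x - med) / (mad_constant * mad)


def aggregate_replicates(z_replicates: list[np.ndarray]) -> np.ndarray:
    """Elementwise arithmetic mean across tumor replicates."""
    if not z_replicates:
        raise ValidationError("no replicates to aggregate")
    arrs = [np.asarray(z, dtype=float) for z in z_replicates]
    if len({a.shape for a in arrs}) != 1:
        raise ValidationError("replicate z vectors have inconsistent lengths")
    return np.mean(arrs, axis=0)


def to_ranks(mean_z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ascending ranks 1..N (rank 1 = most depleted) and percentiles rank/N.

    Ties are broken stably by input order, so rankings are
    deterministic even in the presence of exactly equal scores.
    """
    x = np.asarray(mean_z, dtype=float)
    n = x.size
    if n < 1:
        raise ValidationError("cannot rank an empty vector")
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    return ranks, ranks / float(n)


def score_screen(
    matrix: CountMatrix,
    library: ShrnaLibrary,
    reference_sample: str,
    tumor_samples: list[str],
    config: ScoringConfig = ScoringConfig(),
) -> pd.DataFrame:
    """Full per-hairpin score table for one screen.

    Columns: gene, class, ``norm_<sample>`` for reference and tumors,
    ``lfc_<tumor>`` and ``z_<tumor>`` per replicate, ``mean_z``,
    ``rank`` (1 = most depleted) and ``percentile`` = rank/N.
    """
    matrix.validate_against(library)
    if not tumor_samples:
        raise ValidationError("no tumor replicates given")
    table = pd.DataFrame(index=matrix.counts.index)
    table["gene"] = [e.gene for e in library.entries]
    table["class"] = [e.klass for e in library.entries]
    ref_norm = normalize_counts(matrix.counts[reference_sample])
    table[f"norm_{reference_sample}"] = ref_norm
    z_cols = []
    for sample in tumor_samples:
        norm = normalize_counts(matrix.counts[sample])
        lfc = log_fold_change(norm, ref_norm, config.pseudocount)
        z = robust_z(lfc, config.mad_constant)
        table[f"norm_{sample}"] = norm
        table[f"lfc_{sample}"] = lfc
        table[f"z_{sample}"] = z
        z_cols.append(z)
    table["mean_z"] = aggregate_replicates(z_cols)
    ranks, percentiles = to_ranks(table["mean_z"].to_numpy())
    table["rank"] = ranks
    table["percentile"] = percentiles
    return table


def score_all_screens(
    matrix: CountMatrix,
    library: ShrnaLibrary,
    sheet: SampleSheet,
    config: ScoringConfig = ScoringConfig(),
) -> dict[str, pd.DataFrame]:
    """Score every screen in a sample sheet. Returns screen_id -> table."""
    return {
        screen: score_screen(
            matrix,
            library,
            sheet.reference(screen).sample_id,
            [s.sample_id for s in sheet.tumors(screen)],
            config,
        )
        for screen in sheet.screens
    }
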