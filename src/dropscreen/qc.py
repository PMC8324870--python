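"""Screen quality control and in vivo study metrics.

Control separation: a dropout screen is interpretable only if hairpins
against core-essential positive-control genes (e.g. RPL30, PSMA1)
deplete clearly relative to non-targeting negative controls (LUC).
Separation is summarized by SSMD and by the rank-sum AUC — the
probability that a random negative-control score exceeds a random
positive-control score (1.0 = perfect separation, 0.5 = none).

Representation: the detected-barcode fraction and the Gini coefficient
of the count distribution flag bottlenecked or skewed samples.

Animal-study metrics: tumor volume (length x width^2)/2 from caliper
measurements and percent tumor growth inhibition, 100 x (1 -
MTV_treated / MTV_control) with final median tumor volumes (MTV);
positive %TGI = inhibition.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import ValidationError
from .library import CountMatrix, ShrnaLibrary


def control_separation(
    scores: Sequence[float],
    pos_mask: Sequence[bool],
    neg_mask: Sequence[bool],
) -> tuple[float, float]:
    """SSMD and rank-sum AUC between control classes.

    ``scores`` are per-hairpin mean z-scores; positives should sit
    below negatives in a working screen, making both metrics positive
    (> 0 SSMD) / above 0.5 (AUC). Zero variance in both classes makes
    SSMD undefined and raises.
    """
    s = np.asarray(scores, dtype=float)
    pos = s[np.asarray(pos_mask, dtype=bool)]
    neg = s[np.asarray(neg_mask, dtype=bool)]
    if pos.size < 2 or neg.size < 2:
        raise ValidationError("need >= 2 hairpins in each control class")
    var = pos.var(ddof=1) + neg.var(ddof=1)
    if var == 0:
        raise ValidationError("degenerate control variance: SSMD undefined")
    ssmd = (neg.mean() - pos.mean()) / np.sqrt(var)
    u = mannwhitneyu(neg, pos, alternative="two-sided").statistic
    auc = float(u) / (pos.size * neg.size)
    return float(ssmd), auc


def representation_stats(counts: Sequence[int]) -> tuple[float, float]:
    """(detected_fraction, gini) of one sample's count vector.

    Gini is 0 for perfectly uniform representation and approaches 1 as
    reads concentrate on few barcodes; an all-zero sample is defined
    as gini 0 with detected fraction 0.
    """
    x = np.asarray(counts, dtype=float)
    if x.size < 1:
        raise ValidationError("empty count vector")
    if (x < 0).any():
        raise ValidationError("negative counts")
    detected = float((x > 0).sum()) / x.size
    total = x.sum()
    if total == 0:
        return 0.0, 0.0
    xs = np.sort(x)
    n = x.size
    gini = (2.0 * np.sum(np.arange(1, n + 1) * xs) - (n + 1) * total) / (n * total)
    return detected, float(gini)


def tumor_volume(length: float, width: float) -> float:
    """Caliper tumor volume (length x width^2) / 2, in mm^3.

    Length is the longer axis by convention; swapped with a warning if
    the measurements are given the other way round.
    """
    if length <= 0 or width <= 0:
        raise ValidationError("tumor measurements must be positive")
    if width > length:
        warnings.warn("width > length: swapping axes", stacklevel=2)
        length, width = width, length
    return length * width**2 / 2.0


def percent_tgi(treated_volumes: Sequence[float], control_volumes: Sequence[float]) -> float:
    """Percent tumor growth inhibition from final group volumes.

    100 x (1 - median(treated) / median(control)); negative values
    indicate growth stimulation.
    """
    treated = np.asarray(treated_volumes, dtype=float)
    control = np.asarray(control_volumes, dtype=float)
    if treated.size == 0 or control.size == 0:
        raise ValidationError("both groups must be non-empty")
    mtv_control = np.median(control)
    if mtv_control <= 0:
        raise ValidationError("control median tumor volume must be > 0")
    return float(100.0 * (1.0 - np.median(treated) / mtv_control))


def qc_screen(
    score_table: pd.DataFrame,
    matrix: CountMatrix,
    library: ShrnaLibrary,
    samples: Sequence[str] | None = None,
) -> dict:
    """Assemble the per-screen QC report.

    Returns a JSON-ready dict with control-separation metrics on
    mean_z, the median LFC gap between control classes, and per-sample
    representation stats.
    """
    pos = (score_table["class"] == "positive_control").to_numpy()
    neg = (score_table["class"] == "negative_control").to_numpy()
    scores = score_table["mean_z"].to_numpy()
    ssmd, auc = control_separation(scores, pos, neg)
    lfc_cols = [c for c in score_table.columns if c.startswith("lfc_")]
    mean_lfc = score_table[lfc_cols].mean(axis=1).to_numpy()
    report: dict = {
        "ssmd_controls": ssmd,
        "auc_controls": auc,
        "median_lfc_positive_controls": float(np.median(mean_lfc[pos])),
        "median_lfc_negative_controls": float(np.median(mean_lfc[neg])),
        "samples": {},
    }
    for sample in samples or matrix.samples:
        detected, gini = representation_stats(matrix.counts[sample].to_numpy())
        report["samples"][sample] = {
            "detected_barcode_fraction": detected,
            "gini": gini,
            "assigned_reads": matrix.assigned_total(sample),
            "tallies": matrix.tallies[sample],
        }
    return report
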