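"""Hit calling and cross-screen intersection.

A gene is a hit in a screen when both thresholds hold (inclusive):
RSA logP <= -1.5 and FDR q <= 0.3. Genes hit in every screen of a
multi-model suite are the common (pan-model) dependencies; the
membership matrix supports Venn-style reporting of the per-screen and
shared hits.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

LOGP_THRESHOLD = -1.5
FDR_THRESHOLD = 0.3


def top_k_mean(z_values: Sequence[float], k: int = 3) -> float:
    """Mean of the k most-depleted (smallest) hairpin scores of a gene.

    With fewer than k hairpins, the mean of all of them. This is the
    alternative per-gene summary alongside the RSA statistic.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    z = np.sort(np.asarray(z_values, dtype=float))
    if z.size == 0:
        raise ValidationError("gene has no hairpins")
    return float(z[: min(k, z.size)].mean())


def call_hits(
    results: pd.DataFrame,
    logp_threshold: float = LOGP_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
    targeting_only: bool = True,
) -> set[str]:
    """Genes passing both thresholds in one screen's gene result table.

    Control genes are excluded by default: positive controls are
    essential by design and would otherwise join every hit set.
    """
    if not (np.isfinite(logp_threshold) and np.isfinite(fdr_threshold)):
        raise ValidationError("thresholds must be finite")
    mask = (results["rsa_logp"] <= logp_threshold) & (results["fdr_q"] <= fdr_threshold)
    if targeting_only and "class" in results.columns:
        mask &= results["class"] == "targeting"
    return set(results.index[mask])


def common_hits(
    hit_sets: Mapping[str, set[str]],
) -> tuple[set[str], pd.DataFrame, dict[str, int]]:
    """Intersection of per-screen hit sets plus Venn bookkeeping.

    Returns ``(common, membership, region_counts)`` where membership is
    a boolean gene x screen DataFrame over the union of hits and
    region_counts maps each non-empty screen combination (screen ids
    joined by ``&``) to the number of genes hit in exactly that
    combination — the counts a Venn diagram displays.
    """
    if len(hit_sets) < 2:
        raise ValidationError("need at least 2 screens to intersect")
    screens = list(hit_sets)
    union = sorted(set().union(*hit_sets.values()))
    membership = pd.DataFrame(
        {s: [g in hit_sets[s] for g in union] for s in screens}, index=union, dtype=bool
    )
    common = set.intersection(*(set(v) for v in hit_sets.values()))
    regions: dict[str, int] = {}
    for _gene, row in membership.iterrows():
        key = "&".join(s for s in screens if row[s])
        regions[key] = regions.get(key, 0) + 1
    return common, membership, regions
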