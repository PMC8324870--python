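"""Gene-level redundant shRNA activity (RSA) statistics.

For a gene with n hairpins at ascending depletion ranks
r_1 < ... < r_n among N library hairpins, RSA asks, for each i, how
surprising it is that at least i of the gene's hairpins fall within
the r_i most-depleted hairpins of the screen: p_i = P(X >= i) with
X ~ Hypergeometric(population N, n successes, r_i draws). The gene
statistic is log10 of the minimum p_i — small when several independent
hairpins deplete consistently, which is the redundancy a true
dependency should show. Computation is done in log space (log-gamma
based hypergeometric pmf + logsumexp) so that quantities at the scale
of 1/C(2370, 10) do not underflow.

Taking the minimum over order statistics makes rsa_p anti-conservative
as a p-value (its null distribution is stochastically smaller than
uniform), so Benjamini-Hochberg on rsa_p controls FDR only loosely; it
remains the default because the statistic is conventionally consumed
through fixed logP thresholds. A gene-label permutation FDR, which is
calibrated against the statistic's actual null, is provided as the
alternative (``fdr_method="permutation"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .hits import top_k_mean

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class GeneRankSet:
    """One gene's hairpin ranks within a screen of N hairpins."""

    gene: str
    N: int
    ranks: tuple[int, ...]

    def __post_init__(self):
        ranks = tuple(sorted(int(r) for r in self.ranks))
        object.__setattr__(self, "ranks", ranks)
        if not ranks:
            raise ValidationError(f"gene {self.gene!r}: no ranks")
        if len(set(ranks)) != len(ranks):
            raise ValidationError(f"gene {self.gene!r}: ranks must be distinct")
        if ranks[0] < 1 or ranks[-1] > self.N:
            raise ValidationError(f"gene {self.gene!r}: ranks outside 1..{self.N}")

    @property
    def n(self) -> int:
        return len(self.ranks)


def _log10_tail(i: int, N: int, n: int, r: int) -> float:
    """log10 P(X >= i) for X ~ Hypergeometric(N, n, r), exact in log space."""
    lo = max(0, n + r - N)
    if i <= lo:
        return 0.0
    hi = min(n, r)
    ks = np.arange(i, hi + 1)
    log_tail = logsumexp(hypergeom.logpmf(ks, N, n, r))
    return min(0.0, float(log_tail) / _LN10)


def rsa_logp(g: GeneRankSet) -> float:
    """RSA statistic: log10 of the minimum order-statistic tail probability.

    Always <= log10(p_1) <= 0; more negative = stronger, more
    redundant depletion.
    """
    return min(_log10_tail(i, g.N, g.n, r) for i, r in enumerate(g.ranks, start=1))


def rsa_logp_matrix(ranks: np.ndarray, N: int) -> np.ndarray:
    """Vectorized RSA for many genes sharing the same hairpin count.

    ``ranks`` is a (G, n) integer array of each gene's ranks (any
    order); returns the G per-gene logP values, identical to applying
    :func:`rsa_logp` row by row. All (i, k) tail terms are evaluated in
    one log-gamma pmf call; impossible terms contribute -inf masses.
    """
    ranks = np.sort(np.asarray(ranks, dtype=np.int64), axis=1)
    G, n = ranks.shape
    iu, ku = np.triu_indices(n)  # row-major: segments contiguous in i
    with np.errstate(divide="ignore"):
        logpmf = hypergeom.logpmf(ku + 1, N, n, ranks[:, iu])
    seg_starts = np.flatnonzero(np.r_[1, np.diff(iu)])
    tails = np.logaddexp.reduceat(logpmf, seg_starts, axis=1)
    logp = np.minimum(tails, 0.0).min(axis=1) / _LN10
    # draws >= N - n + i make the tail certain; reduceat rounding can
    # leave tiny negatives there, so clamp through min with 0 above
    return logp


def rsa_logp_oracle(g: GeneRankSet) -> float:
    """Exact-arithmetic reference for :func:`rsa_logp` (small N only).

    Sums hypergeometric masses with rational arithmetic; refuses
    N > 500 where the exact regime stops being cheap.
    """
    if g.N > 500:
        raise ValidationError("oracle restricted to N <= 500")
    best = Fraction(1)
    for i, r in enumerate(g.ranks, start=1):
        denom = math.comb(g.N, r)
        tail = sum(
            Fraction(math.comb(g.n, k) * math.comb(g.N - g.n, r - k), denom)
            for k in range(i, min(g.n, r) + 1)
        )
        best = min(best, tail)
    return math.log10(best)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving on input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("no p-values")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _grouped_ranks(score_table: pd.DataFrame) -> tuple[list[str], list[np.ndarray]]:
    genes: list[str] = []
    rank_sets: list[np.ndarray] = []
    for gene, grp in score_table.groupby("gene", sort=False):
        genes.append(str(gene))
        rank_sets.append(grp["rank"].to_numpy(dtype=np.int64))
    return genes, rank_sets


def _logp_for_rank_sets(rank_sets: list[np.ndarray], N: int) -> np.ndarray:
    """Batched RSA over possibly unequal gene sizes."""
    out = np.empty(len(rank_sets))
    sizes = np.array([len(r) for r in rank_sets])
    for n in np.unique(sizes):
        idx = np.flatnonzero(sizes == n)
        block = np.vstack([rank_sets[i] for i in idx])
        out[idx] = rsa_logp_matrix(block, N)
    return out


def permutation_fdr(
    pvalues: Sequence[float],
    score_table: pd.DataFrame,
    iterations: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Gene-label-shuffle FDR: q(p0) = E0[#p <= p0] / #observed p <= p0.

    Hairpin ranks are held fixed while gene labels are permuted over
    hairpins, regenerating the joint null of the RSA minima under no
    gene-level structure — calibrated for the anti-conservative
    statistic, unlike BH. Monotonized over the observed ordering and
    capped at 1.
    """
    p_obs = np.asarray(pvalues, dtype=float)
    rng = np.random.default_rng(seed)
    _genes, rank_sets = _grouped_ranks(score_table)
    sizes = [len(r) for r in rank_sets]
    all_ranks = score_table["rank"].to_numpy(dtype=np.int64)
    N = len(score_table)
    boundaries = np.cumsum(sizes)[:-1]
    null_blocks = []
    for _ in range(iterations):
        shuffled = rng.permutation(all_ranks)
        null_sets = np.split(shuffled, boundaries)
        null_blocks.append(_logp_for_rank_sets(list(null_sets), N))
    null = np.sort(10.0 ** np.concatenate(null_blocks))
    order = np.argsort(p_obs)
    q = np.empty_like(p_obs)
    for out_rank, idx in enumerate(order, start=1):
        expected_null = np.searchsorted(null, p_obs[idx], side="right") / iterations
        q[idx] = expected_null / out_rank
    q_sorted = np.minimum.accumulate(q[order][::-1])[::-1]
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def gene_results(
    score_table: pd.DataFrame,
    fdr_method: str = "bh",
    permutation_iters: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene result table from one screen's hairpin score table.

    Columns: gene (index), class, n_hairpins, best_rank, rsa_logp,
    rsa_p, fdr_q, top3_mean_z. RSA is computed in the depletion
    direction only (ascending mean_z), as appropriate for a dropout
    screen; FDR is taken across all genes within the screen.
    """
    N = len(score_table)
    genes, rank_sets = _grouped_ranks(score_table)
    logps = _logp_for_rank_sets(rank_sets, N)
    first = score_table.groupby("gene", sort=False).first()
    out = pd.DataFrame(
        {
            "class": first.loc[genes, "class"].to_numpy(),
            "n_hairpins": [len(r) for r in rank_sets],
            "best_rank": [int(r.min()) for r in rank_sets],
            "rsa_logp": logps,
            "rsa_p": 10.0**logps,
            "top3_mean_z": [
                top_k_mean(grp["mean_z"].to_numpy(), k=3)
                for _g, grp in score_table.groupby("gene", sort=False)
            ],
        },
        index=pd.Index(genes, name="gene"),
    )
    if fdr_method == "bh":
        out["fdr_q"] = bh_fdr(out["rsa_p"].to_numpy())
    elif fdr_method == "permutation":
        out["fdr_q"] = permutation_fdr(
            out["rsa_p"].to_numpy(), score_table, permutation_iters, seed
        )
    else:
        raise ValidationError(f"unknown fdr_method {fdr_method!r}")
    return out
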