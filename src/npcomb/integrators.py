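"""Comparison methods: parametric p-value combination, rank-based
meta-analysis (with and without the synchronized-permutation schema), and
the Benjamini-Heller partial-conjunction test.

These are the baselines the NPC framework is judged against.  The rank
baselines deliberately draw an *independent* permutation plan per modality,
which is what makes them miscalibrated when modalities are correlated; the
NPC-wrapped variants share one synchronized plan and stay calibrated.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    OmicsDataset,
    StatisticSpec,
    StudyDesign,
    ValidationError,
)
from .npc import PermutationPlan, build_permutation_plan, compute_statistics, pool_pvalues
from .stats import StatisticEngine

__all__ = [
    "cp_fisher",
    "rank_features",
    "rank_sum_stat",
    "rank_prod_stat",
    "rankprod_approx_pvalue",
    "npc_rank_combine",
    "baseline_rank_pvalues",
    "benjamini_partial_conjunction",
]


def cp_fisher(partial_p: np.ndarray) -> np.ndarray:
    """Classical Fisher combination of parametric per-modality p-values.

    ``partial_p`` is (n_modalities, n_features), or a 1-D per-modality
    vector for a single feature.  ``X = -2 sum log p_i`` is referred to
    chi-square with 2k degrees of freedom.  Valid only under independence
    of the partial p-values; anti-conservative under positive dependence.
    """
    p = np.asarray(partial_p, dtype=float)
    p = p[:, None] if p.ndim == 1 else p
    if np.any(p <= 0):
        raise ValidationError("parametric partial p-values must be > 0")
    if np.any(p > 1):
        raise ValidationError("p-values must be <= 1")
    k = p.shape[0]
    X = -2.0 * np.log(p).sum(axis=0)
    out = sps.chi2.sf(X, 2 * k)
    return out if np.ndim(partial_p) > 1 else float(out[0])


def rank_features(evidence: np.ndarray, smaller_is_better: bool = True) -> np.ndarray:
    """Within-modality feature ranks; rank 1 = strongest evidence.

    ``evidence`` is (n_modalities, n_features); by default smaller values
    (p-values) are better.  Ties receive midranks.  Ranking is invariant
    under strictly monotone transforms of the evidence.
    """
    ev = np.asarray(evidence, dtype=float)
    ev2 = np.atleast_2d(ev)
    ranks = sps.rankdata(ev2 if smaller_is_better else -ev2, axis=1)
    return ranks if ev.ndim > 1 else ranks[0]


def rank_sum_stat(ranks: np.ndarray) -> np.ndarray:
    """Sum of per-modality ranks; smaller = stronger global evidence."""
    return np.atleast_2d(np.asarray(ranks, dtype=float)).sum(axis=0)


def rank_prod_stat(ranks: np.ndarray) -> np.ndarray:
    """Product of per-modality ranks; smaller = stronger global evidence."""
    return np.atleast_2d(np.asarray(ranks, dtype=float)).prod(axis=0)


def rankprod_approx_pvalue(
    rho: Union[float, np.ndarray], k: int, n: int
) -> Union[float, np.ndarray]:
    """Gamma-tail approximation to the null distribution of a rank product.

    Treats the k ranks as iid Uniform(0, n): with ``q = rho / n^k``,
    ``P(prod U_i <= q) = q * sum_{j=0}^{k-1} (-log q)^j / j!`` — the
    continuous approximation to the discrete rank-product null.
    """
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr < 1) or np.any(rho_arr > float(n) ** k):
        raise ValidationError(f"rank product must lie in [1, n^k] = [1, {n**k}]")
    q = rho_arr / float(n) ** k
    logq = np.log(q)
    p = np.zeros_like(q)
    for j in range(k):
        p += (-logq) ** j / math.factorial(j)
    p = np.minimum(q * p, 1.0)
    return p if np.ndim(rho) else float(p)


def _rank_stat_matrix(
    stat_matrices: Sequence[np.ndarray], statistic: str
) -> np.ndarray:
    """(B+1) x features matrix of combined rank statistics.

    Per permutation row, features are ranked within each modality by
    oriented evidence (rank 1 = strongest), then summed or multiplied
    across modalities.
    """
    if statistic not in ("sum", "product"):
        raise ValidationError(f"statistic must be 'sum' or 'product', got {statistic!r}")
    combined = None
    for S in stat_matrices:
        ranks = sps.rankdata(-np.asarray(S, dtype=float), axis=1)
        if combined is None:
            combined = ranks.copy()
        elif statistic == "sum":
            combined += ranks
        else:
            combined *= ranks
    return combined


def npc_rank_combine(
    plan: PermutationPlan,
    datasets: Sequence[OmicsDataset],
    design: StudyDesign,
    specs: Optional[dict[str, StatisticSpec]] = None,
    statistic: str = "sum",
    zero_correction: bool = True,
    stat_matrices: Optional[Sequence[np.ndarray]] = None,
) -> np.ndarray:
    """Rank-combination statistics under the synchronized NPC permutation schema.

    For every permutation row the per-modality statistics are recomputed,
    ranked within modality, and combined by sum or product; the global
    p-value per feature comes from the usual pooling rule applied to the
    negated rank statistics (smaller rank statistic = stronger evidence).
    """
    if stat_matrices is None:
        stat_matrices = [
            compute_statistics(ds, plan, (specs or {}).get(ds.modality_id), design)
            for ds in datasets
        ]
    R = _rank_stat_matrix(stat_matrices, statistic)
    return pool_pvalues(-R, zero_correction)[0]


def baseline_rank_pvalues(
    datasets: Sequence[OmicsDataset],
    design: StudyDesign,
    specs: Optional[dict[str, StatisticSpec]] = None,
    B: int = 1000,
    seed: Optional[int] = None,
    statistic: str = "sum",
    zero_correction: bool = True,
) -> np.ndarray:
    """Correlation-naive rank baseline: independent permutations per modality.

    Identical pipeline to :func:`npc_rank_combine` except each modality
    draws its own permutation plan, deliberately breaking cross-dataset
    dependence — the classical meta-analysis assumption of independent
    studies, and the reason these baselines miscalibrate on correlated
    modalities.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(datasets))
    stat_matrices = []
    for ds, child in zip(datasets, child_seeds):
        plan = build_permutation_plan(
            design, B, seed=int(child.generate_state(1)[0] % (2**31)), exhaustive=False
        )
        stat_matrices.append(
            compute_statistics(ds, plan, (specs or {}).get(ds.modality_id), design)
        )
    R = _rank_stat_matrix(stat_matrices, statistic)
    return pool_pvalues(-R, zero_correction)[0]


def benjamini_partial_conjunction(
    partial_p: np.ndarray, u: int = 1
) -> Union[float, np.ndarray]:
    """Benjamini-Heller test that at least u of n partial nulls are false.

    With the partial p-values sorted ascending, the global p-value is
    ``min over j of ((n - u + 1) / j) * p_(u - 1 + j)`` for
    ``j = 1..n-u+1``, clamped to 1.  At ``u = 1`` this reduces to the
    minimum Benjamini-Hochberg-adjusted p-value; at ``u = n`` it is the
    largest partial p-value.  Accepts a 1-D vector (one feature) or an
    (n_modalities, n_features) array.
    """
    p = np.asarray(partial_p, dtype=float)
    one_dim = p.ndim == 1
    p2 = p[:, None] if one_dim else p
    n = p2.shape[0]
    if not 1 <= u <= n:
        raise ValidationError(f"u must be in [1, {n}], got {u}")
    srt = np.sort(p2, axis=0)
    j = np.arange(1, n - u + 2)
    candidates = ((n - u + 1) / j)[:, None] * srt[u - 2 + j, :]
    out = np.minimum(candidates.min(axis=0), 1.0)
    return float(out[0]) if one_dim else out


def min_bh_pvalue(p: np.ndarray) -> float:
    """Minimum Benjamini-Hochberg-adjusted value of a p-vector (helper)."""
    return float(multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1].min())
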