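"""The non-parametric combination (NPC) engine.

A single global null — "no modality is associated with the outcome" — is
broken into one partial null per modality.  The same permutation of the
outcome is applied across all modalities (synchronized permutation), which
preserves between-dataset dependence; per-modality statistics are pooled
into partial (pseudo-)p-values, combined per permutation with a convex
combining function (Fisher, Liptak or Tippett), and the combined statistics
are pooled again into a global p-value.

Both pooling steps count self-inclusively over all B+1 statistics with the
+1/+1 zero-avoidance correction, so no p-value can fall below 1/(B+1); a
zero permutation p-value would otherwise inflate the type-I error under
multiple testing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    CombinerSpec,
    FeatureMapping,
    NPCResult,
    OmicsDataset,
    StatisticSpec,
    StudyDesign,
    ValidationError,
)
from .mapping import apply_mapping
from .stats import StatisticEngine

__all__ = [
    "PermutationPlan",
    "build_permutation_plan",
    "enumerate_label_assignments",
    "compute_statistics",
    "pool_pvalues",
    "combine",
    "global_pvalue",
    "run_npc",
]


@dataclass
class PermutationPlan:
    """B synchronized permutations of the outcome over the sample universe.

    ``labels`` has shape ``(B+1, n_universe)``; row 0 is the observed
    outcome, rows 1..B are permutations of it.  Every dataset reads the
    permuted label of exactly its own samples, so samples shared between
    datasets receive identical relabelings in every permutation.
    """

    labels: np.ndarray
    seed: Optional[int]
    exhaustive: bool = False

    @property
    def B(self) -> int:
        return self.labels.shape[0] - 1

    @property
    def n_samples(self) -> int:
        return self.labels.shape[1]


def _multiset_permutations(items: list):
    """Yield all distinct permutations of a multiset (lexicographic)."""
    items = sorted(items)
    n = len(items)
    yield tuple(items)
    a = list(items)
    while True:
        # next_permutation
        i = n - 2
        while i >= 0 and not a[i] < a[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while not a[i] < a[j]:
            j -= 1
        a[i], a[j] = a[j], a[i]
        a[i + 1 :] = reversed(a[i + 1 :])
        yield tuple(a)


def _n_distinct_assignments(outcome: np.ndarray) -> float:
    _, counts = np.unique(outcome, return_counts=True)
    total = math.factorial(len(outcome))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def enumerate_label_assignments(outcome: np.ndarray) -> np.ndarray:
    """All distinct label assignments, observed one first."""
    obs = tuple(outcome)
    rows = [obs] + [p for p in _multiset_permutations(list(outcome)) if p != obs]
    return np.array(rows, dtype=np.asarray(outcome).dtype)


def build_permutation_plan(
    design: StudyDesign,
    B: int,
    seed: Optional[int] = None,
    exhaustive: Union[bool, str] = "auto",
) -> PermutationPlan:
    """Draw B uniform random permutations of the outcome over the universe.

    With ``exhaustive='auto'`` (default) the full set of distinct label
    assignments is enumerated instead whenever there are at most ``B+1`` of
    them, making the permutation p-values exact.  Monte-Carlo draws sample
    the permutation group uniformly (duplicates permitted); a warning is
    issued when B exceeds the number of distinct assignments.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    outcome = design.outcome.to_numpy()
    n_distinct = _n_distinct_assignments(outcome)
    if exhaustive is True or (exhaustive == "auto" and n_distinct <= B + 1):
        labels = enumerate_label_assignments(outcome)
        return PermutationPlan(labels=labels, seed=seed, exhaustive=True)
    if B >= n_distinct:
        warnings.warn(
            f"B={B} exceeds the {n_distinct} distinct label assignments; "
            "sampling with replacement"
        )
    rng = np.random.default_rng(seed)
    labels = np.empty((B + 1, len(outcome)), dtype=outcome.dtype)
    labels[0] = outcome
    for b in range(1, B + 1):
        labels[b] = outcome[rng.permutation(len(outcome))]
    return PermutationPlan(labels=labels, seed=seed, exhaustive=False)


def compute_statistics(
    dataset: Union[OmicsDataset, StatisticEngine],
    plan: PermutationPlan,
    spec: Optional[StatisticSpec] = None,
    design: Optional[StudyDesign] = None,
) -> np.ndarray:
    """Statistic matrix: row b holds the oriented statistics under row-b labels.

    Only the outcome is permuted; covariates stay attached to their samples.
    Accepts a prebuilt :class:`~npcomb.stats.StatisticEngine` or builds one
    from ``(dataset, design, spec)``.
    """
    engine = (
        dataset
        if isinstance(dataset, StatisticEngine)
        else StatisticEngine(dataset, design, spec)
    )
    rows = [engine.statistic(plan.labels[b]).values for b in range(plan.B + 1)]
    return np.vstack(rows)


_TIE_RTOL = 1e-9
_TIE_ATOL = 1e-12


def _tie_groups(S_sorted: np.ndarray) -> np.ndarray:
    """Per column: index of the first member of each value's tie group.

    Two adjacent sorted values belong to one group when their gap is within
    floating-point noise (relative 1e-9, absolute 1e-12) — statistics that
    are mathematically equal but computed along different arithmetic paths
    (e.g. mirrored label assignments) must count as ties.
    """
    R = S_sorted.shape[0]
    gaps = S_sorted[1:] - S_sorted[:-1]
    tol = _TIE_RTOL * np.maximum(np.abs(S_sorted[1:]), np.abs(S_sorted[:-1])) + _TIE_ATOL
    is_start = np.vstack([np.ones((1, S_sorted.shape[1]), bool), gaps > tol])
    idx = np.arange(R)[:, None]
    return np.maximum.accumulate(np.where(is_start, idx, 0), axis=0)


def pool_pvalues(stats: np.ndarray, zero_correction: bool = True) -> np.ndarray:
    """Partial (pseudo-)p-values from a (B+1) x features statistic matrix.

    With the zero-avoidance correction on, every statistic (observed row 0
    included) is compared self-inclusively against the pooled B+1 values:
    ``lambda_b = #{b' in 0..B : T_b' >= T_b} / (B+1)``, which for b=0 is the
    +1/+1-corrected permutation p-value and is bounded below by 1/(B+1).
    With the correction off, each statistic is compared against the B
    permutation rows only: ``lambda_b = #{b' in 1..B : T_b' >= T_b} / B``,
    so the observed p-value can reach zero.  Ties count as exceedances
    (conservative), with a floating-point noise tolerance.
    """
    S = np.asarray(stats, dtype=float)
    R = S.shape[0]
    order = np.argsort(S, axis=0, kind="stable")
    S_sorted = np.take_along_axis(S, order, axis=0)
    first = _tie_groups(S_sorted)  # first index of each tie group, sorted scale
    if zero_correction:
        count_sorted = R - first  # members >= value, ties included
        lam = np.empty_like(S)
        np.put_along_axis(lam, order, count_sorted / R, axis=0)
        return lam
    # uncorrected: count permutation rows (1..B) only
    B = R - 1
    perm_sorted = np.take_along_axis(
        (np.arange(R) > 0).astype(float)[:, None] * np.ones_like(S), order, axis=0
    )
    suffix = np.cumsum(perm_sorted[::-1], axis=0)[::-1]  # perm members at >= position
    count_sorted = np.take_along_axis(suffix, first, axis=0)
    lam = np.empty_like(S)
    np.put_along_axis(lam, order, count_sorted / B, axis=0)
    return lam


def combine(
    cube: np.ndarray, combiner: Union[str, CombinerSpec], allow_zero: bool = False
) -> np.ndarray:
    """Combine partial p-values across modalities into global statistics.

    ``cube`` has shape ``(n_modalities, B+1, n_features)``.  Fisher:
    ``-2 * sum_i w_i log(lambda_i)``; Liptak: ``sum_i w_i PhiInv(1 - lambda_i)``;
    Tippett: ``max_i w_i (1 - lambda_i)``.  Unweighted means ``w_i = 1``.
    NaN entries (feature absent from a modality) are skipped.  Liptak z
    values are clamped symmetrically at the 1/(2(B+1)) quantile so a
    partial p of exactly 1 stays finite.
    """
    spec = combiner if isinstance(combiner, CombinerSpec) else CombinerSpec(combiner)
    lam = np.asarray(cube, dtype=float)
    n_mod = lam.shape[0]
    if spec.weights is not None:
        if len(spec.weights) != n_mod:
            raise ValidationError(
                f"{len(spec.weights)} weights for {n_mod} modalities"
            )
        w = spec.weights[:, None, None]
    else:
        w = np.ones((n_mod, 1, 1))
    if spec.name in ("fisher", "liptak") and not allow_zero and np.nanmin(lam) <= 0:
        raise ValidationError(
            "partial p-value of 0 cannot be log/probit-combined; "
            "enable the zero correction"
        )
    if spec.name == "fisher":
        with np.errstate(divide="ignore"):
            return np.nansum(w * (-2.0 * np.log(lam)), axis=0)
    if spec.name == "liptak":
        B_plus_1 = lam.shape[1]
        bound = sps.norm.ppf(1.0 - 1.0 / (2.0 * B_plus_1))
        z = np.clip(sps.norm.ppf(1.0 - lam), -bound, bound)
        return np.nansum(w * z, axis=0)
    # tippett
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmax(w * (1.0 - lam), axis=0)


def global_pvalue(
    global_stats: np.ndarray, zero_correction: bool = True
) -> np.ndarray:
    """Global p-values: the pooling rule applied to the combined statistics."""
    return pool_pvalues(global_stats, zero_correction)[0]


def _bh(p: np.ndarray) -> np.ndarray:
    mask = np.isfinite(p)
    out = np.full_like(p, np.nan, dtype=float)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def run_npc(
    datasets: Sequence[OmicsDataset],
    design: StudyDesign,
    mapping: Optional[FeatureMapping] = None,
    specs: Optional[dict[str, StatisticSpec]] = None,
    combiners: Sequence[Union[str, CombinerSpec]] = ("fisher", "liptak", "tippett"),
    B: int = 1000,
    seed: Optional[int] = None,
    zero_correction: bool = True,
    keep_unmapped: bool = False,
    plan: Optional[PermutationPlan] = None,
    exhaustive: Union[bool, str] = "auto",
) -> NPCResult:
    """Run the full NPC pipeline and return per-group partial/global p-values.

    Orchestrates: feature mapping -> synchronized permutation plan ->
    per-modality statistic matrices -> pooled partial p-values ->
    combination -> global p-values -> Benjamini-Hochberg FDR columns.
    Deterministic given (inputs, B, seed).
    """
    if mapping is not None:
        datasets = apply_mapping(datasets, mapping, keep_unmapped=keep_unmapped)
    design.check_universe(datasets)
    combiners = [c if isinstance(c, CombinerSpec) else CombinerSpec(c) for c in combiners]

    # group universe: first dataset's order, then extras in sorted order
    group_ids: list[str] = []
    seen: set[str] = set()
    for ds in datasets:
        new = [g for g in ds.feature_ids if g not in seen]
        group_ids.extend(new if ds is datasets[0] else sorted(new))
        seen.update(new)
    n_groups = len(group_ids)
    g_index = {g: i for i, g in enumerate(group_ids)}

    if plan is None:
        plan = build_permutation_plan(design, B, seed, exhaustive=exhaustive)
    n_rows = plan.B + 1

    cube = np.full((len(datasets), n_rows, n_groups), np.nan)
    for i, ds in enumerate(datasets):
        spec = (specs or {}).get(ds.modality_id)
        stat_matrix = compute_statistics(ds, plan, spec, design)
        lam = pool_pvalues(stat_matrix, zero_correction)
        cols = np.array([g_index[g] for g in ds.feature_ids])
        cube[i, :, cols] = lam.T

    table = pd.DataFrame(index=pd.Index(group_ids, name="group_id"))
    for i, ds in enumerate(datasets):
        table[f"pvalue_partial_{ds.modality_id}"] = cube[i, 0, :]
    for comb in combiners:
        present = ~np.all(np.isnan(cube[:, 0, :]), axis=0)
        stats_g = combine(cube, comb, allow_zero=not zero_correction)
        pg = np.full(n_groups, np.nan)
        pg[present] = pool_pvalues(stats_g[:, present], zero_correction)[0]
        table[f"pvalue_global_{comb.label}"] = pg
    for ds in datasets:
        table[f"fdr_partial_{ds.modality_id}"] = _bh(
            table[f"pvalue_partial_{ds.modality_id}"].to_numpy()
        )
    for comb in combiners:
        table[f"fdr_global_{comb.label}"] = _bh(
            table[f"pvalue_global_{comb.label}"].to_numpy()
        )

    return NPCResult(
        table=table,
        B=plan.B,
        seed=seed,
        zero_correction=zero_correction,
        modality_ids=[ds.modality_id for ds in datasets],
        combiners=[c.label for c in combiners],
    )
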