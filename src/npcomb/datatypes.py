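"""Core domain types for multi-omics integration.

The central objects are :class:`OmicsDataset` (one modality's feature-by-sample
matrix), :class:`StudyDesign` (the sample universe with outcome and covariates),
and :class:`NPCResult` (per-feature partial and global p-values).  Matrices are
features x samples, the omics convention; all indexing is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModalityKind",
    "OutcomeType",
    "OmicsDataset",
    "StudyDesign",
    "FeatureMapping",
    "CombinerSpec",
    "StatisticSpec",
    "NPCResult",
    "ValidationError",
    "FormatError",
]


class ValidationError(ValueError):
    """Raised when data violate a domain invariant."""


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as the expected format."""


class ModalityKind(str, Enum):
    COUNTS = "counts"
    CONTINUOUS = "continuous"
    GENOTYPE = "genotype"
    UNIFORM_LIKE = "uniform_like"


class OutcomeType(str, Enum):
    DICHOTOMOUS = "dichotomous"
    MULTICLASS = "multiclass"
    CONTINUOUS = "continuous"


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise FormatError(f"duplicate {what}: {dupes[:5]}")
    return ids


@dataclass
class OmicsDataset:
    """One omics modality: a numeric features x samples matrix.

    Parameters
    ----------
    modality_id:
        Short label, e.g. ``"rnaseq"``.
    feature_ids, sample_ids:
        Ordered, unique identifiers matching the matrix axes.
    values:
        Numeric matrix of shape ``(len(feature_ids), len(sample_ids))``
        with no missing values.
    kind:
        Data kind; drives validation and the default association statistic.
    """

    modality_id: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    kind: ModalityKind

    def __post_init__(self) -> None:
        self.kind = ModalityKind(self.kind)
        self.feature_ids = _check_unique(self.feature_ids, "feature ids")
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("matrix contains missing or non-finite values")
        if self.kind is ModalityKind.COUNTS:
            if np.any(self.values < 0):
                raise ValidationError("counts must be non-negative")
            if not np.all(self.values == np.round(self.values)):
                raise ValidationError("counts must be integers")
        if self.kind is ModalityKind.GENOTYPE:
            if not np.all(np.isin(self.values, (0.0, 1.0, 2.0))):
                raise ValidationError("genotype values must be in {0, 1, 2}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class StudyDesign:
    """Sample universe with the outcome of interest and optional covariates.

    ``sample_ids`` define the universe over which permutations are drawn;
    every dataset's samples must be a subset of it.
    """

    sample_ids: list[str]
    outcome: pd.Series
    outcome_type: OutcomeType
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "design sample ids")
        self.outcome_type = OutcomeType(self.outcome_type)
        self.outcome = pd.Series(self.outcome)
        self.outcome.index = pd.Index(self.sample_ids)
        n_levels = self.outcome.nunique()
        if n_levels < 2:
            raise ValidationError("degenerate outcome: a single observed level")
        if self.outcome_type is OutcomeType.DICHOTOMOUS and n_levels != 2:
            raise ValidationError(
                f"dichotomous outcome must have exactly 2 levels, found {n_levels}"
            )
        if self.outcome_type is OutcomeType.MULTICLASS and n_levels < 3:
            raise ValidationError("multi-class outcome needs >= 3 levels")
        if self.covariates is not None:
            self.covariates = pd.DataFrame(self.covariates)
            self.covariates.index = pd.Index(self.sample_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def check_universe(self, datasets: Sequence[OmicsDataset]) -> None:
        """Assert every dataset's samples lie within the design universe."""
        universe = set(self.sample_ids)
        for ds in datasets:
            missing = [s for s in ds.sample_ids if s not in universe]
            if missing:
                raise ValidationError(
                    f"dataset {ds.modality_id!r} has samples outside the design "
                    f"universe: {missing[:5]}"
                )


@dataclass
class FeatureMapping:
    """Cross-modality feature grouping.

    ``records`` is a DataFrame with columns ``group_id``, ``modality_id``,
    ``feature_id``; each (modality, feature) pair may appear in at most one
    group.  ``strategy`` controls how a group with several features in one
    modality is resolved: ``aggregate`` collapses them with ``aggregate_fn``
    over raw values, ``expand`` forms one output group per cross-modality
    feature tuple, ``one_to_one`` requires at most one feature per modality.
    """

    records: pd.DataFrame
    strategy: str = "one_to_one"
    aggregate_fn: str = "mean"

    def __post_init__(self) -> None:
        need = {"group_id", "modality_id", "feature_id"}
        if not need.issubset(self.records.columns):
            raise FormatError(f"mapping table needs columns {sorted(need)}")
        if self.strategy not in ("one_to_one", "expand", "aggregate"):
            raise ValidationError(f"unknown mapping strategy {self.strategy!r}")
        if self.aggregate_fn not in ("mean", "median"):
            raise ValidationError(f"unknown aggregate_fn {self.aggregate_fn!r}")
        dup = self.records.duplicated(subset=["modality_id", "feature_id"])
        if dup.any():
            bad = self.records.loc[dup, ["modality_id", "feature_id"]].iloc[0]
            raise ValidationError(
                f"feature {bad.feature_id!r} of modality {bad.modality_id!r} "
                "mapped to more than one group"
            )


@dataclass
class CombinerSpec:
    """A combining function (fisher / liptak / tippett) with optional weights.

    Weights are per-modality, positive, and normalized to sum to 1 on input.
    """

    name: str
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.name not in ("fisher", "liptak", "tippett"):
            raise ValidationError(f"unknown combining function {self.name!r}")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if np.any(w < 0) or w.sum() <= 0:
                raise ValidationError("combiner weights must be non-negative with positive sum")
            self.weights = w / w.sum()

    @property
    def label(self) -> str:
        return self.name


@dataclass
class StatisticSpec:
    """Choice of per-modality association statistic.

    ``method`` is one of ``linear_model_t``, ``linear_model_F``,
    ``voom_linear_model_t``, ``genotype_trend``, ``ranksum``.  ``moderation``
    turns empirical-Bayes variance shrinkage on (linear-model methods only).
    ``sidedness`` orients the statistic: ``two_sided`` uses magnitudes, the
    one-sided options keep the sign.
    """

    method: str = "linear_model_t"
    moderation: bool = True
    sidedness: str = "two_sided"
    moderation_per_perm: bool = False
    weights_per_perm: bool = False

    _METHODS = (
        "linear_model_t",
        "linear_model_F",
        "voom_linear_model_t",
        "genotype_trend",
        "ranksum",
    )

    def __post_init__(self) -> None:
        if self.method not in self._METHODS:
            raise ValidationError(f"unknown statistic method {self.method!r}")
        if self.sidedness not in ("two_sided", "one_sided_greater", "one_sided_less"):
            raise ValidationError(f"unknown sidedness {self.sidedness!r}")

    @staticmethod
    def default_for(kind: ModalityKind, outcome_type: OutcomeType) -> "StatisticSpec":
        """Modality-appropriate default statistic."""
        kind = ModalityKind(kind)
        if kind is ModalityKind.COUNTS:
            method = "voom_linear_model_t"
        elif kind is ModalityKind.GENOTYPE:
            method = "genotype_trend"
        elif kind is ModalityKind.UNIFORM_LIKE:
            method = "ranksum"
        else:
            method = "linear_model_t"
        if OutcomeType(outcome_type) is OutcomeType.MULTICLASS and method in (
            "linear_model_t",
            "voom_linear_model_t",
        ):
            method = "linear_model_F"
        sided = "one_sided_greater" if method == "ranksum" else "two_sided"
        return StatisticSpec(method=method, moderation=True, sidedness=sided)


@dataclass
class NPCResult:
    """Output of an NPC run: one row per feature group.

    ``table`` columns follow the pattern ``pvalue_partial_<modality>``,
    ``pvalue_global_<combiner>``, ``fdr_partial_<modality>``,
    ``fdr_global_<combiner>``.  All p-values are bounded below by
    ``1/(B+1)`` when the zero-avoidance correction is on.
    """

    table: pd.DataFrame
    B: int
    seed: Optional[int]
    zero_correction: bool = True
    modality_ids: list[str] = field(default_factory=list)
    combiners: list[str] = field(default_factory=list)

    @property
    def group_ids(self) -> list[str]:
        return list(self.table.index)

    def global_pvalues(self, combiner: str) -> pd.Series:
        return self.table[f"pvalue_global_{combiner}"]

    def partial_pvalues(self, modality: str) -> pd.Series:
        return self.table[f"pvalue_partial_{modality}"]
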