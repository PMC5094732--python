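"""Readers and writers for the TSV interchange formats.

All tables are UTF-8 tab-separated text with dot decimals.  Matrices carry
feature ids in the first column and sample ids in the header row.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datatypes import (
    FeatureMapping,
    FormatError,
    ModalityKind,
    NPCResult,
    OmicsDataset,
    OutcomeType,
    StudyDesign,
    ValidationError,
)

logger = logging.getLogger("npcomb")

PathLike = Union[str, Path]


def read_matrix(
    path: PathLike, kind: Union[str, ModalityKind], modality_id: Optional[str] = None
) -> OmicsDataset:
    """Read a feature-by-sample TSV matrix into an :class:`OmicsDataset`.

    Non-numeric cells are reported with their row/column coordinates;
    duplicate feature or sample ids are format errors.  ``kind='counts'``
    additionally requires non-negative integer values.
    """
    path = Path(path)
    kind = ModalityKind(kind)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.columns.duplicated().any() or df.index.duplicated().any():
        raise FormatError(f"{path.name}: duplicate feature or sample ids")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy()
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = df.index[int(np.argmax(bad.isna().to_numpy()))]
            raise FormatError(
                f"{path.name}: non-numeric value at feature {row!r}, sample {col!r}"
            ) from None
    return OmicsDataset(
        modality_id=modality_id or path.stem,
        feature_ids=list(df.index),
        sample_ids=list(df.columns),
        values=values,
        kind=kind,
    )


def write_matrix(dataset: OmicsDataset, path: PathLike) -> None:
    dataset.to_frame().to_csv(path, sep="\t", float_format="%.12g")


def infer_outcome_type(values: pd.Series) -> OutcomeType:
    """Auto-detect the outcome type from its observed values.

    Two levels -> dichotomous.  Otherwise numeric with many distinct values
    is treated as continuous; few-level data as multi-class.
    """
    n_levels = values.nunique()
    if n_levels < 2:
        raise ValidationError("degenerate outcome: a single observed level")
    if n_levels == 2:
        return OutcomeType.DICHOTOMOUS
    numeric = pd.to_numeric(values, errors="coerce")
    if numeric.notna().all() and n_levels > max(5, len(values) // 4):
        return OutcomeType.CONTINUOUS
    return OutcomeType.MULTICLASS


def read_design(
    path: PathLike,
    outcome_col: str,
    covariate_cols: Sequence[str] = (),
    sample_col: Optional[str] = None,
    outcome_type: Optional[Union[str, OutcomeType]] = None,
) -> StudyDesign:
    """Read a study-design TSV (one row per sample).

    ``sample_col`` defaults to the first column.  The outcome type is
    auto-detected unless ``outcome_type`` overrides it.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if sample_col is None:
        sample_col = df.columns[0]
    for col in [sample_col, outcome_col, *covariate_cols]:
        if col not in df.columns:
            raise FormatError(f"{path.name}: column {col!r} not in header")
    rows = df.drop_duplicates()
    if rows[sample_col].duplicated().any():
        raise ValidationError(
            f"{path.name}: the same sample id appears with conflicting rows"
        )
    outcome = rows[outcome_col]
    numeric = pd.to_numeric(outcome, errors="coerce")
    if numeric.notna().all():
        outcome = numeric
    otype = OutcomeType(outcome_type) if outcome_type else infer_outcome_type(outcome)
    covariates = None
    if covariate_cols:
        covariates = rows[list(covariate_cols)].copy()
        for c in covariate_cols:
            num = pd.to_numeric(covariates[c], errors="coerce")
            if num.notna().all():
                covariates[c] = num
    return StudyDesign(
        sample_ids=list(rows[sample_col]),
        outcome=outcome.reset_index(drop=True),
        outcome_type=otype,
        covariates=covariates.reset_index(drop=True) if covariates is not None else None,
    )


def read_mapping(
    path: PathLike, strategy: str = "one_to_one", aggregate_fn: str = "mean"
) -> FeatureMapping:
    """Read a (group_id, modality_id, feature_id) mapping table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return FeatureMapping(records=df, strategy=strategy, aggregate_fn=aggregate_fn)


def write_result(result: NPCResult, path: PathLike) -> None:
    """Write an :class:`NPCResult` table; values keep 12 significant digits."""
    result.table.to_csv(path, sep="\t", index_label="group_id", float_format="%.12g")


def read_result_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="group_id")


def read_config(path: PathLike) -> dict:
    """Parse a simple ``key=value`` configuration file; '#' starts a comment."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"config line {lineno}: expected key=value")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out
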