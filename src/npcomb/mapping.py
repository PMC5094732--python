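"""Re-indexing modality features onto shared cross-modality groups.

Different omics technologies measure different feature sets (probes, CpG
sites, transcripts).  Before combination each modality is re-indexed onto a
common set of group ids (typically genes), either by aggregating multiple
features into one summary row or by expanding each cross-modality feature
tuple into its own group.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from typing import Sequence

import numpy as np

from .datatypes import FeatureMapping, ModalityKind, OmicsDataset, ValidationError

logger = logging.getLogger("npcomb")

__all__ = ["apply_mapping", "identity_mapping"]


def identity_mapping(datasets: Sequence[OmicsDataset]) -> FeatureMapping:
    """Map each feature to the group named after itself (shared feature ids)."""
    import pandas as pd

    rows = [
        (fid, ds.modality_id, fid) for ds in datasets for fid in ds.feature_ids
    ]
    return FeatureMapping(
        records=pd.DataFrame(rows, columns=["group_id", "modality_id", "feature_id"]),
        strategy="one_to_one",
    )


def _aggregate(rows: np.ndarray, fn: str) -> np.ndarray:
    return np.mean(rows, axis=0) if fn == "mean" else np.median(rows, axis=0)


def apply_mapping(
    datasets: Sequence[OmicsDataset],
    mapping: FeatureMapping,
    keep_unmapped: bool = False,
) -> list[OmicsDataset]:
    """Re-index each dataset's features by group id.

    Unmapped features are dropped (with a logged count) unless
    ``keep_unmapped`` promotes each to its own singleton group.  Group order
    in the output is deterministic (sorted by group id).  Groups with no
    feature in any modality are dropped with a warning.

    With ``strategy='aggregate'`` each group contributes one row per
    modality: the ``aggregate_fn`` over its mapped features' raw values.
    With ``strategy='expand'`` one output group is formed per cross-modality
    feature tuple, duplicating rows as needed.
    """
    rec = mapping.records
    per_modality = {ds.modality_id: ds for ds in datasets}
    # group -> modality -> list of feature ids, in record order
    groups: dict[str, dict[str, list[str]]] = {}
    mapped_features: dict[str, set] = {m: set() for m in per_modality}
    for gid, mod, fid in rec[["group_id", "modality_id", "feature_id"]].itertuples(
        index=False
    ):
        if mod not in per_modality:
            continue
        groups.setdefault(str(gid), {}).setdefault(str(mod), []).append(str(fid))
        mapped_features[str(mod)].add(str(fid))

    for ds in datasets:
        n_unmapped = sum(1 for f in ds.feature_ids if f not in mapped_features[ds.modality_id])
        if n_unmapped:
            if keep_unmapped:
                for f in ds.feature_ids:
                    if f not in mapped_features[ds.modality_id]:
                        groups.setdefault(f"unmapped:{ds.modality_id}:{f}", {})[
                            ds.modality_id
                        ] = [f]
                logger.info(
                    "%s: %d unmapped features kept as singleton groups",
                    ds.modality_id,
                    n_unmapped,
                )
            else:
                logger.info(
                    "%s: dropping %d unmapped features", ds.modality_id, n_unmapped
                )

    empty = [
        g
        for g, mods in groups.items()
        if not any(
            f in set(per_modality[m].feature_ids)
            for m, fids in mods.items()
            for f in fids
        )
    ]
    if empty:
        warnings.warn(f"{len(empty)} groups have no mapped feature in any modality")
        for g in empty:
            del groups[g]

    if mapping.strategy == "one_to_one":
        for g, mods in groups.items():
            for m, fids in mods.items():
                if len(fids) > 1:
                    raise ValidationError(
                        f"group {g!r} maps {len(fids)} features of modality {m!r} "
                        "under strategy=one_to_one"
                    )

    out: list[OmicsDataset] = []
    ordered = sorted(groups)
    for ds in datasets:
        row_of = {f: i for i, f in enumerate(ds.feature_ids)}
        new_ids: list[str] = []
        new_rows: list[np.ndarray] = []
        for g in ordered:
            fids = [f for f in groups[g].get(ds.modality_id, []) if f in row_of]
            if not fids:
                continue
            if mapping.strategy == "aggregate" and len(fids) > 1:
                new_ids.append(g)
                new_rows.append(
                    _aggregate(ds.values[[row_of[f] for f in fids]], mapping.aggregate_fn)
                )
            elif mapping.strategy == "expand" and len(fids) > 1:
                # expansion handled jointly below; collect per-feature rows
                for f in fids:
                    new_ids.append(f"{g}|{ds.modality_id}={f}")
                    new_rows.append(ds.values[row_of[f]])
            else:
                new_ids.append(g)
                new_rows.append(ds.values[row_of[fids[0]]])
        out.append(
            OmicsDataset(
                modality_id=ds.modality_id,
                feature_ids=new_ids,
                sample_ids=ds.sample_ids,
                values=np.vstack(new_rows) if new_rows else np.empty((0, ds.n_samples)),
                kind=ds.kind,
            )
        )

    if mapping.strategy == "expand":
        return _expand_tuples(datasets, groups, ordered, per_modality)
    return out


def _expand_tuples(datasets, groups, ordered, per_modality) -> list[OmicsDataset]:
    """One output group per cross-modality feature tuple (cartesian product)."""
    new_ids_per_mod: dict[str, list[str]] = {m: [] for m in per_modality}
    rows_per_mod: dict[str, list[np.ndarray]] = {m: [] for m in per_modality}
    row_of = {
        m: {f: i for i, f in enumerate(ds.feature_ids)} for m, ds in per_modality.items()
    }
    for g in ordered:
        mods_present = [
            m
            for m in per_modality
            if any(f in row_of[m] for f in groups[g].get(m, []))
        ]
        if not mods_present:
            continue
        choices = [
            [(m, f) for f in groups[g][m] if f in row_of[m]] for m in mods_present
        ]
        for combo in itertools.product(*choices):
            suffix = "+".join(f"{m}={f}" for m, f in combo)
            tuple_id = f"{g}|{suffix}" if any(len(c) > 1 for c in choices) else g
            for m, f in combo:
                new_ids_per_mod[m].append(tuple_id)
                rows_per_mod[m].append(per_modality[m].values[row_of[m][f]])
    out = []
    for ds in datasets:
        m = ds.modality_id
        out.append(
            OmicsDataset(
                modality_id=m,
                feature_ids=new_ids_per_mod[m],
                sample_ids=ds.sample_ids,
                values=np.vstack(rows_per_mod[m])
                if rows_per_mod[m]
                else np.empty((0, ds.n_samples)),
                kind=ds.kind,
            )
        )
    return out
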