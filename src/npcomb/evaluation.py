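"""Performance and calibration metrics.

Discrimination is measured with the McClish-standardized partial AUC over
the high-specificity region (specificity in [0.9, 1] by default): on the
standardized scale chance ordering scores 0.5 and a perfect ranking 1,
matching the interpretation of the full AUC.  Calibration is assessed with
the joint null criterion: p-values produced on data where every null holds
should be uniform, checked by a double Kolmogorov-Smirnov ("dks")
procedure — one KS test per simulated null study, then a KS test of those
KS p-values against Uniform(0, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import StatisticSpec, StudyDesign, ValidationError
from .integrators import (
    baseline_rank_pvalues,
    benjamini_partial_conjunction,
    cp_fisher,
    npc_rank_combine,
    rank_features,
    rank_prod_stat,
    rankprod_approx_pvalue,
)
from .npc import build_permutation_plan, combine, compute_statistics, pool_pvalues
from .simulate import SimulationConfig, sim_correlated_pair
from .stats import StatisticEngine, parametric_pvalues

__all__ = [
    "roc_points",
    "pauc_mcclish",
    "median_pauc_experiment",
    "PaucExperiment",
    "double_ks",
    "JNCReport",
    "score_methods",
    "METHOD_NAMES",
]


# ---------------------------------------------------------------------------
# ROC / partial AUC


def roc_points(scores: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tie-grouped ROC vertices for p-value-like scores (smaller = positive call).

    Returns ``(fpr, tpr)`` arrays starting at (0, 0) and ending at (1, 1),
    with one vertex per distinct score.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if not np.all(np.isfinite(s)):
        raise ValidationError("scores must be finite")
    P = int(t.sum())
    N = int((~t).sum())
    if P == 0 or N == 0:
        raise ValidationError("truth must contain at least one positive and one negative")
    order = np.argsort(s, kind="stable")
    s_sorted, t_sorted = s[order], t[order]
    # group ties: one vertex after each distinct score block
    boundary = np.nonzero(np.diff(s_sorted))[0]
    idx = np.concatenate([boundary, [len(s_sorted) - 1]])
    tp = np.cumsum(t_sorted)[idx]
    fp = np.cumsum(~t_sorted)[idx]
    fpr = np.concatenate([[0.0], fp / N])
    tpr = np.concatenate([[0.0], tp / P])
    return fpr, tpr


def _clip_integrate(fpr: np.ndarray, tpr: np.ndarray, a: float, b: float) -> float:
    """Trapezoidal area of the ROC polyline over FPR in [a, b], with linear
    interpolation at the boundaries."""
    xs: list[float] = []
    ys: list[float] = []

    def add(x, y):
        if not xs or x != xs[-1] or y != ys[-1]:
            xs.append(x)
            ys.append(y)

    for (x0, y0), (x1, y1) in zip(zip(fpr, tpr), zip(fpr[1:], tpr[1:])):
        if x1 < a or x0 > b:
            continue
        if x1 == x0:  # vertical jump: zero width
            if a <= x0 <= b:
                add(x0, y0)
                add(x0, y1)
            continue
        lo, hi = max(x0, a), min(x1, b)
        slope = (y1 - y0) / (x1 - x0)
        add(lo, y0 + slope * (lo - x0))
        add(hi, y0 + slope * (hi - x0))
    if not xs:
        return 0.0
    return float(np.trapezoid(ys, xs))


def pauc_mcclish(
    scores: np.ndarray,
    truth: np.ndarray,
    spec_lo: float = 0.9,
    spec_hi: float = 1.0,
    standardize: bool = True,
) -> float:
    """McClish-standardized partial AUC over specificity in [spec_lo, spec_hi].

    The raw pAUC is the trapezoidal area of TPR over FPR in
    ``[1 - spec_hi, 1 - spec_lo]``.  Standardization maps it to [~0, 1] via
    ``0.5 * (1 + (pAUC - min) / (max - min))`` with ``min`` the diagonal
    (chance) area and ``max`` the rectangle, so chance = 0.5 and a perfect
    ranking = 1.
    """
    a, b = 1.0 - spec_hi, 1.0 - spec_lo
    if not (0.0 <= a < b <= 1.0):
        raise ValidationError("empty or invalid specificity range")
    fpr, tpr = roc_points(scores, truth)
    raw = _clip_integrate(fpr, tpr, a, b)
    if not standardize:
        return raw
    min_area = (b**2 - a**2) / 2.0
    max_area = b - a
    return 0.5 * (1.0 + (raw - min_area) / (max_area - min_area))


# ---------------------------------------------------------------------------
# repeated-simulation pAUC comparison


@dataclass
class PaucExperiment:
    """Per-repetition pAUCs, medians, and Wilcoxon comparisons vs the best."""

    pauc: pd.DataFrame  # repetitions x methods
    medians: pd.Series
    best_method: str
    wilcoxon_p: pd.Series  # paired two-sided signed-rank vs the best method


def median_pauc_experiment(
    simulate_fn: Callable[[int], object],
    score_fns: dict[str, Callable],
    repetitions: int = 20,
    seed: Optional[int] = None,
    truth_fn: Optional[Callable] = None,
    spec_lo: float = 0.9,
) -> PaucExperiment:
    """Median pAUC over repeated simulations with paired Wilcoxon comparisons.

    Each repetition simulates one study (``simulate_fn(rep_seed)``) that all
    methods score (paired design); ``truth_fn(study)`` returns
    ``(truth, subset_mask)`` selecting the evaluation genes.  The best
    method (highest median) is compared to every other with the paired
    two-sided Wilcoxon signed-rank test.  A method failure in a repetition
    is recorded as missing and excluded pairwise, with a warning.
    """
    if repetitions < 2:
        raise ValidationError("need at least 2 repetitions")
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(repetitions)]
    rows = []
    for r, rep_seed in enumerate(rep_seeds):
        study = simulate_fn(rep_seed)
        truth, subset = truth_fn(study) if truth_fn else (study.truth_any.to_numpy(), None)
        truth = np.asarray(truth, dtype=bool)
        row = {}
        for name, fn in score_fns.items():
            try:
                scores = np.asarray(fn(study, rep_seed), dtype=float)
                if subset is not None:
                    row[name] = pauc_mcclish(scores[subset], truth[subset], spec_lo=spec_lo)
                else:
                    row[name] = pauc_mcclish(scores, truth, spec_lo=spec_lo)
            except Exception as exc:  # noqa: BLE001 - record and move on
                warnings.warn(f"method {name!r} failed in repetition {r}: {exc}")
                row[name] = np.nan
        rows.append(row)
    pauc = pd.DataFrame(rows)
    medians = pauc.median()
    best = medians.idxmax()
    wp = {}
    for name in pauc.columns:
        if name == best:
            wp[name] = 1.0
            continue
        pair = pauc[[best, name]].dropna()
        diffs = pair[best] - pair[name]
        if np.allclose(diffs, 0.0):
            wp[name] = 1.0
        else:
            wp[name] = float(sps.wilcoxon(pair[best], pair[name]).pvalue)
    return PaucExperiment(
        pauc=pauc,
        medians=medians,
        best_method=best,
        wilcoxon_p=pd.Series(wp),
    )


# ---------------------------------------------------------------------------
# joint null criterion: double Kolmogorov-Smirnov


@dataclass
class JNCReport:
    """Joint-null-criterion diagnostics for one method / scenario."""

    method: str
    scenario: str
    repetitions: int
    first_level_ps: np.ndarray
    dks_p: float
    mean_mass_at_005: float  # mean empirical CDF of gene p-values at 0.05

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "scenario": self.scenario,
            "repetitions": self.repetitions,
            "first_level_ps": [float(x) for x in self.first_level_ps],
            "dks_p": float(self.dks_p),
            "mean_mass_at_005": float(self.mean_mass_at_005),
        }


def _ks_uniform(p: np.ndarray) -> float:
    return float(sps.kstest(p, "uniform", mode="asymp").pvalue)


def double_ks(
    method: Callable,
    repetitions: int = 1000,
    genes: int = 1000,
    samples: int = 20,
    scenario: str = "uncorrelated",
    seed: Optional[int] = None,
) -> Union[JNCReport, dict[str, JNCReport]]:
    """Double-KS check of the joint null criterion.

    Per repetition: simulate two all-null microarray-like datasets (either
    uncorrelated or perfectly correlated), randomly split the samples
    equally into two groups, apply ``method(datasets, design, rep_seed)``,
    and KS-test the resulting gene p-values against Uniform(0, 1).  The
    second-level (dks) p-value KS-tests the repetition KS p-values against
    Uniform(0, 1).  ``method`` may return a single p-value vector or a dict
    of vectors keyed by method name, in which case a report per key is
    returned.
    """
    if scenario not in ("uncorrelated", "correlated"):
        raise ValidationError("scenario must be 'uncorrelated' or 'correlated'")
    if samples % 2:
        raise ValidationError("samples must be even (equal group split)")
    rho = 1.0 if scenario == "correlated" else 0.0
    config = SimulationConfig(
        num_genes=genes,
        num_samples_per_group=samples // 2,
        rnaseq_de=0,
        microarray_de=0,
        snp_de=0,
        unif_de=0,
        common_de=0,
        cor_level=rho,
    )
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(repetitions)]
    first: dict[str, list[float]] = {}
    mass: dict[str, list[float]] = {}
    n = samples // 2
    for rep_seed in rep_seeds:
        rng = np.random.default_rng(rep_seed)
        ds1, ds2, _ = sim_correlated_pair(config, rng)
        labels = rng.permutation(np.array(["group1"] * n + ["group2"] * n))
        design = StudyDesign(
            sample_ids=config.sample_ids,
            outcome=pd.Series(labels),
            outcome_type="dichotomous",
        )
        out = method([ds1, ds2], design, rep_seed)
        if not isinstance(out, dict):
            out = {"method": np.asarray(out)}
        for name, p in out.items():
            p = np.asarray(p, dtype=float)
            first.setdefault(name, []).append(_ks_uniform(p))
            mass.setdefault(name, []).append(float(np.mean(p <= 0.05)))
    reports = {
        name: JNCReport(
            method=name,
            scenario=scenario,
            repetitions=repetitions,
            first_level_ps=np.array(ps),
            dks_p=_ks_uniform(np.array(ps)) if repetitions > 1 else np.nan,
            mean_mass_at_005=float(np.mean(mass[name])),
        )
        for name, ps in first.items()
    }
    return reports["method"] if set(reports) == {"method"} else reports


# ---------------------------------------------------------------------------
# method registry shared by the benchmark harnesses and the CLI

METHOD_NAMES = (
    "npc-fisher",
    "npc-liptak",
    "npc-tippett",
    "npc-nocorr-fisher",
    "npc-nocorr-liptak",
    "npc-nocorr-tippett",
    "npc-ranksum",
    "npc-rankprod",
    "ranksum",
    "rankprod",
    "rankprod-approx",
    "cp",
    "benjamini",
)


def score_methods(
    names: Sequence[str],
    datasets: Sequence,
    design: StudyDesign,
    specs: Optional[dict[str, StatisticSpec]] = None,
    B: int = 1000,
    seed: Optional[int] = None,
) -> dict[str, np.ndarray]:
    """Per-gene p-values for each named method, sharing computation.

    All synchronized-permutation methods reuse one permutation plan and one
    set of per-modality statistic matrices; parametric methods reuse the
    observed statistics.  ``single:<modality_id>`` names give the
    per-modality parametric analysis.  Datasets must share feature ids.
    """
    names = list(names)
    for nm in names:
        if nm not in METHOD_NAMES and not nm.startswith("single:"):
            raise ValidationError(f"unknown method {nm!r}; valid: {METHOD_NAMES}")
    engines = {
        ds.modality_id: StatisticEngine(ds, design, (specs or {}).get(ds.modality_id))
        for ds in datasets
    }
    mod_ids = [ds.modality_id for ds in datasets]

    needs_sync = any(
        nm.startswith("npc-") for nm in names
    )
    needs_parametric = any(nm in ("cp", "benjamini", "rankprod-approx") for nm in names) or any(
        nm.startswith("single:") for nm in names
    )

    stat_mats = None
    plan = None
    if needs_sync:
        plan = build_permutation_plan(design, B, seed)
        stat_mats = [
            np.vstack(
                [engines[m].statistic(plan.labels[b]).values for b in range(plan.B + 1)]
            )
            for m in mod_ids
        ]
    parametric = None
    if needs_parametric:
        parametric = np.vstack([engines[m].parametric_pvalues() for m in mod_ids])

    cube = cube_nc = None
    out: dict[str, np.ndarray] = {}
    for nm in names:
        if nm.startswith("single:"):
            mod = nm.split(":", 1)[1]
            out[nm] = parametric[mod_ids.index(mod)]
        elif nm in ("cp",):
            out[nm] = cp_fisher(parametric)
        elif nm == "benjamini":
            out[nm] = benjamini_partial_conjunction(parametric, u=1)
        elif nm == "rankprod-approx":
            ranks = rank_features(parametric)
            rho = rank_prod_stat(ranks)
            out[nm] = np.asarray(
                rankprod_approx_pvalue(rho, k=len(mod_ids), n=parametric.shape[1])
            )
        elif nm in ("ranksum", "rankprod"):
            out[nm] = baseline_rank_pvalues(
                datasets,
                design,
                specs,
                B=B,
                seed=seed,
                statistic="sum" if nm == "ranksum" else "product",
            )
        elif nm in ("npc-ranksum", "npc-rankprod"):
            out[nm] = npc_rank_combine(
                plan,
                datasets,
                design,
                specs,
                statistic="sum" if nm == "npc-ranksum" else "product",
                stat_matrices=stat_mats,
            )
        else:  # npc-[nocorr-]<combiner>
            nocorr = "nocorr" in nm
            comb = nm.split("-")[-1]
            if nocorr:
                if cube_nc is None:
                    cube_nc = np.stack([pool_pvalues(S, False) for S in stat_mats])
                stats_g = combine(cube_nc, comb, allow_zero=True)
                out[nm] = pool_pvalues(stats_g, False)[0]
            else:
                if cube is None:
                    cube = np.stack([pool_pvalues(S, True) for S in stat_mats])
                stats_g = combine(cube, comb)
                out[nm] = pool_pvalues(stats_g, True)[0]
    return out
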