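"""Per-modality association statistics between features and an outcome.

Each statistic is oriented so that *larger values mean stronger evidence
against the partial null*, the convention the permutation pooling step
relies on.  Linear-model statistics support empirical-Bayes variance
moderation; sequencing counts are pretreated with a log-cpm transform plus
mean-variance precision weights before entering the (weighted) linear model.

A :class:`StatisticEngine` precomputes everything that does not depend on
the outcome labeling (ranks, genotype indicators, precision weights,
moderation hyperparameters) so that re-evaluating the statistic under
thousands of permuted labelings stays cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datatypes import (
    ModalityKind,
    OmicsDataset,
    OutcomeType,
    StatisticSpec,
    StudyDesign,
    ValidationError,
)

__all__ = [
    "StatisticVector",
    "StatisticEngine",
    "design_matrix",
    "linear_model_stats",
    "voom_transform",
    "genotype_trend_stat",
    "ranksum_stat",
    "parametric_pvalues",
    "fit_scaled_f_prior",
]

# sentinel magnitude for perfect separation (zero residual variance, nonzero effect)
SEPARATION_SENTINEL = 1e12


@dataclass
class StatisticVector:
    """Per-feature statistics for one modality under one labeling.

    ``values`` is the oriented evidence (larger = stronger); ``raw`` keeps
    the signed statistic for parametric p-value computation.  ``dist`` is
    the reference distribution ("t", "F" or "normal") with ``df`` its
    degrees of freedom (scalar for t/normal, ``(df1, df2)`` for F).
    """

    values: np.ndarray
    raw: np.ndarray
    dist: str
    df: Union[float, tuple]
    sidedness: str = "two_sided"
    flags: np.ndarray = field(default=None)  # True where degenerate (zero variance)
    cc: Union[float, np.ndarray] = 0.0  # continuity correction in z units

    def __post_init__(self):
        if self.flags is None:
            self.flags = np.zeros(len(self.values), dtype=bool)


def parametric_pvalues(sv: StatisticVector) -> np.ndarray:
    """P-values from the statistic's parametric reference distribution."""
    if sv.dist == "F":
        df1, df2 = sv.df
        p = sps.f.sf(sv.raw, df1, df2)
    else:
        dist = sps.t(sv.df) if sv.dist == "t" else sps.norm()
        if sv.sidedness == "two_sided":
            p = 2.0 * dist.sf(np.maximum(np.abs(sv.raw) - sv.cc, 0.0))
        elif sv.sidedness == "one_sided_greater":
            p = dist.sf(sv.raw - sv.cc)
        else:
            p = dist.cdf(sv.raw + sv.cc)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p[sv.flags] = 1.0
    return p


# ---------------------------------------------------------------------------
# model matrices


def design_matrix(
    design: StudyDesign, outcome_labels: Optional[np.ndarray] = None
) -> tuple[np.ndarray, list[int]]:
    """Build the model matrix: intercept, outcome column(s), covariates.

    Returns ``(X, outcome_cols)`` where ``outcome_cols`` indexes the
    outcome's columns in ``X`` (one indicator column for a dichotomous
    outcome, k-1 for multi-class, one numeric column for continuous).
    Categorical covariates are expanded to indicator columns.  A
    rank-deficient matrix (e.g. a constant covariate, or outcome collinear
    with covariates) raises :class:`ValidationError`.
    """
    labels = design.outcome.to_numpy() if outcome_labels is None else np.asarray(outcome_labels)
    n = len(labels)
    cols = [np.ones(n)]
    if design.outcome_type is OutcomeType.CONTINUOUS:
        cols.append(np.asarray(labels, dtype=float))
        outcome_cols = [1]
    else:
        levels = np.unique(design.outcome.to_numpy())
        outcome_cols = []
        for lev in levels[1:]:  # first level is the reference
            outcome_cols.append(len(cols))
            cols.append((labels == lev).astype(float))
    if design.covariates is not None:
        for name in design.covariates.columns:
            col = design.covariates[name]
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.to_numpy(dtype=float))
            else:
                vals = col.to_numpy()
                for lev in np.unique(vals)[1:]:
                    cols.append((vals == lev).astype(float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(
            "rank-deficient model matrix (constant or collinear columns, "
            "possibly outcome confounded with covariates)"
        )
    return X, outcome_cols


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (monotone, well-behaved)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # starting value from the large-y expansion
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) / y < 1e-10):
            break
    return y


def fit_scaled_f_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log sample variances against a scaled-F model.

    Under the hierarchical model ``s2_g ~ s0^2 * F(df, d0)`` the log
    variances have known mean/variance in terms of di/trigamma functions;
    matching the first two moments of ``log s2_g`` yields the prior degrees
    of freedom ``d0`` and prior variance ``s0^2``.  Returns
    ``(d0, s0_sq)``; ``d0 = inf`` when the observed spread of log variances
    is no larger than expected from sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * float(_trigamma_inverse(np.array([evar]))[0])
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderate_variances(
    s2: np.ndarray, df: float, d0: float, s0_sq: float
) -> tuple[np.ndarray, float]:
    """Shrink per-feature variances toward the prior; returns (s2_post, df_post)."""
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, dtype=float), s0_sq), np.inf
    s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    return s2_post, d0 + df


# ---------------------------------------------------------------------------
# linear-model statistics


def _ols_fit(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature OLS: returns (beta, rss). Y is features x samples."""
    H = np.linalg.pinv(X)  # p x n
    beta = Y @ H.T  # G x p
    resid = Y - beta @ X.T
    rss = np.einsum("gn,gn->g", resid, resid)
    return beta, rss


def _wls_fit(
    Y: np.ndarray, X: np.ndarray, W: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature weighted LS with per-observation weights W (features x samples).

    Returns (beta, rss, xtwx_inv) with xtwx_inv of shape (G, p, p).
    """
    xtwx = np.einsum("ni,gn,nj->gij", X, W, X)
    xtwy = np.einsum("ni,gn->gi", X, W * Y)
    xtwx_inv = np.linalg.inv(xtwx)
    beta = np.einsum("gij,gj->gi", xtwx_inv, xtwy)
    fitted = beta @ X.T
    rss = np.einsum("gn,gn->g", W * (Y - fitted), Y - fitted)
    return beta, rss, xtwx_inv


def linear_model_stats(
    data: Union[OmicsDataset, np.ndarray],
    model: np.ndarray,
    coef: list[int],
    spec: StatisticSpec,
    weights: Optional[np.ndarray] = None,
    prior: Optional[tuple[float, float]] = None,
    rss_reduced: Optional[np.ndarray] = None,
) -> StatisticVector:
    """Per-feature (weighted) least-squares t or partial-F statistics.

    ``coef`` indexes the outcome columns of ``model``.  With a single
    outcome column the statistic is ``t = beta / (s * c)``; with several
    (multi-class outcome) it is the partial F over those columns.  When
    ``spec.moderation`` is on, the residual variance is replaced by its
    empirical-Bayes posterior with hyperparameters ``prior`` (estimated
    here if not supplied) and the degrees of freedom grow accordingly.
    """
    Y = data.values if isinstance(data, OmicsDataset) else np.asarray(data, dtype=float)
    X = np.asarray(model, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValidationError(f"need more samples ({n}) than model columns ({p})")
    df_resid = n - p

    if weights is None:
        beta, rss = _ols_fit(Y, X)
        xtx_inv = np.linalg.inv(X.T @ X)
        c_diag = np.diag(xtx_inv)
        var_unit = np.broadcast_to(c_diag, (Y.shape[0], p))
    else:
        beta, rss, xtwx_inv = _wls_fit(Y, X, weights)
        var_unit = np.einsum("gii->gi", xtwx_inv.copy())

    # catastrophic-cancellation guard: residuals at machine-noise level count as zero
    scale = np.einsum("gn,gn->g", Y, Y)
    rss = np.where(rss <= scale * 1e-24, 0.0, rss)
    s2 = rss / df_resid
    if spec.moderation:
        if prior is None:
            prior = fit_scaled_f_prior(s2, df_resid)
        s2_post, df_post = moderate_variances(s2, df_resid, *prior)
    else:
        s2_post, df_post = s2, float(df_resid)

    if len(coef) == 1:
        b = beta[:, coef[0]]
        b = np.where(np.abs(b) <= np.sqrt(scale) * 1e-12, 0.0, b)
        se = np.sqrt(np.maximum(s2_post * var_unit[:, coef[0]], 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = b / se
        zero_var = se == 0
        t = np.where(zero_var & (b != 0), np.sign(b) * SEPARATION_SENTINEL, t)
        t = np.where(zero_var & (b == 0), 0.0, t)
        flags = zero_var & (b == 0)
        if spec.sidedness == "two_sided":
            evidence = np.abs(t)
        elif spec.sidedness == "one_sided_greater":
            evidence = t
        else:
            evidence = -t
        return StatisticVector(
            values=evidence,
            raw=t,
            dist="t",
            df=df_post,
            sidedness=spec.sidedness,
            flags=flags,
        )

    # partial F over the outcome's indicator columns
    q = len(coef)
    keep = [j for j in range(p) if j not in coef]
    if rss_reduced is None:
        if weights is None:
            _, rss_reduced = _ols_fit(Y, X[:, keep])
        else:
            _, rss_reduced, _ = _wls_fit(Y, X[:, keep], weights)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (rss_reduced - rss) / q / s2_post
    zero_var = s2_post == 0
    effect = (rss_reduced - rss) > 0
    F = np.where(zero_var & effect, SEPARATION_SENTINEL, F)
    F = np.where(zero_var & ~effect, 0.0, F)
    F = np.maximum(F, 0.0)  # numerical guard: nested models
    flags = zero_var & ~effect
    return StatisticVector(
        values=F,
        raw=F,
        dist="F",
        df=(float(q), df_post),
        sidedness="two_sided",
        flags=flags,
    )


# ---------------------------------------------------------------------------
# voom-style count pretreatment


def voom_transform(
    counts: Union[OmicsDataset, np.ndarray],
    model: np.ndarray,
    lowess_frac: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-cpm transform of counts with mean-variance precision weights.

    ``logcpm = log2((count + 0.5) / (libsize + 1.0) * 1e6)``.  A lowess
    curve of the quarter-root residual variance (sqrt of the residual
    standard deviation) versus mean log2-count is fitted across genes,
    evaluated at each observation's fitted value, and raised to the -4th
    power to give precision weights for downstream weighted least squares.
    """
    Y = counts.values if isinstance(counts, OmicsDataset) else np.asarray(counts, dtype=float)
    lib = Y.sum(axis=0)
    if np.any(lib <= 0):
        raise ValidationError("sample with zero total counts")
    logcpm = np.log2((Y + 0.5) / (lib + 1.0) * 1e6)

    X = np.asarray(model, dtype=float)
    n, p = X.shape
    beta, rss = _ols_fit(logcpm, X)
    sigma = np.sqrt(rss / max(n - p, 1))
    # mean log2-count per gene (shift log-cpm back by the mean log library size)
    sx = logcpm.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)

    ok = np.isfinite(sx) & np.isfinite(sy)
    if np.ptp(sx[ok]) == 0:  # degenerate: all genes share one mean count
        lo_x = np.array([sx[ok][0] - 0.5, sx[ok][0] + 0.5])
        lo_y = np.full(2, max(float(np.mean(sy[ok])), 1e-6))
    else:
        fit = lowess(sy[ok], sx[ok], frac=lowess_frac, return_sorted=True)
        lo_x, lo_y = fit[:, 0], np.maximum(fit[:, 1], 1e-6)

    fitted = beta @ X.T  # fitted log-cpm per observation
    fitted_logcount = fitted + (np.mean(np.log2(lib + 1.0)) - np.log2(1e6))
    w = np.interp(fitted_logcount, lo_x, lo_y) ** -4
    return logcpm, w


# ---------------------------------------------------------------------------
# genotype trend and rank-sum statistics


def genotype_trend_stat(
    data: Union[OmicsDataset, np.ndarray],
    groups: np.ndarray,
    sidedness: str = "two_sided",
) -> StatisticVector:
    """Cochran-Armitage trend statistic per SNP with scores (0, 1, 2).

    ``groups`` is a boolean case indicator.  The z statistic uses the
    permutation (hypergeometric) variance conditional on the genotype
    margins; monomorphic SNPs get statistic 0 and are flagged.
    """
    G = data.values if isinstance(data, OmicsDataset) else np.asarray(data, dtype=float)
    case = np.asarray(groups, dtype=bool)
    N = G.shape[1]
    R = int(case.sum())
    if R == 0 or R == N:
        raise ValidationError("both groups must be non-empty")
    scores = np.array([0.0, 1.0, 2.0])
    ind = np.stack([(G == k) for k in (0, 1, 2)])  # 3 x G x n
    n_k = ind.sum(axis=2)  # 3 x G (genotype margins)
    r_k = ind[:, :, case].sum(axis=2)  # 3 x G (cases per genotype)
    U = np.einsum("k,kg->g", scores, r_k) - (R / N) * np.einsum("k,kg->g", scores, n_k)
    sum_nx2 = np.einsum("k,kg->g", scores**2, n_k)
    sum_nx = np.einsum("k,kg->g", scores, n_k)
    var = (R * (N - R)) / (N**2 * (N - 1)) * (N * sum_nx2 - sum_nx**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = U / np.sqrt(var)
    flags = var <= 0
    z = np.where(flags, 0.0, z)
    if sidedness == "two_sided":
        evidence = np.abs(z)
    elif sidedness == "one_sided_greater":
        evidence = z
    else:
        evidence = -z
    return StatisticVector(
        values=evidence, raw=z, dist="normal", df=np.inf, sidedness=sidedness, flags=flags
    )


def _midranks(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise midranks and the tie-corrected rank-sum variance factor."""
    ranks = sps.rankdata(Y, axis=1)
    n = Y.shape[1]
    # tie correction: sum(t^3 - t) per row
    tie_term = np.zeros(Y.shape[0])
    for g in range(Y.shape[0]):
        _, counts = np.unique(Y[g], return_counts=True)
        tie_term[g] = np.sum(counts**3 - counts)
    return ranks, tie_term


def ranksum_stat(
    data: Union[OmicsDataset, np.ndarray],
    groups: np.ndarray,
    sidedness: str = "one_sided_greater",
    _ranks: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> StatisticVector:
    """Wilcoxon rank-sum statistic per feature (midranks for ties).

    ``groups`` marks the comparison group (group 2); ``one_sided_greater``
    means evidence of a shift *upward* in group 2.  The oriented statistic
    is the standardized W with tie-corrected variance; the parametric
    p-value applies the usual 0.5 continuity correction.
    """
    Y = data.values if isinstance(data, OmicsDataset) else np.asarray(data, dtype=float)
    g2 = np.asarray(groups, dtype=bool)
    n = Y.shape[1]
    n2 = int(g2.sum())
    n1 = n - n2
    if n1 == 0 or n2 == 0:
        raise ValidationError("both groups must be non-empty")
    ranks, tie_term = _midranks(Y) if _ranks is None else _ranks
    W = ranks[:, g2].sum(axis=1)
    mu = n2 * (n + 1) / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (W - mu) / np.sqrt(var)
        cc = 0.5 / np.sqrt(var)
    flags = var <= 0
    z = np.where(flags, 0.0, z)
    cc = np.where(flags, 0.0, cc)
    if sidedness == "two_sided":
        evidence = np.abs(z)
    elif sidedness == "one_sided_greater":
        evidence = z
    else:
        evidence = -z
    return StatisticVector(
        values=evidence,
        raw=z,
        dist="normal",
        df=np.inf,
        sidedness=sidedness,
        flags=flags,
        cc=cc,
    )


# ---------------------------------------------------------------------------
# the per-modality engine used by the permutation machinery


class StatisticEngine:
    """Evaluates one modality's statistic under arbitrary outcome labelings.

    Label-independent work — midranks, genotype indicators, voom precision
    weights and moderation hyperparameters (both estimated under the
    observed labels and reused across permutations unless the per-perm
    options are set) — happens once at construction.
    """

    def __init__(
        self,
        dataset: OmicsDataset,
        design: StudyDesign,
        spec: Optional[StatisticSpec] = None,
    ):
        self.dataset = dataset
        self.design = design
        self.spec = spec or StatisticSpec.default_for(dataset.kind, design.outcome_type)
        # positions of this dataset's samples within the design universe
        pos = {s: i for i, s in enumerate(design.sample_ids)}
        self.sample_pos = np.array([pos[s] for s in dataset.sample_ids])
        self._sub_design = StudyDesign(
            sample_ids=list(dataset.sample_ids),
            outcome=design.outcome.loc[dataset.sample_ids].reset_index(drop=True),
            outcome_type=design.outcome_type,
            covariates=(
                design.covariates.loc[dataset.sample_ids].reset_index(drop=True)
                if design.covariates is not None
                else None
            ),
        )
        self._prepare()

    # -- label-independent precomputation ----------------------------------
    def _prepare(self) -> None:
        spec, ds = self.spec, self.dataset
        self._ranks = None
        self._weights = None
        self._prior = None
        self._Y = ds.values
        obs_labels = self._sub_design.outcome.to_numpy()
        if spec.method == "ranksum":
            self._ranks = _midranks(ds.values)
            self._case_level = np.unique(obs_labels)[1]
        elif spec.method == "genotype_trend":
            self._case_level = np.unique(obs_labels)[1]
        else:
            X_obs, self._coef = design_matrix(self._sub_design, obs_labels)
            if spec.method == "voom_linear_model_t":
                self._Y, w = voom_transform(ds, X_obs)
                self._weights = w if not spec.weights_per_perm else None
            if spec.moderation and not spec.moderation_per_perm:
                sv = linear_model_stats(
                    self._Y,
                    X_obs,
                    self._coef,
                    StatisticSpec(
                        method=spec.method, moderation=False, sidedness=spec.sidedness
                    ),
                    weights=self._weights,
                )
                n, p = X_obs.shape
                if self._weights is None:
                    _, rss = _ols_fit(self._Y, X_obs)
                else:
                    _, rss, _ = _wls_fit(self._Y, X_obs, self._weights)
                self._prior = fit_scaled_f_prior(rss / (n - p), n - p)

    # -- statistic under one labeling of the universe -----------------------
    def statistic(self, universe_labels: np.ndarray) -> StatisticVector:
        """Oriented statistic vector under a labeling of the sample universe."""
        labels = np.asarray(universe_labels)[self.sample_pos]
        spec = self.spec
        if spec.method == "ranksum":
            return ranksum_stat(
                self._Y, labels == self._case_level, spec.sidedness, _ranks=self._ranks
            )
        if spec.method == "genotype_trend":
            return genotype_trend_stat(self._Y, labels == self._case_level, spec.sidedness)
        X, coef = design_matrix(self._sub_design, labels)
        weights = self._weights
        if spec.method == "voom_linear_model_t" and spec.weights_per_perm:
            _, weights = voom_transform(self.dataset, X)
        return linear_model_stats(
            self._Y, X, coef, spec, weights=weights, prior=self._prior
        )

    def observed(self) -> StatisticVector:
        return self.statistic(self.design.outcome.to_numpy())

    def parametric_pvalues(self) -> np.ndarray:
        """Classical per-feature p-values under the observed labels."""
        return parametric_pvalues(self.observed())
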