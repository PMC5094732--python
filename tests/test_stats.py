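"""Association-statistic oracles and invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from npcomb import (
    StatisticSpec,
    StudyDesign,
    ValidationError,
    design_matrix,
    genotype_trend_stat,
    linear_model_stats,
    parametric_pvalues,
    ranksum_stat,
    voom_transform,
)
from npcomb.stats import (
    SEPARATION_SENTINEL,
    StatisticEngine,
    fit_scaled_f_prior,
    moderate_variances,
)

from conftest import make_dataset, make_design


def trend_z_closed_form(cases, controls):
    """Independent 2x3 Cochran-Armitage evaluation from the raw cell counts."""
    x = np.array([0.0, 1.0, 2.0])
    r = np.asarray(cases, dtype=float)
    n = r + np.asarray(controls, dtype=float)
    R, N = r.sum(), n.sum()
    U = (x * r).sum() - R / N * (x * n).sum()
    var = R * (N - R) / (N**2 * (N - 1)) * (N * (x**2 * n).sum() - ((x * n).sum()) ** 2)
    return U / np.sqrt(var)


class TestDesignMatrix:
    def test_two_group_no_covariates(self, small_design):
        X, coef = design_matrix(small_design)
        assert X.shape == (6, 2)
        assert coef == [1]
        np.testing.assert_array_equal(np.unique(X[:, 1]), [0.0, 1.0])

    def test_constant_covariate_is_rank_deficient(self):
        design = make_design(3, covariates=pd.DataFrame({"c": [1.0] * 6}))
        with pytest.raises(ValidationError, match="rank-deficient"):
            design_matrix(design)

    def test_numeric_covariate_appends_column(self):
        design = make_design(3, covariates=pd.DataFrame({"age": [31.0, 45, 52, 38, 61, 29]}))
        X, coef = design_matrix(design)
        assert X.shape == (6, 3)
        assert coef == [1]

    def test_outcome_confounded_with_covariate(self):
        design = make_design(
            3, covariates=pd.DataFrame({"batch": ["a", "a", "a", "b", "b", "b"]})
        )
        with pytest.raises(ValidationError, match="rank-deficient"):
            design_matrix(design)


class TestLinearModel:
    def test_ols_t_equals_pooled_two_sample_t(self, rng):
        """Without covariates/moderation the OLS t is the equal-variance t-test."""
        design = make_design(5)
        Y = rng.standard_normal((20, 10))
        X, coef = design_matrix(design)
        sv = linear_model_stats(Y, X, coef, StatisticSpec(moderation=False))
        # reference level is the alphabetically first ("case"); the coefficient
        # is mean(ctrl) - mean(case)
        grp = design.outcome.to_numpy() == "ctrl"
        expected = sps.ttest_ind(Y[:, grp], Y[:, ~grp], axis=1, equal_var=True).statistic
        np.testing.assert_allclose(sv.raw, expected, atol=1e-10)

    def test_moderation_d0_zero_recovers_ordinary_t(self, rng):
        design = make_design(5)
        Y = rng.standard_normal((30, 10))
        X, coef = design_matrix(design)
        plain = linear_model_stats(Y, X, coef, StatisticSpec(moderation=False))
        shrunk = linear_model_stats(
            Y, X, coef, StatisticSpec(moderation=True), prior=(0.0, 1.0)
        )
        np.testing.assert_allclose(shrunk.raw, plain.raw, rtol=1e-12)

    def test_moderation_d0_infinite_uses_prior_variance_only(self, rng):
        design = make_design(5)
        Y = rng.standard_normal((30, 10))
        X, coef = design_matrix(design)
        s0_sq = 2.5
        sv = linear_model_stats(
            Y, X, coef, StatisticSpec(moderation=True), prior=(np.inf, s0_sq)
        )
        beta = Y @ np.linalg.pinv(X).T
        c = np.sqrt(np.linalg.inv(X.T @ X)[1, 1])
        np.testing.assert_allclose(sv.raw, beta[:, 1] / (np.sqrt(s0_sq) * c), rtol=1e-12)

    def test_perfect_separation_and_constant_feature(self):
        design = make_design(3)
        Y = np.array([[0.0, 0, 0, 1, 1, 1], [2.0, 2, 2, 2, 2, 2]])
        X, coef = design_matrix(design)
        sv = linear_model_stats(Y, X, coef, StatisticSpec(moderation=False))
        assert abs(sv.raw[0]) == SEPARATION_SENTINEL
        assert sv.raw[1] == 0.0 and sv.flags[1]
        assert parametric_pvalues(sv)[1] == 1.0

    def test_scale_equivariance(self, rng):
        design = make_design(5)
        Y = rng.standard_normal((10, 10))
        X, coef = design_matrix(design)
        spec = StatisticSpec(moderation=False)
        t1 = linear_model_stats(Y, X, coef, spec).raw
        t2 = linear_model_stats(Y * 7.3, X, coef, spec).raw
        np.testing.assert_allclose(t1, t2, rtol=1e-10)

    def test_multiclass_partial_f_matches_anova(self, rng):
        n_per = 4
        design = StudyDesign(
            sample_ids=[f"s{i}" for i in range(3 * n_per)],
            outcome=pd.Series(["a"] * n_per + ["b"] * n_per + ["c"] * n_per),
            outcome_type="multiclass",
        )
        Y = rng.standard_normal((15, 3 * n_per))
        X, coef = design_matrix(design)
        sv = linear_model_stats(Y, X, coef, StatisticSpec(method="linear_model_F", moderation=False))
        groups = [Y[:, i * n_per : (i + 1) * n_per] for i in range(3)]
        expected = sps.f_oneway(*groups, axis=1).statistic
        np.testing.assert_allclose(sv.raw, expected, rtol=1e-8)


class TestScaledFPrior:
    def test_moment_match_recovers_prior_on_simulated_variances(self, rng):
        d0, s0_sq, df = 8.0, 1.7, 6
        n = 20000
        s2 = s0_sq * sps.f.rvs(df, d0, size=n, random_state=7)
        d0_hat, s0_hat = fit_scaled_f_prior(s2, df)
        assert abs(d0_hat - d0) / d0 < 0.15
        assert abs(s0_hat - s0_sq) / s0_sq < 0.1

    def test_homogeneous_variances_give_infinite_d0(self, rng):
        s2 = np.full(100, 2.0) * np.exp(rng.normal(0, 1e-8, 100))
        d0, s0 = fit_scaled_f_prior(s2, 10)
        assert np.isinf(d0)
        s2_post, df_post = moderate_variances(s2, 10, d0, s0)
        np.testing.assert_allclose(s2_post, s0)


class TestVoom:
    def test_constant_counts_give_equal_logcpm_and_weights(self, small_design):
        counts = make_dataset(np.full((5, 6), 50.0), kind="counts")
        X, _ = design_matrix(small_design)
        logcpm, w = voom_transform(counts, X)
        assert np.allclose(logcpm, logcpm.flat[0])
        assert np.allclose(w, w.flat[0])
        assert np.all(w > 0)

    def test_doubling_one_sample_barely_moves_its_logcpm(self, rng):
        counts = rng.poisson(100, size=(50, 6)).astype(float) + 10
        design = make_design(3)
        X, _ = design_matrix(design)
        logcpm1, _ = voom_transform(make_dataset(counts, kind="counts"), X)
        doubled = counts.copy()
        doubled[:, 0] *= 2
        logcpm2, _ = voom_transform(make_dataset(doubled, kind="counts"), X)
        cmin = counts[:, 0].min()
        bound = np.log2((cmin + 0.5) / (cmin + 0.25)) + 0.01
        assert np.max(np.abs(logcpm2[:, 0] - logcpm1[:, 0])) <= bound

    def test_weights_positive_finite(self, rng):
        counts = rng.poisson(rng.lognormal(4, 1, size=(100, 1)), size=(100, 6)).astype(float)
        counts[0] += 1  # guard against an all-zero library corner
        X, _ = design_matrix(make_design(3))
        _, w = voom_transform(make_dataset(counts, kind="counts"), X)
        assert np.all(np.isfinite(w)) and np.all(w > 0)

    def test_zero_library_rejected(self, small_design):
        counts = make_dataset(np.zeros((3, 6)), kind="counts")
        X, _ = design_matrix(small_design)
        with pytest.raises(ValidationError, match="zero total counts"):
            voom_transform(counts, X)


class TestGenotypeTrend:
    def _dataset_from_table(self, cases, controls):
        row = sum([[k] * controls[k] for k in range(3)], []) + sum(
            [[k] * cases[k] for k in range(3)], []
        )
        values = np.array([row], dtype=float)
        groups = np.array([False] * sum(controls) + [True] * sum(cases))
        return values, groups

    def test_identical_distributions_give_zero(self):
        values, groups = self._dataset_from_table([5, 5, 5], [5, 5, 5])
        sv = genotype_trend_stat(values, groups)
        assert sv.raw[0] == pytest.approx(0.0)

    def test_extreme_table_matches_closed_form(self):
        values, groups = self._dataset_from_table([0, 0, 10], [10, 0, 0])
        sv = genotype_trend_stat(values, groups)
        expected = trend_z_closed_form([0, 0, 10], [10, 0, 0])
        assert sv.raw[0] == pytest.approx(expected, rel=1e-12)
        assert sv.raw[0] == pytest.approx(np.sqrt(20 - 1))  # maximal trend: |z|=sqrt(N-1)

    def test_antisymmetry_under_group_swap(self, rng):
        values = rng.integers(0, 3, size=(10, 16)).astype(float)
        groups = np.arange(16) < 8
        z1 = genotype_trend_stat(values, groups).raw
        z2 = genotype_trend_stat(values, ~groups).raw
        np.testing.assert_allclose(z1, -z2, atol=1e-12)

    def test_monomorphic_flagged_zero(self):
        values = np.full((1, 10), 2.0)
        sv = genotype_trend_stat(values, np.arange(10) < 5)
        assert sv.raw[0] == 0.0 and sv.flags[0]


class TestRankSum:
    def test_extreme_ordering(self):
        values = np.array([[1.0, 2, 3, 4, 5, 6]])
        g2 = np.array([False] * 3 + [True] * 3)
        sv = ranksum_stat(values, g2, sidedness="one_sided_greater")
        # W for group 1 is 6 (the minimum); for group 2, W = 15, z = (15-10.5)/sd
        sd = np.sqrt(3 * 3 * 7 / 12)
        assert sv.raw[0] == pytest.approx((15 - 10.5) / sd)

    def test_all_tied_hits_null_expectation(self):
        values = np.ones((1, 8))
        sv = ranksum_stat(values, np.arange(8) < 4)
        assert sv.raw[0] == 0.0 and sv.flags[0]

    def test_normal_approximation_close_to_exact_enumeration(self, rng):
        from itertools import combinations

        values = rng.standard_normal(6)
        obs_g2 = np.array([False, False, False, True, True, True])
        ranks = sps.rankdata(values)
        w_obs = ranks[obs_g2].sum()
        ws = [ranks[list(idx)].sum() for idx in combinations(range(6), 3)]
        exact = np.mean([w >= w_obs for w in ws])
        sv = ranksum_stat(values[None, :], obs_g2, "one_sided_greater")
        approx = parametric_pvalues(sv)[0]
        assert abs(approx - exact) < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError, match="non-empty"):
            ranksum_stat(np.ones((1, 4)), np.zeros(4, dtype=bool))


class TestStatisticEngine:
    def test_recomputation_is_bit_identical(self, rng):
        design = make_design(5)
        ds = make_dataset(rng.standard_normal((15, 10)))
        engine = StatisticEngine(ds, design)
        labels = design.outcome.to_numpy()
        a = engine.statistic(labels).values
        b = engine.statistic(labels).values
        np.testing.assert_array_equal(a, b)

    def test_subset_modality_reads_only_its_samples(self, rng):
        design = make_design(4)  # universe s0..s7
        ds = make_dataset(
            rng.standard_normal((10, 4)), sample_ids=["s2", "s3", "s4", "s5"]
        )
        engine = StatisticEngine(ds, design)
        labels = design.outcome.to_numpy().copy()
        sv1 = engine.statistic(labels).values
        labels_mod = labels.copy()
        labels_mod[0] = "case"  # s0 is not in the dataset; statistic must not change
        labels_mod[7] = "ctrl"
        sv2 = engine.statistic(labels_mod).values
        np.testing.assert_array_equal(sv1, sv2)
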