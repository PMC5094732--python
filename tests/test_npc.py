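"""Permutation-plan invariants, pooling rules, combining functions and the
full NPC pipeline against small independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from npcomb import (
    CombinerSpec,
    StatisticSpec,
    StudyDesign,
    ValidationError,
    build_permutation_plan,
    combine,
    compute_statistics,
    global_pvalue,
    pool_pvalues,
    run_npc,
)
from npcomb.npc import enumerate_label_assignments

from conftest import make_dataset, make_design


class TestPermutationPlan:
    def test_row_zero_is_observed_and_rows_are_permutations(self):
        design = make_design(6)
        plan = build_permutation_plan(design, B=50, seed=3, exhaustive=False)
        obs = design.outcome.to_numpy()
        np.testing.assert_array_equal(plan.labels[0], obs)
        for b in range(51):
            assert sorted(plan.labels[b]) == sorted(obs)

    def test_seeded_determinism(self):
        design = make_design(6)
        p1 = build_permutation_plan(design, B=30, seed=11, exhaustive=False)
        p2 = build_permutation_plan(design, B=30, seed=11, exhaustive=False)
        np.testing.assert_array_equal(p1.labels, p2.labels)

    def test_exhaustive_enumeration_auto_enabled(self):
        design = make_design(3)  # C(6,3) = 20 distinct assignments
        plan = build_permutation_plan(design, B=19, seed=0)
        assert plan.exhaustive
        assert plan.labels.shape == (20, 6)
        assert len({tuple(r) for r in plan.labels}) == 20

    def test_oversampling_warns_without_exhaustive(self):
        design = make_design(2)  # C(4,2) = 6 assignments
        with pytest.warns(UserWarning, match="distinct label assignments"):
            build_permutation_plan(design, B=100, seed=0, exhaustive=False)

    def test_shared_samples_get_identical_labels_across_views(self, rng):
        # one assignment table serves every modality: restrictions agree by construction
        design = make_design(3)
        plan = build_permutation_plan(design, B=10, seed=5, exhaustive=False)
        ids = design.sample_ids
        view_a = {s: i for i, s in enumerate(ids) if s in ids[:4]}
        view_b = {s: i for i, s in enumerate(ids) if s in ids[2:]}
        shared = set(view_a) & set(view_b)
        for s in shared:
            np.testing.assert_array_equal(
                plan.labels[:, view_a[s]], plan.labels[:, view_b[s]]
            )


class TestPooling:
    def test_corrected_pooling_reproduces_counting_formula(self):
        stats = np.array([[5.0], [1.0], [2.0], [3.0], [4.0]])
        lam = pool_pvalues(stats, zero_correction=True)
        assert lam[0, 0] == pytest.approx(1 / 5)  # (1 + 0) / (B + 1)

    def test_unique_maximum_hits_floor(self):
        stats = np.concatenate([[10.0], np.arange(9, dtype=float)])[:, None]
        assert pool_pvalues(stats, True)[0, 0] == pytest.approx(1 / 10)
        assert pool_pvalues(stats, False)[0, 0] == 0.0

    def test_total_ties_give_one(self):
        stats = np.ones((7, 3))
        np.testing.assert_array_equal(pool_pvalues(stats, True), 1.0)
        np.testing.assert_array_equal(pool_pvalues(stats, False), 1.0)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(st.integers(-5, 5), min_size=2, max_size=8),
            min_size=2,
            max_size=15,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_pooling_matches_brute_force_count(self, rows):
        S = np.array(rows, dtype=float)
        n_rows = S.shape[0]
        lam = pool_pvalues(S, True)
        brute = np.empty_like(S)
        for b in range(n_rows):
            for g in range(S.shape[1]):
                brute[b, g] = np.sum(S[:, g] >= S[b, g]) / n_rows
        np.testing.assert_allclose(lam, brute)
        assert lam.min() >= 1 / n_rows and lam.max() <= 1.0


class TestCombine:
    def _cube(self, *lams):
        return np.array(lams, dtype=float)[:, None, None]

    def test_fisher_of_ones_is_zero(self):
        assert combine(self._cube(1.0, 1.0), "fisher")[0, 0] == pytest.approx(0.0)

    def test_liptak_of_halves_is_zero(self):
        assert combine(self._cube(0.5, 0.5), "liptak")[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_tippett_takes_best_partial(self):
        assert combine(self._cube(0.2, 0.7), "tippett")[0, 0] == pytest.approx(0.8)

    def test_weight_annihilation(self, rng):
        lam2 = rng.uniform(0.01, 1, size=(1, 5))
        cube1 = np.stack([np.full((1, 5), 0.3), lam2])
        cube2 = np.stack([np.full((1, 5), 0.3), rng.uniform(0.01, 1, size=(1, 5))])
        spec = CombinerSpec("fisher", weights=np.array([1.0, 0.0]))
        np.testing.assert_allclose(combine(cube1, spec), combine(cube2, spec))

    def test_zero_partial_rejected_without_correction(self):
        with pytest.raises(ValidationError, match="zero correction"):
            combine(self._cube(0.0, 0.5), "fisher")

    def test_monotonicity_in_each_partial(self, rng):
        lam = rng.uniform(0.05, 1.0, size=(3, 1, 10))
        better = lam.copy()
        better[1] *= 0.5  # strictly decrease one modality's partials
        for name in ("fisher", "liptak", "tippett"):
            assert np.all(combine(better, name) >= combine(lam, name) - 1e-12)


class TestRunNpc:
    def test_single_modality_fisher_global_equals_partial(self, rng):
        # exhaustive 3v3: fisher is a strictly decreasing transform of one lambda
        design = make_design(3)
        ds = make_dataset(rng.standard_normal((12, 6)))
        res = run_npc(
            [ds],
            design,
            B=19,
            seed=1,
            specs={"m1": StatisticSpec(moderation=False)},
            combiners=["fisher"],
        )
        np.testing.assert_allclose(
            res.table["pvalue_global_fisher"], res.table["pvalue_partial_m1"]
        )

    def test_statistic_matrix_rows_follow_plan_rows(self, rng):
        design = make_design(3)
        ds = make_dataset(rng.standard_normal((5, 6)))
        plan = build_permutation_plan(design, B=5, seed=2, exhaustive=False)
        S = compute_statistics(ds, plan, StatisticSpec(moderation=False), design)
        swapped = plan.labels.copy()
        swapped[[1, 3]] = swapped[[3, 1]]
        plan2 = type(plan)(labels=swapped, seed=None)
        S2 = compute_statistics(ds, plan2, StatisticSpec(moderation=False), design)
        np.testing.assert_array_equal(S[[1, 3]], S2[[3, 1]])
        np.testing.assert_array_equal(S[[0, 2, 4, 5]], S2[[0, 2, 4, 5]])

    def test_null_calibration_over_replicate_runs(self):
        """On null data the global p-value rejection rate matches alpha.

        Sharing one permutation plan across features correlates their
        p-values, so the rate is averaged over independent replicate runs
        rather than bounded binomially within one run.
        """
        design = make_design(5)
        B = 100
        fracs = {0.05: [], 0.1: []}
        for s in range(15):
            rng = np.random.default_rng(7000 + s)
            ds1 = make_dataset(rng.standard_normal((500, 10)), modality_id="a")
            ds2 = make_dataset(rng.standard_normal((500, 10)), modality_id="b")
            spec = {m: StatisticSpec(moderation=False) for m in ("a", "b")}
            res = run_npc(
                [ds1, ds2], design, B=B, seed=s, specs=spec, combiners=["fisher"],
                exhaustive=False,
            )
            p = res.table["pvalue_global_fisher"].to_numpy()
            for alpha in fracs:
                fracs[alpha].append(np.mean(p <= alpha))
        for alpha, vals in fracs.items():
            target = np.floor(alpha * (B + 1)) / (B + 1)  # grid-exact null rate
            assert abs(np.mean(vals) - target) < 0.025

    def test_duplicated_modality_preserves_ranking(self, rng):
        design = make_design(5)
        values = rng.standard_normal((100, 10))
        values[:30, 5:] += 1.0
        ds1 = make_dataset(values, modality_id="a")
        ds2 = make_dataset(values.copy(), modality_id="b")
        spec = {m: StatisticSpec(moderation=False) for m in ("a", "b", "m1")}
        single = run_npc(
            [make_dataset(values)], design, B=300, seed=4, specs=spec, combiners=["fisher"]
        )
        dup = run_npc([ds1, ds2], design, B=300, seed=4, specs=spec, combiners=["fisher"])
        rho = sps.spearmanr(
            single.table["pvalue_partial_m1"], dup.table["pvalue_global_fisher"]
        ).statistic
        assert rho > 0.999

    def test_fdr_columns_monotone_and_above_raw(self, rng):
        design = make_design(4)
        ds = make_dataset(rng.standard_normal((50, 8)))
        res = run_npc([ds], design, B=49, seed=0, combiners=["fisher"])
        raw = res.table["pvalue_global_fisher"]
        adj = res.table["fdr_global_fisher"]
        assert np.all(adj >= raw - 1e-12)
        order = np.argsort(raw.to_numpy())
        assert np.all(np.diff(adj.to_numpy()[order]) >= -1e-12)

    def test_min_pvalue_floor(self, rng):
        # 10 vs 10: Monte-Carlo draws essentially never tie the observed labeling
        design = make_design(10)
        values = rng.standard_normal((80, 20))
        values[:40, 10:] += 5.0  # strong signal: some features hit the floor
        ds = make_dataset(values)
        res = run_npc([ds], design, B=99, seed=6, combiners=["fisher", "tippett"])
        ps = res.table.filter(like="pvalue_").to_numpy()
        assert ps.min() >= 1 / 100 - 1e-12
        assert ps.min() == pytest.approx(1 / 100)

    def test_deterministic_given_seed(self, rng):
        design = make_design(4)
        ds = make_dataset(rng.standard_normal((20, 8)))
        r1 = run_npc([ds], design, B=29, seed=13, exhaustive=False)
        r2 = run_npc([ds], design, B=29, seed=13, exhaustive=False)
        pd.testing.assert_frame_equal(r1.table, r2.table)


class TestExchangeability:
    def test_observed_statistic_within_permutation_range(self):
        """For outcome-independent data, row 0 is rarely the extreme row."""
        design = make_design(4)
        hits = 0
        n_seeds = 200
        for s in range(n_seeds):
            rng = np.random.default_rng(1000 + s)
            ds = make_dataset(rng.standard_normal((1, 8)))
            plan = build_permutation_plan(design, B=30, seed=s, exhaustive=False)
            S = compute_statistics(ds, plan, StatisticSpec(moderation=False), design)
            hits += S[0, 0] <= S[1:, 0].max()
        assert hits / n_seeds >= 30 / 31 - 3 * np.sqrt((1 / 31) * (30 / 31) / n_seeds)


def test_enumerate_label_assignments_complete_and_unique():
    out = enumerate_label_assignments(np.array(["a", "a", "b", "b"]))
    assert out.shape == (6, 4)
    assert len({tuple(r) for r in out}) == 6
    np.testing.assert_array_equal(out[0], ["a", "a", "b", "b"])
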