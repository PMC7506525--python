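"""Group statistics: rank consensus, Welch tests, omnibus permutation,
split-half robustness, covariate regression and power."""

import itertools

import numpy as np
import pytest

import envnet as en
from envnet.groupstats import ValidEdgeMask


def make_cohort(values, is_case, with_covariates=False, seed=0):
    values = np.asarray(values, float)
    rng = np.random.default_rng(seed)
    n = values.shape[0]
    kw = {}
    if with_covariates:
        kw = dict(
            age=rng.normal(35, 10, n),
            gender=rng.integers(0, 2, n).astype(float),
            icv=rng.normal(1.5e6, 1e5, n),
        )
    return en.CohortData(
        subject_ids=[f"s{i}" for i in range(n)],
        values=values,
        is_case=np.asarray(is_case, bool),
        **kw,
    )


def full_mask(n_edges):
    return ValidEdgeMask(mask=np.ones(n_edges, bool), fraction=1.0)


class TestRankThreshold:
    def test_identical_maps_select_exact_top_fraction(self, rng):
        base = rng.standard_normal(en.n_edges(90))
        values = np.tile(base, (8, 1))
        cohort = make_cohort(values, [True] * 4 + [False] * 4)
        mask = en.rank_threshold(cohort, fraction=0.20)
        assert mask.n_valid == 801  # strictly above rank 0.8 of 4005
        top = np.argsort(base)[-801:]
        assert set(mask.edge_indices) == set(top)

    def test_five_edge_toy_selects_single_top_edge(self):
        values = np.array([
            [1.0, 2.0, 3.0, 4.0, 5.0],
            [1.1, 2.1, 3.1, 4.1, 5.1],
            [0.9, 1.9, 2.9, 3.9, 4.9],
            [1.0, 2.0, 3.0, 4.0, 5.0],
        ])
        cohort = make_cohort(values, [True, True, False, False])
        mask = en.rank_threshold(cohort, fraction=0.2)
        assert list(mask.edge_indices) == [4]

    def test_union_of_disjoint_group_tops_exceeds_fraction(self, rng):
        E = 50
        case = np.tile(np.arange(E, dtype=float), (4, 1))
        ctrl = np.tile(np.arange(E, dtype=float)[::-1], (4, 1))
        cohort = make_cohort(
            np.vstack([case + rng.normal(0, .01, (4, E)),
                       ctrl + rng.normal(0, .01, (4, E))]),
            [True] * 4 + [False] * 4,
        )
        mask = en.rank_threshold(cohort, fraction=0.2)
        assert mask.n_valid > 0.2 * E

    def test_invariant_under_monotone_transform(self, rng):
        values = rng.standard_normal((10, 30))
        labels = [True] * 5 + [False] * 5
        m1 = en.rank_threshold(make_cohort(values, labels))
        m2 = en.rank_threshold(make_cohort(np.exp(values * 2), labels))
        assert np.array_equal(m1.mask, m2.mask)

    def test_bad_fraction_rejected(self, rng):
        cohort = make_cohort(rng.standard_normal((4, 6)),
                             [True, True, False, False])
        with pytest.raises(ValueError):
            en.rank_threshold(cohort, fraction=1.5)


class TestWelchEdges:
    def test_textbook_formula_oracle(self):
        cohort = make_cohort(
            np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]]),
            [True, True, True, False, False, False],
        )
        res = en.welch_edges(cohort, full_mask(1))
        # independent recomputation from the defining formulas
        m1, m2, v1, v2, n1, n2 = 2.0, 5.0, 1.0, 1.0, 3, 3
        t_ref = (m1 - m2) / np.sqrt(v1 / n1 + v2 / n2)
        df_ref = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        assert res.t[0] == pytest.approx(t_ref, abs=1e-10)
        assert res.df[0] == pytest.approx(df_ref, abs=1e-10)

    def test_matches_scipy_welch(self, rng):
        from scipy import stats

        values = rng.standard_normal((12, 7))
        labels = [True] * 5 + [False] * 7
        cohort = make_cohort(values, labels)
        res = en.welch_edges(cohort, full_mask(7))
        ref = stats.ttest_ind(values[:5], values[5:], equal_var=False)
        assert np.allclose(res.t, ref.statistic, atol=1e-12)
        assert np.allclose(res.p, ref.pvalue, atol=1e-12)

    def test_identical_groups_give_t_zero_p_one(self):
        v = np.array([[1.0], [2.0], [1.0], [2.0]])
        res = en.welch_edges(
            make_cohort(v, [True, True, False, False]), full_mask(1)
        )
        assert res.t[0] == pytest.approx(0.0)
        assert res.p[0] == pytest.approx(1.0)

    def test_group_swap_negates_t(self, rng):
        values = rng.standard_normal((10, 4))
        labels = np.array([True] * 5 + [False] * 5)
        a = en.welch_edges(make_cohort(values, labels), full_mask(4))
        b = en.welch_edges(make_cohort(values, ~labels), full_mask(4))
        assert np.allclose(a.t, -b.t)
        assert np.allclose(a.p, b.p)


class TestOmnibusPermutation:
    def test_matches_exhaustive_enumeration_tiny_cohort(self, rng):
        values = rng.standard_normal((6, 2))
        labels = [True] * 3 + [False] * 3
        cohort = make_cohort(values, labels)
        # exhaustive null: all 20 assignments of 3-of-6 to "case"
        from envnet.groupstats import _welch

        maxes = []
        for comb in itertools.combinations(range(6), 3):
            rest = [i for i in range(6) if i not in comb]
            t, _ = _welch(values[list(comb)], values[rest])
            maxes.append(np.abs(t).max())
        exact = np.quantile(maxes, 0.95)
        res = en.omnibus_permutation(
            cohort, full_mask(2), n_perm=4000, alpha=0.05, seed=1
        )
        # sampled max-|t| values must come from the exhaustive support
        assert res.omnibus_threshold == pytest.approx(exact, rel=0.02)

    def test_huge_effect_always_flagged(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            values = rng.standard_normal((20, 5))
            values[:10, 2] += 5.0  # d = 5 at edge 2
            cohort = make_cohort(values, [True] * 10 + [False] * 10)
            res = en.omnibus_permutation(
                cohort, full_mask(5), n_perm=500, seed=seed
            )
            assert res.omnibus_significant[2]

    def test_omnibus_subset_of_uncorrected(self, rng):
        values = rng.standard_normal((16, 10))
        values[:8, :3] += 1.0
        cohort = make_cohort(values, [True] * 8 + [False] * 8)
        res = en.omnibus_permutation(cohort, full_mask(10),
                                     n_perm=500, seed=0)
        uncorrected = res.p < 0.05
        assert np.all(~res.omnibus_significant | uncorrected)

    def test_deterministic_given_seed(self, rng):
        values = rng.standard_normal((12, 6))
        cohort = make_cohort(values, [True] * 6 + [False] * 6)
        a = en.omnibus_permutation(cohort, full_mask(6), n_perm=300, seed=9)
        b = en.omnibus_permutation(cohort, full_mask(6), n_perm=300, seed=9)
        assert a.omnibus_threshold == b.omnibus_threshold

    def test_low_n_perm_warns(self, rng):
        cohort = make_cohort(rng.standard_normal((8, 3)),
                             [True] * 4 + [False] * 4)
        with pytest.warns(RuntimeWarning, match="n_perm"):
            en.omnibus_permutation(cohort, full_mask(3), n_perm=50, seed=0)


class TestSplitHalfRobustness:
    def test_dominant_edge_fully_consistent(self, rng):
        values = rng.uniform(0, 1, (16, 3))
        values[:8, 1] -= 10.0  # every case below every control at edge 1
        cohort = make_cohort(values, [True] * 8 + [False] * 8)
        res = en.split_half_robustness(cohort, full_mask(3),
                                       n_iter=500, seed=0)
        assert res.consistency[1] == pytest.approx(1.0)
        assert res.robust[1]
        assert res.sign[1] == -1

    def test_null_calibration_matches_closed_form(self):
        # split-half signs are correlated through the fixed cohort: for
        # a null edge, consistency ~ Phi(|z|) with z standard normal
        # (the subsampling sd of the half-cohort difference equals the
        # sampling sd of the observed difference), so the robust rate
        # converges to 2*Phi(-1.645) ~ 10%, not to zero
        flags, cons = [], []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            values = rng.standard_normal((40, 5))
            cohort = make_cohort(values, [True] * 20 + [False] * 20)
            res = en.split_half_robustness(cohort, full_mask(5),
                                           n_iter=1000, seed=seed)
            flags.append(res.robust)
            cons.append(res.consistency)
        rate = np.mean(flags)
        assert 0.04 < rate < 0.18
        assert np.median(np.concatenate(cons)) < 0.95

    def test_deterministic_given_seed(self, rng):
        values = rng.standard_normal((12, 4))
        cohort = make_cohort(values, [True] * 6 + [False] * 6)
        a = en.split_half_robustness(cohort, full_mask(4),
                                     n_iter=200, seed=5)
        b = en.split_half_robustness(cohort, full_mask(4),
                                     n_iter=200, seed=5)
        assert np.array_equal(a.consistency, b.consistency)

    def test_requires_four_per_group(self, rng):
        cohort = make_cohort(rng.standard_normal((6, 3)),
                             [True] * 3 + [False] * 3)
        with pytest.raises(ValueError, match=">= 4"):
            en.split_half_robustness(cohort, full_mask(3), n_iter=10,
                                     seed=0)


class TestCovariateRegression:
    def test_true_group_effect_is_robust(self, rng):
        n = 40
        values = rng.standard_normal((n, 4))
        values[:20] -= 2.0  # strong case deficit everywhere
        cohort = make_cohort(values, [True] * 20 + [False] * 20,
                             with_covariates=True)
        res = en.covariate_regression_robustness(
            cohort, full_mask(4), n_iter=300, seed=0
        )
        assert res.robust.all()
        assert (res.sign == -1).all()

    def test_pure_age_effect_not_attributed_to_group(self, rng):
        n = 40
        age = rng.normal(35, 10, n)
        values = np.outer(age, np.ones(3)) + rng.normal(0, .5, (n, 3))
        cohort = en.CohortData(
            subject_ids=[f"s{i}" for i in range(n)],
            values=values,
            is_case=np.array([True] * 20 + [False] * 20),
            age=age,
            gender=rng.integers(0, 2, n).astype(float),
            icv=rng.normal(1.5e6, 1e5, n),
        )
        res = en.covariate_regression_robustness(
            cohort, full_mask(3), n_iter=300, seed=1
        )
        assert not res.robust.any()
        assert np.all(res.consistency < 0.9)

    def test_intercept_absorbs_constant_shift(self, rng):
        n = 24
        values = rng.standard_normal((n, 3))
        labels = [True] * 12 + [False] * 12
        a = en.covariate_regression_robustness(
            make_cohort(values, labels, with_covariates=True),
            full_mask(3), n_iter=50, seed=2,
        )
        b = en.covariate_regression_robustness(
            make_cohort(values + 100.0, labels, with_covariates=True),
            full_mask(3), n_iter=50, seed=2,
        )
        assert np.allclose(a.group_slope, b.group_slope, atol=1e-8)
        assert np.array_equal(a.consistency, b.consistency)

    def test_collinear_design_named(self, rng):
        n = 16
        values = rng.standard_normal((n, 2))
        is_case = np.array([True] * 8 + [False] * 8)
        cohort = en.CohortData(
            subject_ids=[f"s{i}" for i in range(n)],
            values=values,
            is_case=is_case,
            age=is_case.astype(float),  # identical to group indicator
            gender=rng.integers(0, 2, n).astype(float),
            icv=rng.normal(1.5e6, 1e5, n),
        )
        with pytest.raises(ValueError, match="age"):
            en.covariate_regression_robustness(
                cohort, full_mask(2), n_iter=10, seed=0
            )

    def test_missing_covariates_rejected(self, rng):
        cohort = make_cohort(rng.standard_normal((8, 2)),
                             [True] * 4 + [False] * 4)
        with pytest.raises(ValueError, match="covariate"):
            en.covariate_regression_robustness(cohort, full_mask(2),
                                               n_iter=10, seed=0)


class TestTtestPower:
    def test_large_effect_rounds_to_95_percent(self):
        assert round(en.ttest_power(0.8, 42, 0.05), 2) == 0.95

    def test_moderate_effect_rounds_to_62_percent(self):
        assert round(en.ttest_power(0.5, 42, 0.05), 2) == 0.62

    def test_null_effect_gives_alpha(self):
        assert en.ttest_power(0.0, 42, 0.05) == pytest.approx(0.05,
                                                              abs=1e-9)
        assert en.ttest_power(0.0, 10, 0.10) == pytest.approx(0.10,
                                                              abs=1e-9)

    def test_monotone_in_effect_size_and_n(self):
        ds = [0.1, 0.3, 0.5, 0.8, 1.2]
        powers = [en.ttest_power(d, 30) for d in ds]
        assert np.all(np.diff(powers) > 0)
        ns = [5, 10, 20, 40, 80]
        powers_n = [en.ttest_power(0.5, n) for n in ns]
        assert np.all(np.diff(powers_n) > 0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.power import TTestIndPower

        ref = TTestIndPower().power(0.6, 35, 0.05)
        assert en.ttest_power(0.6, 35, 0.05) == pytest.approx(ref,
                                                              abs=1e-8)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            en.ttest_power(-0.5, 42)
        with pytest.raises(ValueError):
            en.ttest_power(0.5, 42, alpha=1.5)


class TestConsistencyScaling:
    def test_consistency_stabilizes_with_more_iterations(self, rng):
        values = rng.standard_normal((24, 5))
        values[:12] -= 0.8
        cohort = make_cohort(values, [True] * 12 + [False] * 12)
        a = en.split_half_robustness(cohort, full_mask(5),
                                     n_iter=500, seed=1)
        b = en.split_half_robustness(cohort, full_mask(5),
                                     n_iter=2000, seed=2)
        # O(1/sqrt(n_iter)) agreement between independent runs
        assert np.abs(a.consistency - b.consistency).max() < 0.06
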