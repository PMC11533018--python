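import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ironmap.cohort import simulate_cohort
from ironmap.roi import merge_hemispheres
from ironmap.stats import (
    assign_age_group,
    assign_groups,
    bonferroni,
    compare_groups,
    compare_two_groups,
    comparison_plan,
    compute_crs,
    fit_age_regression,
    mann_whitney,
)


class TestComputeCrs:
    @pytest.mark.parametrize(
        "true_flags,expected",
        [((), 0),
         (("hypertension", "diabetes", "dyslipidemia", "smoking", "obesity"), 5),
         (("hypertension", "smoking"), 2)],
    )
    def test_counts_present_factors(self, true_flags, expected):
        flags = {f: f in true_flags for f in
                 ("hypertension", "diabetes", "dyslipidemia", "smoking", "obesity")}
        assert compute_crs(flags) == expected

    def test_missing_flag_errors(self):
        with pytest.raises(ValueError, match="missing"):
            compute_crs({"hypertension": True})


class TestAssignGroups:
    def test_boundary_ages_go_to_older_group(self):
        assert assign_age_group(62.0) == "62-69"
        assert assign_age_group(69.0) == "69-78"
        assert assign_age_group(78.0) == "69-78"
        assert assign_age_group(54.0) == "54-62"

    def test_out_of_range_age_is_excluded(self):
        cohort = simulate_cohort(seed=0).cohort.copy()
        cohort.loc[0, "age"] = 83.0
        grouped = assign_groups(cohort)
        assert grouped.loc[0, "excluded"]
        assert not grouped.loc[1:, "excluded"].any()

    def test_bmi_boundary_is_not_overweight(self):
        cohort = simulate_cohort(seed=0).cohort.copy()
        cohort.loc[0, "bmi"] = 25.0
        cohort.loc[1, "bmi"] = 25.01
        grouped = assign_groups(cohort)
        assert not grouped.loc[0, "overweight"]
        assert grouped.loc[1, "overweight"]

    def test_apoe_carrier_definition(self):
        cohort = simulate_cohort(seed=0).cohort.copy()
        cohort["apoe"] = "e3/e3"
        cohort.loc[0, "apoe"] = "e3/e4"
        cohort.loc[1, "apoe"] = "e4/e4"
        cohort = cohort.drop(columns=["apoe_e4_carrier"])
        grouped = assign_groups(cohort)
        assert list(grouped.loc[:2, "apoe_group"]) == ["carrier", "carrier",
                                                       "non-carrier"]


class TestAgeRegression:
    def test_exact_line(self):
        ages = np.array([54.0, 60.0, 66.0, 72.0, 78.0])
        fit = fit_age_regression(ages, 2 * ages + 1)
        assert fit["slope"] == pytest.approx(2.0, abs=1e-12)
        assert fit["intercept"] == pytest.approx(1.0, abs=1e-10)
        assert fit["slope_se"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_matrix_algebra_oracle(self):
        """Closed-form OLS via the normal equations, to 1e-10."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(5, 40)
            x = rng.normal(65, 7, n)
            y = rng.normal(30, 10, n)
            fit = fit_age_regression(x, y)
            X = np.column_stack([np.ones(n), x])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta
            sigma2 = resid @ resid / (n - 2)
            cov = sigma2 * np.linalg.inv(X.T @ X)
            from scipy import stats as sps

            t = beta[1] / np.sqrt(cov[1, 1])
            p = 2 * sps.t.sf(abs(t), n - 2)
            assert fit["slope"] == pytest.approx(beta[1], abs=1e-10)
            assert fit["intercept"] == pytest.approx(beta[0], abs=1e-10)
            assert fit["slope_se"] == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-10)
            assert fit["intercept_se"] == pytest.approx(np.sqrt(cov[0, 0]), abs=1e-10)
            assert fit["p_value"] == pytest.approx(p, abs=1e-10)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            fit_age_regression([60, 60, 60], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            fit_age_regression([60, 61], [1.0, 2.0])


def _mw_enumeration_oracle(a, b):
    """Exact two-sided Mann-Whitney by enumerating all rank assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    na = len(a)

    def u_of(subset):
        x = pooled[list(subset)]
        rest = np.delete(pooled, list(subset))
        gt = (x[:, None] > rest[None, :]).sum()
        eq = (x[:, None] == rest[None, :]).sum()
        return float(gt) + 0.5 * float(eq)

    u_obs = (float((a[:, None] > b[None, :]).sum())
             + 0.5 * float((a[:, None] == b[None, :]).sum()))
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), na)]
    us = np.asarray(us, float)
    mean_u = na * (len(pooled) - na) / 2.0
    p = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)
    return u_obs, float(p)


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 arrangements are as extreme

    def test_identical_multisets(self):
        u, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert u == pytest.approx(4.5)  # n^2 / 2
        assert p == pytest.approx(1.0)

    def test_exact_path_matches_enumeration_for_small_samples(self):
        rng = np.random.default_rng(0)
        for na in range(1, 8):
            for nb in range(1, 8):
                vals = rng.permutation(np.arange(1.0, na + nb + 1.0))
                a, b = vals[:na], vals[na:]
                u, p = mann_whitney(a, b)
                u_ref, p_ref = _mw_enumeration_oracle(a, b)
                assert u == pytest.approx(u_ref)
                assert p == pytest.approx(p_ref, abs=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(1, 12), st.integers(1, 12), st.integers(0, 2**31 - 1))
    def test_u_statistics_sum_to_product(self, na, nb, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=na)
        b = rng.normal(size=nb)
        ua, _ = mann_whitney(a, b)
        ub, _ = mann_whitney(b, a)
        assert ua + ub == pytest.approx(na * nb)
        assert 0 <= ua <= na * nb

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestBonferroni:
    @pytest.mark.parametrize("p,expected", [(0.0001, 0.0112), (0.02, 1.0), (0.0, 0.0)])
    def test_correction(self, p, expected):
        assert bonferroni(p) == pytest.approx(expected)

    def test_invalid_factor_errors(self):
        with pytest.raises(ValueError):
            bonferroni(0.01, factor=0)


class TestComparisonPlan:
    def test_age_parameter_alone_has_three_pairs(self):
        plan = comparison_plan(parameters=("age",))
        assert plan.n_pairs == 3

    def test_full_plan_counts(self):
        plan = comparison_plan()
        assert plan.n_pairs == 16
        assert plan.n_tests == 112
        assert plan.pairs_per_parameter == {
            "age": 3, "sex": 1, "age_sex": 6, "apoe": 1, "crs": 3, "bmi": 2,
        }

    def test_unknown_parameter_errors(self):
        with pytest.raises(ValueError, match="parameter"):
            comparison_plan(parameters=("age", "favourite_color"))


class TestCompareGroups:
    def test_identical_groups_are_null(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = compare_two_groups(a, list(a))
        assert res["percent_difference"] == 0.0
        assert res["p_raw"] == pytest.approx(1.0)

    def test_negative_median_denominator_keeps_difference_sign(self):
        a = np.array([-12.0, -10.0, -8.0])
        res = compare_two_groups(a, a + 2.0)
        assert res["median_a"] == -10.0
        assert res["percent_difference"] == pytest.approx(20.0)

    def test_default_plan_produces_112_rows_per_metric(self):
        data = simulate_cohort(seed=0)
        grouped = assign_groups(data.cohort)
        roi = pd.concat([data.roi, merge_hemispheres(data.roi)],
                        ignore_index=True)
        res = compare_groups(roi, grouped)
        assert res.groupby("metric").size().to_dict() == {"qsm": 112,
                                                          "r2star": 112}
        assert ((res.p_bonferroni.dropna()
                 - (112 * res.p_raw.dropna()).clip(upper=1.0)).abs() < 1e-12).all()
        assert res.u_statistic.dropna().between(
            0, res.n_a.max() * res.n_b.max()
        ).all()
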