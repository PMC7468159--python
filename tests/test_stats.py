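"""Normality gate, two-sample tests against independent oracles,
densitometry normalization."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import gliamorph as gm
from gliamorph.stats import (EXACT_MW_MAX_N, GroupSample, compare_parameter,
                             densitometry_percent, lilliefors_ks,
                             mann_whitney_u, significance_stars,
                             student_t_two_sample, summary_ttest,
                             welch_t_two_sample)


def brute_force_mw_p(x, y):
    """Independent enumeration oracle for the exact Mann-Whitney p."""
    pooled = np.concatenate([x, y])
    n_x, n_y = len(x), len(y)
    centre = n_x * n_y / 2

    def u_of(ix):
        xs = pooled[list(ix)]
        ys = np.delete(pooled, list(ix))
        return ((xs[:, None] > ys[None, :]).sum()
                + 0.5 * (xs[:, None] == ys[None, :]).sum())

    u_obs = u_of(range(n_x))
    devs = [abs(u_of(c) - centre) for c in combinations(range(n_x + n_y), n_x)]
    return sum(d >= abs(u_obs - centre) - 1e-12 for d in devs) / len(devs)


class TestLilliefors:
    def test_near_perfect_normal_sample_passes(self):
        x = sps.norm.ppf((np.arange(1, 21) - 0.5) / 20)
        res = lilliefors_ks(x)
        assert res.pvalue > 0.5
        assert not res.zero_variance

    def test_zero_variance_flagged_non_normal(self):
        res = lilliefors_ks([3.0, 3.0, 3.0, 3.0])
        assert res.zero_variance and res.pvalue == 0.0

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            lilliefors_ks([1.0, 2.0, 3.0])

    def test_bimodal_sample_rejected(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(-4, 0.3, 25), rng.normal(4, 0.3, 25)])
        assert lilliefors_ks(x).pvalue < 0.05

    def test_statistic_matches_statsmodels(self):
        from statsmodels.stats.diagnostic import lilliefors as sm_lf
        rng = np.random.default_rng(2)
        for n in (8, 15, 40):
            x = rng.normal(3, 2, n)
            d_sm, p_sm = sm_lf(x, dist="norm")
            res = lilliefors_ks(x)
            assert res.statistic == pytest.approx(d_sm, abs=1e-12)
            # table-based and approximation p agree in the decision range
            if p_sm < 0.8:
                assert res.pvalue == pytest.approx(p_sm, abs=0.05)

    def test_type_one_error_near_alpha(self):
        rng = np.random.default_rng(9)
        rej = sum(lilliefors_ks(rng.normal(0, 1, 25)).pvalue < 0.05
                  for _ in range(500)) / 500
        assert 0.03 <= rej <= 0.07


class TestStudentT:
    def test_identical_samples(self):
        res = student_t_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_textbook_pair(self):
        res = student_t_two_sample((1, 2, 3), (2, 3, 4))
        assert res.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == 4
        assert res.pvalue == pytest.approx(0.2879, abs=1e-4)

    def test_zero_variance_cases(self):
        res = student_t_two_sample([5.0, 5.0], [5.0, 5.0])
        assert res.pvalue == 1.0
        with pytest.raises(ValueError, match="zero pooled variance"):
            student_t_two_sample([5.0, 5.0], [6.0, 6.0])

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0.0, 1.0, 10)
        y = rng.normal(0.8, 1.0, 10)
        t_obs = abs(student_t_two_sample(x, y).statistic)
        pooled = np.concatenate([x, y])
        hits = 0
        reps = 5000
        for _ in range(reps):
            perm = rng.permutation(pooled)
            t = abs(student_t_two_sample(perm[:10], perm[10:]).statistic)
            hits += t >= t_obs - 1e-12
        p_perm = hits / reps
        assert student_t_two_sample(x, y).pvalue == pytest.approx(p_perm, abs=0.02)

    def test_welch_differs_under_variance_heterogeneity(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [10.0, 30.0, 50.0, 70.0, 90.0, 110.0]
        pooled = student_t_two_sample(x, y)
        welch = welch_t_two_sample(x, y)
        assert welch.df < pooled.df


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        res = mann_whitney_u((1, 2, 3), (4, 5, 6))
        assert res.statistic == 0.0
        assert res.method == "exact"
        # 2 of the C(6,3) = 20 assignments are as extreme
        assert res.pvalue == pytest.approx(0.1)

    def test_equal_multisets(self):
        res = mann_whitney_u([1, 2, 2, 3], [3, 2, 1, 2])
        assert res.pvalue == 1.0

    def test_all_tied(self):
        res = mann_whitney_u([7.0] * 3, [7.0] * 4)
        assert res.pvalue == 1.0 and res.tied

    def test_exact_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(1)
        for nx in (2, 4, 6):
            for ny in (3, 5):
                for _ in range(5):
                    x = rng.integers(0, 6, nx).astype(float)
                    y = rng.integers(0, 6, ny).astype(float)
                    res = mann_whitney_u(x, y)
                    assert res.method == "exact"
                    assert res.pvalue == pytest.approx(
                        brute_force_mw_p(x, y), abs=1e-12)

    def test_exact_close_to_asymptotic(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 6)
        y = rng.normal(0.5, 1, 6)
        exact = mann_whitney_u(x, y)
        approx = sps.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic")
        assert exact.method == "exact"
        assert exact.pvalue == pytest.approx(float(approx.pvalue), abs=0.02)

    def test_large_samples_use_asymptotic(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        assert len(x) + len(y) > EXACT_MW_MAX_N
        res = mann_whitney_u(x, y)
        assert res.method == "asymptotic"
        oracle = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.pvalue == pytest.approx(float(oracle.pvalue), abs=1e-12)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(0, 1, 5), rng.normal(1, 1, 6)
        assert mann_whitney_u(x, y).pvalue == pytest.approx(
            mann_whitney_u(y, x).pvalue, abs=1e-12)


class TestSummaryTTest:
    def test_equal_means(self):
        res = summary_ttest(5.0, 1.0, 5, 5.0, 1.0, 5)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_published_branch_length_row(self):
        # 167 +/- 15 vs 96.8 +/- 13, n = 5 per group
        res = summary_ttest(167.0, 15.0, 5, 96.8, 13.0, 5)
        assert res.statistic == pytest.approx(3.537, abs=0.001)
        assert res.df == 8
        assert res.pvalue == pytest.approx(0.0077, abs=0.0005)

    def test_identity_with_sample_t_for_balanced_groups(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(10, 2, 7), rng.normal(12, 3, 7)
        direct = student_t_two_sample(x, y)
        summary = summary_ttest(
            x.mean(), x.std(ddof=1) / math.sqrt(7), 7,
            y.mean(), y.std(ddof=1) / math.sqrt(7), 7)
        assert summary.statistic == pytest.approx(direct.statistic, abs=1e-12)
        assert summary.pvalue == pytest.approx(direct.pvalue, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            summary_ttest(1.0, 0.0, 5, 2.0, 1.0, 5)
        with pytest.raises(ValueError):
            summary_ttest(1.0, 1.0, 1, 2.0, 1.0, 5)


class TestCompareParameter:
    def test_gaussian_groups_use_t(self):
        rng = np.random.default_rng(0)
        wt = GroupSample("WT", "radius", tuple(rng.normal(34, 2, 8)))
        mut = GroupSample("NL3", "radius", tuple(rng.normal(23, 2, 8)))
        res = compare_parameter(wt, mut)
        assert res.test_used == "student_t"
        assert res.significant and res.stars in ("*", "**")

    def test_skewed_group_uses_mann_whitney(self):
        rng = np.random.default_rng(7)
        wt = GroupSample("WT", "x", tuple(np.exp(rng.normal(0, 1.5, 40))))
        mut = GroupSample("NL3", "x", tuple(rng.normal(5, 1, 40)))
        res = compare_parameter(wt, mut)
        assert res.test_used == "mann_whitney"
        assert not res.normal_wt

    def test_small_groups_fall_back_with_warning(self):
        wt = GroupSample("WT", "x", (1.0, 2.0, 3.0))
        mut = GroupSample("NL3", "x", (2.0, 3.0, 4.0))
        with pytest.warns(UserWarning, match="normality is untestable"):
            res = compare_parameter(wt, mut)
        assert res.test_used == "student_t"

    def test_parameter_mismatch(self):
        with pytest.raises(ValueError, match="parameter mismatch"):
            compare_parameter(GroupSample("WT", "a", (1.0, 2.0, 3.0, 4.0)),
                              GroupSample("NL3", "b", (1.0, 2.0, 3.0, 4.0)))

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(21)
        hits = 0
        reps = 400
        for _ in range(reps):
            wt = GroupSample("WT", "x", tuple(rng.normal(10, 2, 5)))
            mut = GroupSample("NL3", "x", tuple(rng.normal(10, 2, 5)))
            hits += compare_parameter(wt, mut).significant
        assert hits / reps == pytest.approx(0.05, abs=0.03)

    def test_p_in_unit_interval_and_swap_invariant(self):
        rng = np.random.default_rng(30)
        for _ in range(20):
            a = tuple(rng.normal(0, 1, 6))
            b = tuple(rng.normal(rng.uniform(-2, 2), 1, 6))
            r1 = compare_parameter(GroupSample("WT", "x", a), GroupSample("NL3", "x", b))
            r2 = compare_parameter(GroupSample("WT", "x", b), GroupSample("NL3", "x", a))
            assert 0.0 <= r1.p_two_tailed <= 1.0
            assert r1.p_two_tailed == pytest.approx(r2.p_two_tailed, abs=1e-9)


class TestDensitometry:
    def test_identical_lanes(self):
        rows = [dict(blot_id="b1", lane=f"l{i}", genotype=g,
                     target_intensity=500.0, actin_intensity=1000.0)
                for i, g in enumerate(["WT"] * 3 + ["NL3"] * 3)]
        norm, comp = densitometry_percent(pd.DataFrame(rows))
        assert (norm["percent_of_wt"] == 100.0).all()
        assert comp.loc[0, "p_two_tailed"] == 1.0

    def test_wt_mean_always_100(self):
        for seed in range(5):
            tab = gm.make_densitometry_table(rng_seed=seed, n_blots=2,
                                             effect=0.4 + 0.2 * seed)
            norm, _ = densitometry_percent(tab)
            wt = norm.loc[norm["genotype"] == "WT", "percent_of_wt"]
            assert wt.mean() == pytest.approx(100.0, abs=1e-9)

    def test_planted_effect_recovered(self):
        tab = gm.make_densitometry_table(rng_seed=77, effect=0.67, n_blots=3)
        norm, comp = densitometry_percent(tab)
        assert comp.loc[0, "mut_mean"] == pytest.approx(67.0, abs=8.0)

    def test_missing_actin_names_lane(self):
        tab = gm.make_densitometry_table(rng_seed=0)
        tab.loc[2, "actin_intensity"] = 0.0
        with pytest.raises(ValueError, match=str(tab.loc[2, "lane"])):
            densitometry_percent(tab)

    def test_wt_only_lanes_no_test(self):
        tab = gm.make_densitometry_table(rng_seed=0, n_mut=0)
        norm, comp = densitometry_percent(tab)
        assert norm["percent_of_wt"].mean() == pytest.approx(100.0)
        assert np.isnan(comp.loc[0, "p_two_tailed"])
        assert comp.loc[0, "significance"] == ""

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="lacks columns"):
            densitometry_percent(pd.DataFrame({"lane": ["a"]}))


def test_significance_stars_convention():
    assert significance_stars(0.2) == "NS"
    assert significance_stars(0.049) == "*"
    assert significance_stars(0.009) == "**"
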