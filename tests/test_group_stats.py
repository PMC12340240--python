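"""Rank statistics, FDR, the discrimination criterion and power curves."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from bsdti.group_stats import (METRICS, bh_fdr, chi_square_2x2, compare_groups,
                               discrimination_report, group_size_curve,
                               mann_whitney, wilcoxon_paired)


class TestMannWhitney:
    def test_identical_groups_are_null(self):
        x = np.arange(10.0)
        u, z, p, r = mann_whitney(x, x)
        assert p > 0.9 and r < 0.1

    def test_complete_separation_gives_extreme_u(self):
        u, z, p, r = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert u == 0.0
        assert z < 0 and r > 0.7

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(size=rng.integers(5, 30))
            b = rng.normal(0.3, size=rng.integers(5, 30))
            u, z, p, r = mann_whitney(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic")
            assert np.isclose(u, ref.statistic)
            assert np.isclose(p, ref.pvalue, rtol=1e-10)

    def test_tie_correction_matches_scipy(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 4, 25).astype(float)
        b = rng.integers(1, 5, 20).astype(float)
        _, _, p, _ = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert np.isclose(p, ref.pvalue, rtol=1e-10)

    def test_constant_data_degenerates_to_null(self):
        u, z, p, r = mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0 and r == 0.0

    def test_power_matches_exact_statistic_oracle(self):
        """Asymptotic rejection rate tracks the exact-distribution test."""
        rng = np.random.default_rng(7)
        n, alpha, reps = 50, 0.005, 400
        rej_approx = rej_exact = 0
        for _ in range(reps):
            a = rng.normal(0.0, 1.0, n)
            b = rng.normal(1.0, 1.0, n)
            _, _, p, _ = mann_whitney(a, b)
            rej_approx += p < alpha
            p_ex = sps.mannwhitneyu(a, b, alternative="two-sided",
                                    method="exact").pvalue
            rej_exact += p_ex < alpha
        assert abs(rej_approx - rej_exact) / reps <= 0.03


class TestWilcoxon:
    def test_equal_pairs_are_null(self):
        x = np.arange(12.0)
        w, z, p, r = wilcoxon_paired(x, x)
        assert p == 1.0 and r == 0.0

    def test_constant_positive_shift_dominates(self):
        x = np.linspace(0, 1, 30)
        w, z, p, r = wilcoxon_paired(x + 1.0, x)
        assert p < 0.001 and r > 0.5

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=25)
        y = x + rng.normal(0.2, 0.5, size=25)
        _, z1, p1, r1 = wilcoxon_paired(x, y)
        _, z2, p2, r2 = wilcoxon_paired(y, x)
        assert np.isclose(p1, p2) and np.isclose(z1, -z2) and np.isclose(r1, r2)

    def test_approximation_validated_by_exact_enumeration(self):
        """n=10: enumerate all 2^10 sign patterns for the exact null p."""
        rng = np.random.default_rng(3)
        d = rng.normal(0.4, 1.0, 10)
        d = d[d != 0]
        n = d.size
        w_obs = sps.wilcoxon(d, method="approx").statistic
        ranks = sps.rankdata(np.abs(d))
        w_plus = ranks[d > 0].sum()
        total = ranks.sum()
        stat_obs = min(w_plus, total - w_plus)
        count = 0
        for signs in itertools.product([0, 1], repeat=n):
            wp = sum(r for s, r in zip(signs, ranks) if s)
            if min(wp, total - wp) <= stat_obs:
                count += 1
        p_exact = count / 2 ** n
        _, _, p_approx, _ = wilcoxon_paired(d, np.zeros(n))
        # the normal approximation is good to a few percent at n=10
        assert abs(p_approx - p_exact) < 0.08
        assert np.isclose(p_approx,
                          sps.wilcoxon(d, correction=False, method="approx").pvalue,
                          rtol=1e-10)


class TestChiSquare:
    def test_demographic_sex_table_is_null(self):
        chi2, p = chi_square_2x2([[16, 34], [15, 35]])
        assert round(p, 1) == 1.0

    def test_equal_rows_give_zero_statistic(self):
        chi2, p = chi_square_2x2([[12, 30], [12, 30]])
        assert chi2 == 0.0 and p == 1.0

    def test_perfect_association_is_extreme(self):
        chi2, p = chi_square_2x2([[50, 0], [0, 50]])
        # Yates-corrected closed form: N(|ad-bc|-N/2)^2 / (row/col products)
        expected = 100 * (2500 - 50) ** 2 / 50 ** 4
        assert np.isclose(chi2, expected)
        assert p < 1e-15

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2([[0, 0], [5, 5]])

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(np.array([[1.5, 2.0], [3.0, 4.0]]))


def _bh_oracle(p):
    """Step-up definition: sort, scale by m/rank, cumulative min, clip."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_brute_force_definition(self, ps):
        np.testing.assert_allclose(bh_fdr(ps), _bh_oracle(ps), rtol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=100)
        assert np.all(bh_fdr(p) >= p - 1e-15)


def _synthetic_summary(n_rois=20, n_per_group=15, effect=0.0, seed=0):
    """Tidy ROI summary with a known standardized group effect on MD/RD."""
    rng = np.random.default_rng(seed)
    rows = []
    for grp, shift in (("HC", 0.0), ("MS", effect)):
        for s in range(n_per_group):
            sid = f"{grp}{s}"
            for roi in range(1, n_rois + 1):
                base = rng.normal(shift, 1.0)
                for metric in METRICS:
                    rows.append({"subject": sid, "group": grp,
                                 "roi": str(roi), "metric": metric,
                                 "mean": base + 0.1 * rng.normal()})
    return pd.DataFrame(rows)


class TestDiscrimination:
    def test_saturated_effect_flags_every_roi(self):
        summ = _synthetic_summary(n_rois=10, n_per_group=20, effect=5.0, seed=1)
        rep = discrimination_report(summ)
        assert np.allclose(rep["ANY"], 100.0)

    def test_null_cohort_flags_almost_nothing(self):
        summ = _synthetic_summary(n_rois=25, n_per_group=20, effect=0.0, seed=2)
        rep = discrimination_report(summ)
        assert rep["ANY"].iloc[0] <= 8.0

    def test_any_dominates_metrics_and_large_below_medium(self):
        summ = _synthetic_summary(n_rois=15, n_per_group=12, effect=1.0, seed=3)
        rep = discrimination_report(summ).set_index("threshold")
        for thr in (0.3, 0.5):
            assert all(rep.loc[thr, "ANY"] >= rep.loc[thr, m] for m in METRICS)
        assert rep.loc[0.5, "ANY"] <= rep.loc[0.3, "ANY"]

    def test_missing_metric_is_named(self):
        summ = _synthetic_summary(n_rois=5, n_per_group=8, seed=4)
        summ = summ[summ.metric != "RD"]
        with pytest.raises(ValueError, match="RD"):
            discrimination_report(summ)

    def test_fdr_column_dominates_raw(self):
        summ = _synthetic_summary(n_rois=10, n_per_group=10, effect=0.5, seed=5)
        table = compare_groups(summ)
        assert np.all(table["p_fdr"] >= table["p"] - 1e-15)


def _region_summary(effect, n=20, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for grp, shift in (("HC", 0.0), ("MS", effect)):
        for s in range(n):
            rows.append({"subject": f"{grp}{s}", "group": grp, "roi": "WB",
                         "metric": "MD", "mean": rng.normal(shift, 1.0)})
    return pd.DataFrame(rows)


class TestGroupSizeCurve:
    def test_full_cohort_single_resample_equals_direct_test(self):
        summ = _region_summary(effect=1.0, n=15, seed=6)
        curve = group_size_curve(summ, "WB", "MD", sizes=[15], n_resamples=1)
        va = summ[summ.group == "HC"]["mean"].to_numpy()
        vb = summ[summ.group == "MS"]["mean"].to_numpy()
        _, _, p, _ = mann_whitney(va, vb)
        assert np.isclose(curve["p_median"].iloc[0], p)

    def test_null_median_near_half(self):
        summ = _region_summary(effect=0.0, n=30, seed=7)
        curve = group_size_curve(summ, "WB", "MD", sizes=[10, 20],
                                 n_resamples=60, seed=1)
        assert np.all(curve["p_median"].between(0.15, 0.85))

    def test_oversized_request_rejected(self):
        summ = _region_summary(effect=0.0, n=10, seed=8)
        with pytest.raises(ValueError, match="exceeds"):
            group_size_curve(summ, "WB", "MD", sizes=[11])
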