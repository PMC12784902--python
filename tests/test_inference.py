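"""ANOVA, Kruskal-Wallis, Mann-Whitney and BH adjustment oracles."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from turnvar import anova_bias, bh_adjust, kruskal_activity, mann_whitney_u
from turnvar.inference import pairwise_activity_tests


def kw_rank_oracle(groups):
    """Brute-force tie-corrected Kruskal-Wallis H from first principles."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)  # average ranks for ties
    n = len(pooled)
    offsets = np.cumsum([0] + [len(g) for g in groups])
    h = 0.0
    for i, g in enumerate(groups):
        r = ranks[offsets[i]: offsets[i + 1]]
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


def mwu_exact_oracle(a, b):
    """Exact two-sided MWU p by enumerating all label assignments."""
    pooled = np.concatenate([a, b])
    na, n = len(a), len(pooled)
    u_obs = sum(x > y for x in a for y in b)
    nm = na * (n - na)
    u_low = min(u_obs, nm - u_obs)
    us = []
    for idx in combinations(range(n), na):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        us.append(sum(x > y for x in pooled[mask] for y in pooled[~mask]))
    us = np.asarray(us)
    return np.mean((us <= u_low) | (us >= nm - u_low))


class TestAnova:
    def test_hand_computed_fixture(self):
        # SSB = 13.5, SSW = 4, MSW = 1 -> F = 13.5 on (1, 4) df
        res = anova_bias({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        assert res.statistic == pytest.approx(13.5)
        assert (res.df1, res.df2) == (1, 4)
        assert res.p_value == pytest.approx(sps.f.sf(13.5, 1, 4))

    def test_identical_groups_give_zero_f(self):
        res = anova_bias({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]})
        assert res.statistic == pytest.approx(0.0)

    def test_two_group_f_equals_squared_t(self, rng):
        for _ in range(5):
            a, b = rng.normal(size=12), rng.normal(0.4, 1.2, size=9)
            res = anova_bias({"a": a, "b": b})
            t = sps.ttest_ind(a, b, equal_var=True).statistic
            assert res.statistic == pytest.approx(t**2, rel=1e-10)

    def test_relabeling_leaves_f_unchanged(self, rng):
        a, b, c = rng.normal(size=8), rng.normal(size=8), rng.normal(size=8)
        r1 = anova_bias({"a": a, "b": b, "c": c})
        r2 = anova_bias({"x": c, "y": a, "z": b})
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_diagnostics_attached(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        res = anova_bias({"a": a, "b": b})
        assert set(res.diagnostics) == {"shapiro_stat", "shapiro_p", "levene_stat", "levene_p"}
        # the homoscedasticity diagnostic is the median-centered (Brown-Forsythe) form
        lv = sps.levene(a, b, center="median")
        assert res.diagnostics["levene_stat"] == pytest.approx(lv.statistic)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="sizes"):
            anova_bias({"a": [1.0], "b": [2.0, 3.0]})


class TestKruskal:
    def test_printed_fixture(self):
        res = kruskal_activity([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        assert res.statistic == pytest.approx(32.0 / 7.0)  # 4.571...
        assert res.df1 == 2
        assert res.p_value == pytest.approx(sps.chi2.sf(32.0 / 7.0, 2))

    def test_identical_multisets_give_zero_h(self):
        res = kruskal_activity([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_values_return_h0_p1(self):
        res = kruskal_activity([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_tie_correction_matches_rank_oracle(self, rng):
        for _ in range(20):
            groups = [rng.choice([1.0, 2.0, 3.0, 4.0], size=rng.integers(2, 5))
                      for _ in range(3)]
            pooled = np.concatenate(groups)
            if np.all(pooled == pooled[0]):
                continue
            res = kruskal_activity(groups)
            assert res.statistic == pytest.approx(kw_rank_oracle(groups), rel=1e-10)

    def test_invariant_to_monotone_transform(self, rng):
        groups = [rng.random(6), rng.random(8) + 0.2, rng.random(5)]
        h1 = kruskal_activity(groups).statistic
        h2 = kruskal_activity([np.exp(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2, rel=1e-12)


class TestMannWhitney:
    def test_complete_separation_fixture(self):
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 assignments as extreme

    def test_identical_lists_sit_at_the_midpoint(self):
        u, _ = mann_whitney_u([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert u == pytest.approx(8.0)  # n_a * n_b / 2

    def test_swap_antisymmetry(self, rng):
        a, b = rng.random(7), rng.random(5)
        u1, p1 = mann_whitney_u(a, b)
        u2, p2 = mann_whitney_u(b, a)
        assert u1 + u2 == pytest.approx(len(a) * len(b))
        assert p1 == pytest.approx(p2)

    def test_exact_branch_matches_enumeration(self, rng):
        for na in range(2, 7):
            for nb in range(2, 7):
                a = rng.random(na)
                b = rng.random(nb) + rng.normal(0, 0.5)
                _, p = mann_whitney_u(a, b)
                assert p == pytest.approx(mwu_exact_oracle(a, b), abs=1e-12)

    def test_exact_and_asymptotic_agree_at_n8(self, rng):
        for _ in range(5):
            a, b = rng.random(8), rng.random(8) + 0.1
            _, p_exact = mann_whitney_u(a, b)  # tie-free n=8 takes the exact branch
            p_asym = sps.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic").pvalue
            assert abs(p_exact - p_asym) <= 0.02

    def test_invariant_to_monotone_transform(self, rng):
        a, b = rng.random(10), rng.random(12)
        _, p1 = mann_whitney_u(a, b)
        _, p2 = mann_whitney_u(np.log(a + 1), np.log(b + 1))
        assert p1 == pytest.approx(p2)


class TestBHAdjust:
    def test_hand_step_up_example(self):
        # m*p/rank = (0.03, 0.06, 0.045); cumulative min from the top reordered
        out = bh_adjust([0.01, 0.04, 0.03])
        assert out == pytest.approx([0.03, 0.04, 0.04])

    def test_singleton_identity(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([0.1, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_step_up_properties(self, ps):
        out = np.asarray(bh_adjust(ps))
        p = np.asarray(ps)
        assert np.all(out >= p - 1e-12)
        assert np.all(out <= 1.0 + 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(out[order]) >= -1e-12)  # monotone in sorted order

    def test_fdr_controlled_under_uniform_nulls(self, rng):
        # all-null simulation: empirical FDR at alpha=0.05 stays near/below alpha
        alpha, m, n_rep = 0.05, 3, 1000
        fdr = 0.0
        for _ in range(n_rep):
            q = bh_adjust(rng.random(m))
            rejected = np.sum(q <= alpha)
            fdr += (rejected > 0)  # all rejections are false here
        fdr /= n_rep
        assert fdr <= 0.064


class TestPairwiseActivity:
    def test_family_of_three_pairs(self, rng):
        groups = {"a": rng.random(20), "b": rng.random(20) + 0.3, "c": rng.random(20)}
        out = pairwise_activity_tests(groups)
        assert len(out) == 3
        assert (out["p_adjusted"] >= out["p_raw"] - 1e-12).all()
        assert (out["method"] == "mann_whitney_bh").all()
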