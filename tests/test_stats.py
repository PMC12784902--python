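"""MAD statistic, permutation test, bootstrap: oracles and invariants."""

import statistics
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import median_abs_deviation

from turnvar import (
    bootstrap_mad,
    group_mad,
    perm_test_mad,
    sample_bias,
    summarize_flies,
)
from turnvar.stats import pairwise_mad_tests, per_fly_choice_mad

from conftest import make_events


def mad_oracle(values):
    """Direct-enumeration MAD oracle built on statistics.median only."""
    med = statistics.median(values)
    return statistics.median([abs(v - med) for v in values])


def exhaustive_perm_p(a, b, alternative="two_sided"):
    """Exact permutation p over all label assignments of the pooled sample."""
    pooled = np.concatenate([a, b])
    na, n = len(a), len(pooled)
    obs = group_mad(a) - group_mad(b)
    stats = []
    for idx_a in combinations(range(n), na):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx_a)] = True
        stats.append(group_mad(pooled[mask]) - group_mad(pooled[~mask]))
    stats = np.asarray(stats)
    if alternative == "two_sided":
        return np.mean(np.abs(stats) >= abs(obs) - 1e-12)
    if alternative == "less":
        return np.mean(stats <= obs + 1e-12)
    return np.mean(stats >= obs - 1e-12)


class TestGroupMad:
    def test_zero_dispersion(self):
        assert group_mad([0.5, 0.5, 0.5]) == 0.0

    def test_worked_example(self):
        # median 0.5, deviations (0.3, 0, 0, 0.3, 0.4) -> median 0.3
        assert group_mad([0.2, 0.5, 0.5, 0.8, 0.9]) == pytest.approx(0.3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            group_mad([])

    def test_matches_enumeration_oracle_and_scipy(self, rng):
        # even/odd lengths and heavy ties; scipy (scale=1) as second oracle
        for _ in range(500):
            n = rng.integers(1, 30)
            vals = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=n) if rng.random() < 0.5 \
                else rng.random(n)
            x = vals.tolist()
            assert group_mad(x) == pytest.approx(mad_oracle(x), abs=1e-12)
            assert group_mad(x) == pytest.approx(median_abs_deviation(x, scale=1.0), abs=1e-12)

    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=40),
        st.floats(-100, 100),
        st.floats(0.01, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_location_invariance_and_scale_equivariance(self, xs, c, k):
        base = group_mad(xs)
        assert group_mad([x + c for x in xs]) == pytest.approx(base, abs=1e-6)
        assert group_mad([x * k for x in xs]) == pytest.approx(base * k, rel=1e-9, abs=1e-9)

    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=25), st.randoms())
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariant_nonnegative_zero_iff_majority_at_median(self, xs, rnd):
        shuffled = list(xs)
        rnd.shuffle(shuffled)
        m = group_mad(xs)
        assert group_mad(shuffled) == m
        assert m >= 0
        med = statistics.median(xs)
        majority_at_median = sum(x == med for x in xs) > len(xs) / 2
        assert (m == 0) == majority_at_median


class TestSummarizeFlies:
    def test_direct_proportion(self):
        ev = make_events({"f1": "RRLR"})
        s, _ = summarize_flies(ev, observation_minutes=120.0, min_turns=1)
        assert s.loc[0, "prop_right"] == pytest.approx(0.75)
        assert s.loc[0, "n_turns"] == 4

    def test_turns_per_min_is_count_over_minutes(self):
        ev = make_events({"f1": "RL" * 72})  # 144 events
        s, _ = summarize_flies(ev, observation_minutes=120.0, min_turns=1)
        assert s.loc[0, "turns_per_min"] == pytest.approx(1.2)

    def test_zero_event_fly_excluded_with_reason(self):
        ev = make_events({"f1": "RRLL"})
        roster = pd.DataFrame(
            {"fly_id": ["f1", "f2"], "treatment": ["g", "g"]}
        )
        s, excluded = summarize_flies(ev, min_turns=1, roster=roster)
        assert s["fly_id"].tolist() == ["f1"]
        assert excluded["fly_id"].tolist() == ["f2"]
        assert excluded["reason"].tolist() == ["insufficient_turns"]

    def test_threshold_boundary(self):
        ev = make_events({"f1": "RRLL", "f2": "RL"})
        s, excluded = summarize_flies(ev, min_turns=3)
        assert s["fly_id"].tolist() == ["f1"]
        assert excluded["n_turns"].tolist() == [2]

    def test_duplicate_timestamps_rejected_with_rows(self):
        ev = make_events({"f1": "RRLL"})
        ev.loc[3, "time_s"] = ev.loc[2, "time_s"]
        with pytest.raises(ValueError, match=r"duplicate.*\[2, 3\]"):
            summarize_flies(ev, min_turns=1)

    def test_unknown_direction_code_rejected(self):
        ev = make_events({"f1": "RRLL"})
        ev.loc[1, "direction"] = "left"
        with pytest.raises(ValueError, match="left"):
            summarize_flies(ev, min_turns=1)

    def test_per_fly_choice_mad_is_degenerate_for_majorities(self):
        # a strict majority of one direction pins the within-fly MAD at zero,
        # which is why group-level dispersion uses prop_right instead
        assert per_fly_choice_mad(list("RRRL")) == 0.0
        assert per_fly_choice_mad(list("RRLL")) == 0.5
        ev = make_events({"f1": "RRRL"})
        s, _ = summarize_flies(ev, min_turns=1, include_choice_mad=True)
        assert s.loc[0, "choice_mad"] == 0.0


class TestPermTestMad:
    def test_exchangeable_null_on_identical_lists(self):
        vals = [0.1, 0.4, 0.45, 0.5, 0.55, 0.6, 0.9]
        res = perm_test_mad(vals, vals, n_iter=2000, seed=4)
        assert res.stat_observed == 0.0
        assert res.p_value > 0.5

    @pytest.mark.parametrize("na, nb", [(3, 3), (4, 3)])
    def test_monte_carlo_matches_exhaustive(self, rng, na, nb):
        a = rng.random(na)
        b = rng.random(nb) * 2.0
        p_ex = exhaustive_perm_p(a, b)
        res = perm_test_mad(a, b, n_iter=10_000, seed=8)
        se = np.sqrt(p_ex * (1 - p_ex) / 10_000)
        assert abs(res.p_value - p_ex) <= 3 * se + 2e-4

    def test_one_sided_alternatives_are_coherent(self, rng):
        a = sample_bias(0.5, 60.0, 80, rng)   # tight
        b = sample_bias(0.5, 8.0, 80, rng)    # loose
        less = perm_test_mad(a, b, n_iter=2000, alternative="less", seed=1)
        greater = perm_test_mad(a, b, n_iter=2000, alternative="greater", seed=1)
        assert less.stat_observed < 0
        assert less.p_value < 0.05 < greater.p_value

    def test_deterministic_given_seed(self, rng):
        a, b = rng.random(10), rng.random(12)
        r1 = perm_test_mad(a, b, n_iter=500, seed=9)
        r2 = perm_test_mad(a, b, n_iter=500, seed=9)
        assert r1 == r2

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            perm_test_mad([0.1], [0.2, 0.3], n_iter=10)

    def test_p_value_in_half_open_unit_interval(self, rng):
        a = rng.random(5) + 10.0  # wildly different dispersion scales
        b = rng.random(5) * 50.0
        res = perm_test_mad(a, b, n_iter=200, seed=0)
        assert 0.0 < res.p_value <= 1.0


class TestBootstrapMad:
    def test_degenerate_input_propagates_zeros(self):
        res = bootstrap_mad([0.4] * 10, n_boot=200, seed=0)
        assert (res.mad, res.boot_se, res.ci_low, res.ci_high) == (0.0, 0.0, 0.0, 0.0)

    def test_ci_brackets_the_point_estimate(self):
        res = bootstrap_mad([0.2, 0.5, 0.5, 0.8, 0.9], n_boot=5000, seed=1)
        assert res.ci_low <= res.mad <= res.ci_high
        assert res.mad == pytest.approx(0.3)

    def test_deterministic_given_seed(self, rng):
        vals = rng.random(30)
        assert bootstrap_mad(vals, n_boot=300, seed=3) == bootstrap_mad(vals, n_boot=300, seed=3)

    def test_coverage_of_population_mad(self):
        # population MAD of Beta(kappa=10) from a large one-off reference draw
        big = sample_bias(0.5, 10.0, 1_000_000, np.random.default_rng(123))
        pop_mad = group_mad(big)
        hits = 0
        n_rep = 300
        for seed in range(n_rep):
            sample = sample_bias(0.5, 10.0, 200, np.random.default_rng(1000 + seed))
            res = bootstrap_mad(sample, n_boot=800, seed=seed)
            hits += res.ci_low <= pop_mad <= res.ci_high
        assert hits / n_rep >= 0.90

    def test_too_few_resamples_rejected(self):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_mad([0.1, 0.2, 0.3], n_boot=50)


class TestPairwiseMadTests:
    def test_three_groups_give_three_bh_adjusted_pairs(self, rng):
        rows = []
        for label, kappa in [("a", 10.0), ("b", 20.0), ("c", 40.0)]:
            for i, v in enumerate(sample_bias(0.5, kappa, 60, rng)):
                rows.append({"fly_id": f"{label}{i}", "treatment": label, "prop_right": v})
        summaries = pd.DataFrame(rows)
        out = pairwise_mad_tests(summaries, n_iter=500, seed=2)
        assert len(out) == 3
        assert (out["p_adjusted"] >= out["p_raw"] - 1e-12).all()
        assert set(zip(out["group_a"], out["group_b"])) == {("a", "b"), ("a", "c"), ("b", "c")}
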