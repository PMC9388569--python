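"""Rank/contingency statistics and survival analysis against independent oracles."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from gliomics.survival import (
    combined_low_group,
    dichotomize_expression,
    fisher_exact_2x2,
    km_estimate,
    logrank_test,
    wilcoxon_rank_sum,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def _wilcoxon_enumeration_oracle(x, y):
    """Exact two-sided p: enumerate every assignment of pooled ranks to x."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[:nx].sum()
    mean = nx * (n + 1) / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), nx):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total


def _fisher_enumeration_oracle(table):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k):
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


def _km_hand_oracle(times, events):
    """Product over risk sets, computed independently of the implementation."""
    records = sorted(zip(times, events))
    s = 1.0
    out = {}
    at_risk = len(records)
    i = 0
    while i < len(records):
        t = records[i][0]
        d = sum(1 for tt, ee in records if tt == t and ee)
        c = sum(1 for tt, ee in records if tt == t and not ee)
        if d:
            s *= 1 - d / at_risk
            out[t] = s
        at_risk -= d + c
        i += d + c
    return out


# ---------------------------------------------------------------------------
# Wilcoxon
# ---------------------------------------------------------------------------


class TestWilcoxon:
    def test_fully_separated_small_samples(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_samples_give_p_near_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_matches_enumeration_oracle_on_random_tie_free_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            nx, ny = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            x = rng.normal(size=nx)
            y = rng.normal(size=ny)
            _, p = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(_wilcoxon_enumeration_oracle(x, y), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# Fisher
# ---------------------------------------------------------------------------


class TestFisher:
    def test_symmetric_table(self):
        odds, p = fisher_exact_2x2([[5, 5], [5, 5]])
        assert odds == 1.0 and p == 1.0

    def test_diagonal_table(self):
        odds, p = fisher_exact_2x2([[3, 0], [0, 3]])
        assert odds == float("inf")
        assert p == pytest.approx(0.1)  # 2 * 1/20

    def test_matches_enumeration_on_all_small_tables(self):
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        tab = [[a, b], [c, d]]
                        if (a + b == 0 or c + d == 0) or (a + c == 0 or b + d == 0):
                            continue  # degenerate margins: p = 1 by convention
                        _, p = fisher_exact_2x2(tab)
                        assert p == pytest.approx(_fisher_enumeration_oracle(tab), abs=1e-9), tab

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([5, 8, 12], [False, False, False])
        assert km.survival_at(100) == 1.0 and np.isnan(km.median)

    def test_single_death_among_four(self):
        km = km_estimate([2, 3, 4, 5], [True, False, False, False])
        assert km.survival_at(2) == pytest.approx(3 / 4)

    def test_mixed_case_matches_hand_oracle(self):
        times = [1, 2, 2, 3, 4, 5, 6, 6, 7]
        events = [True, True, False, True, False, True, True, False, True]
        km = km_estimate(times, events)
        oracle = _km_hand_oracle(times, events)
        for t, s in oracle.items():
            assert km.survival_at(t) == pytest.approx(s)

    def test_monotone_nonincreasing_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(1, 40))
            km = km_estimate(rng.exponential(10, n), rng.random(n) < 0.7)
            s = km.table["survival"].to_numpy()
            assert (np.diff(s) <= 1e-12).all()
            assert ((s >= 0) & (s <= 1)).all()

    def test_against_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(9)
        t = rng.exponential(10, 50)
        e = rng.random(50) < 0.6
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for q in np.quantile(t, [0.2, 0.5, 0.8]):
            assert km.survival_at(q) == pytest.approx(float(kmf.predict(q)), abs=1e-9)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([0.0, 1.0], [True, True])


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------


class TestLogrank:
    def test_identical_groups_give_null(self):
        t = [1, 2, 3, 4, 5]
        e = [True, True, False, True, True]
        res = logrank_test(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_small_case_matches_hand_tabulated_oe_v(self):
        # A: deaths at 1, 3; B: death at 2, censored at 4
        ta, ea = [1, 3], [True, True]
        tb, eb = [2, 4], [True, False]
        # time 1: nA=2,nB=2,d=1 -> E=0.5, V=1*(2/4)*(2/4)*(3/3)=0.25
        # time 2: nA=1,nB=2,d=1 -> E=1/3, V=(1/3)*(2/3)*(1)=2/9
        # time 3: nA=1,nB=1,d=1 -> E=0.5, V=0.25
        o, ex, v = 2.0, 0.5 + 1 / 3 + 0.5, 0.25 + 2 / 9 + 0.25
        res = logrank_test(ta, ea, tb, eb)
        assert res.observed_a == pytest.approx(o)
        assert res.expected_a == pytest.approx(ex)
        assert res.variance == pytest.approx(v)
        assert res.statistic == pytest.approx((o - ex) ** 2 / v)

    def test_symmetric_under_group_exchange(self):
        rng = np.random.default_rng(2)
        ta, tb = rng.exponential(10, 30), rng.exponential(20, 25)
        ea, eb = rng.random(30) < 0.8, rng.random(25) < 0.8
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_against_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(4)
        ta, tb = rng.exponential(10, 40), rng.exponential(25, 35)
        ea, eb = rng.random(40) < 0.7, rng.random(35) < 0.7
        mine = logrank_test(ta, ea, tb, eb)
        theirs = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert mine.statistic == pytest.approx(theirs.test_statistic, rel=1e-9)
        assert mine.p_value == pytest.approx(theirs.p_value, rel=1e-9)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="zero events"):
            logrank_test([1, 2], [False, False], [3], [False])

    def test_null_rejection_rate_bounded(self):
        """With identical generating distributions the test rejects at <= alpha + 2 SE."""
        rng = np.random.default_rng(17)
        alpha, reps = 0.05, 400
        rejections = 0
        for _ in range(reps):
            t1, t2 = rng.exponential(10, 40), rng.exponential(10, 40)
            rejections += logrank_test(t1, np.ones(40, bool), t2, np.ones(40, bool)).p_value < alpha
        assert rejections / reps <= alpha + 2 * np.sqrt(alpha * (1 - alpha) / reps)


# ---------------------------------------------------------------------------
# dichotomization and the combined low/low group
# ---------------------------------------------------------------------------


class TestDichotomize:
    def test_mean_mode(self):
        eg = dichotomize_expression(pd.Series({"a": 7.0, "b": 9.0}), "mean")
        assert eg.cutoff == 8.0
        assert eg.labels.tolist() == ["low", "high"]

    def test_value_equal_to_cutoff_is_high(self):
        eg = dichotomize_expression(pd.Series({"a": 7.8, "b": 5.0}), "fixed", fixed_cutoff=7.8)
        assert eg.labels["a"] == "high" and eg.labels["b"] == "low"

    def test_all_equal_values_all_high(self):
        eg = dichotomize_expression(pd.Series({"a": 5.0, "b": 5.0, "c": 5.0}), "mean")
        assert (eg.labels == "high").all()

    def test_combined_low_group(self):
        a = dichotomize_expression(pd.Series({"x": 1.0, "y": 9.0, "z": 1.0}), "fixed", 5.0, gene="A")
        b = dichotomize_expression(pd.Series({"x": 2.0, "y": 2.0, "z": 9.0}), "fixed", 5.0, gene="B")
        combo = combined_low_group(a, b)
        assert combo.tolist() == ["low/low", "other", "other"]

    def test_mismatched_case_sets_named_in_error(self):
        a = dichotomize_expression(pd.Series({"x": 1.0, "y": 2.0}), "fixed", 5.0, gene="A")
        b = dichotomize_expression(pd.Series({"x": 1.0, "q": 2.0}), "fixed", 5.0, gene="B")
        with pytest.raises(ValueError, match="q"):
            combined_low_group(a, b)
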