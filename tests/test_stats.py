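"""Statistical primitives: exact/approximate Mann-Whitney, Welch t,
Benjamini-Hochberg, and the two-sided Fisher exact test."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps

from clonodiff.errors import DataError
from clonodiff.stats import (
    ContingencyTable2x2,
    bh_adjust,
    fisher_exact_2x2,
    mann_whitney_u,
    welch_t,
)


def midranks(values):
    """Mid-ranks computed by hand (average rank of tied values)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def mwu_enumeration_oracle(x, y):
    """Exact two-sided Mann-Whitney p by brute-force enumeration of all
    C(m+n, m) assignments of the pooled mid-ranks to the x-group."""
    pooled = list(x) + list(y)
    m = len(x)
    ranks = midranks(pooled)
    offset = m * (m + 1) / 2.0
    u_obs = sum(ranks[:m]) - offset
    lower = upper = total = 0
    for combo in itertools.combinations(range(len(pooled)), m):
        u = sum(ranks[i] for i in combo) - offset
        total += 1
        lower += u <= u_obs + 1e-9
        upper += u >= u_obs - 1e-9
    return min(1.0, 2.0 * min(lower, upper) / total)


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(0.1)  # 2 / C(6,3)

    def test_single_observation_per_group(self):
        res = mann_whitney_u([1], [2])
        assert res.method == "exact"
        assert res.pvalue == 1.0

    def test_identical_groups_approximate_path(self):
        x = list(range(20))
        res = mann_whitney_u(x, x)
        assert res.method == "normal-approx"
        assert res.pvalue == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            mann_whitney_u([], [1.0])

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            m, n = rng.integers(1, 7, size=2)
            vals = rng.permutation(100)[: m + n].astype(float)
            x, y = vals[:m], vals[m:]
            res = mann_whitney_u(x, y)
            assert res.method == "exact"
            assert res.pvalue == pytest.approx(mwu_enumeration_oracle(x, y))

    def test_exact_midrank_path_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(19)
        for _ in range(100):
            m, n = rng.integers(2, 7, size=2)
            x = rng.integers(0, 5, size=m).astype(float)
            y = rng.integers(0, 5, size=n).astype(float)
            res = mann_whitney_u(x, y)
            assert res.method == "exact"
            assert res.pvalue == pytest.approx(mwu_enumeration_oracle(x, y))

    def test_exact_matches_scipy_exact(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            m, n = rng.integers(2, 8, size=2)
            vals = rng.permutation(1000)[: m + n].astype(float)
            x, y = vals[:m], vals[m:]
            expected = sps.mannwhitneyu(x, y, method="exact").pvalue
            assert mann_whitney_u(x, y).pvalue == pytest.approx(float(expected))

    def test_approximate_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            x = rng.integers(0, 6, size=15).astype(float)
            y = rng.integers(0, 6, size=15).astype(float)
            res = mann_whitney_u(x, y)
            assert res.method == "normal-approx"
            expected = sps.mannwhitneyu(
                x, y, method="asymptotic", use_continuity=True
            ).pvalue
            assert res.pvalue == pytest.approx(float(expected), rel=1e-9)

    def test_group_swap_leaves_p_unchanged(self):
        x, y = [1.0, 5.0, 9.0, 2.0], [3.0, 7.0, 8.0]
        assert mann_whitney_u(x, y).pvalue == pytest.approx(
            mann_whitney_u(y, x).pvalue
        )


class TestWelchT:
    def test_hand_computed_example(self):
        res = welch_t([40, 45, 50], [10, 15, 20])
        assert res.statistic == pytest.approx(7.348469, rel=1e-6)
        assert res.df == pytest.approx(4.0)
        assert res.pvalue == pytest.approx(0.00182626, rel=1e-5)

    def test_zero_variance_flagged_not_raised(self):
        res = welch_t([5.0, 5.0, 5.0], [5.0, 5.0])
        assert res.pvalue == 1.0
        assert res.zero_variance

    def test_swap_negates_statistic_keeps_p(self):
        a = welch_t([1.0, 2.0, 4.0], [5.0, 7.0, 8.0])
        b = welch_t([5.0, 7.0, 8.0], [1.0, 2.0, 4.0])
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.pvalue == pytest.approx(b.pvalue)

    def test_too_small_group_rejected(self):
        with pytest.raises(DataError):
            welch_t([1.0], [2.0, 3.0])


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.04], [0.04]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_step_up_examples(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(11)
        p = rng.random(50)
        assert bh_adjust(p) == pytest.approx(
            sps.false_discovery_control(p, method="bh")
        )

    def test_q_at_least_p_and_capped(self):
        rng = np.random.default_rng(5)
        p = rng.random(30)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.5])


def fisher_enumeration_oracle(a, b, c, d):
    """Independent two-sided Fisher p: cumulative sum over the support using
    log-factorials directly (no scipy hypergeom)."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lf = [0.0] * (n + 1)
    for i in range(2, n + 1):
        lf[i] = lf[i - 1] + math.log(i)

    def logp(k):
        a_, b_, c_, d_ = k, row1 - k, col1 - k, n - row1 - col1 + k
        return (
            lf[row1] + lf[n - row1] + lf[col1] + lf[n - col1]
            - lf[n] - lf[a_] - lf[b_] - lf[c_] - lf[d_]
        )

    k_min = max(0, col1 - (n - row1))
    k_max = min(row1, col1)
    p_obs = logp(a)
    total = 0.0
    for k in range(k_min, k_max + 1):
        lp = logp(k)
        if lp <= p_obs + 1e-7:
            total += math.exp(lp)
    return min(1.0, total)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((43, 26, 11, 8), 0.793),   # objective response by arm
            ((5, 5, 5, 5), 1.0),
            ((10, 0, 0, 10), 2 / math.comb(20, 10)),
        ],
    )
    def test_reference_tables(self, table, expected):
        res = fisher_exact_2x2(ContingencyTable2x2(*table))
        assert res.pvalue == pytest.approx(expected, abs=5e-4)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(101)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 41, size=4)
            if a + b + c + d == 0:
                continue
            res = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            assert res.pvalue == pytest.approx(
                fisher_enumeration_oracle(int(a), int(b), int(c), int(d)),
                rel=1e-6,
            )

    def test_matches_scipy(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            a, b, c, d = (int(v) for v in rng.integers(0, 30, size=4))
            if a + b + c + d == 0:
                continue
            ours = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d)).pvalue
            ref = sps.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(float(ref), rel=1e-6)

    def test_invariant_under_row_and_column_swap(self):
        p1 = fisher_exact_2x2(ContingencyTable2x2(7, 3, 2, 9)).pvalue
        p2 = fisher_exact_2x2(ContingencyTable2x2(9, 2, 3, 7)).pvalue
        assert p1 == pytest.approx(p2)

    def test_odds_ratio_conventions(self):
        assert fisher_exact_2x2(ContingencyTable2x2(4, 2, 1, 3)).odds_ratio == (
            pytest.approx(6.0)
        )
        assert fisher_exact_2x2(ContingencyTable2x2(4, 0, 1, 3)).odds_ratio == (
            math.inf
        )

    def test_all_zero_table_rejected(self):
        with pytest.raises(DataError):
            ContingencyTable2x2(0, 0, 0, 0)

    def test_negative_cell_rejected(self):
        with pytest.raises(DataError):
            ContingencyTable2x2(-1, 2, 3, 4)
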