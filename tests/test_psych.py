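"""Ordinal effect sizes, rank tests, scalability and reliability."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu, rankdata

from catqol.psych import (
    AcceptabilityRecord,
    Verdict,
    classify_p,
    cliffs_delta,
    compare_groups,
    cronbach_alpha,
    loevinger_h,
    wilcoxon_rank_sum,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def delta_double_loop(x, y):
    gt = sum(1 for a in x for b in y if a > b)
    lt = sum(1 for a in x for b in y if a < b)
    return (gt - lt) / (len(x) * len(y))


def wilcoxon_enumeration(x, y):
    """Two-sided exact P by literal enumeration over pooled splits."""
    pooled = list(x) + list(y)
    ranks = rankdata(pooled)
    n1, n = len(x), len(pooled)
    mu = n1 * (n + 1) / 2
    obs = abs(sum(ranks[: n1]) - mu)
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        total += 1
        if abs(sum(ranks[i] for i in idx) - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


def h_pair_covmax(xi, xj):
    """Loevinger H_ij via covariance over maximum covariance given the
    marginals (comonotone coupling) — an independent derivation of the
    weighted-Guttman-error ratio."""
    cov = np.cov(xi, xj, ddof=0)[0, 1]
    covmax = np.mean(np.sort(xi) * np.sort(xj)) - np.mean(xi) * np.mean(xj)
    return cov / covmax


# ---------------------------------------------------------------------------
# Cliff's delta
# ---------------------------------------------------------------------------

class TestCliffsDelta:
    def test_identical_samples_give_zero(self):
        assert cliffs_delta([1, 2, 3], [1, 2, 3]).delta == 0.0

    def test_complete_dominance_gives_one(self):
        assert cliffs_delta([2, 3], [0, 1]).delta == 1.0

    def test_sixteen_pair_example(self):
        res = cliffs_delta([1, 1, 2, 3], [1, 2, 2, 2])
        assert res.delta == pytest.approx(delta_double_loop([1, 1, 2, 3], [1, 2, 2, 2]))

    def test_matches_pair_enumeration_on_random_instances(self, rng):
        for _ in range(200):
            x = rng.integers(0, 5, rng.integers(2, 15))
            y = rng.integers(0, 5, rng.integers(2, 15))
            assert cliffs_delta(x, y).delta == pytest.approx(delta_double_loop(x, y))

    @given(
        st.lists(st.integers(0, 4), min_size=2, max_size=20),
        st.lists(st.integers(0, 4), min_size=2, max_size=20),
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry_and_bounds(self, x, y):
        a, b = cliffs_delta(x, y), cliffs_delta(y, x)
        assert a.delta == pytest.approx(-b.delta)
        assert -1.0 <= a.ci_low <= a.delta <= a.ci_high <= 1.0

    def test_variance_estimator_calibrated(self, rng):
        # empirical sampling SD of delta vs the consistent SE estimate
        deltas, ses = [], []
        for _ in range(300):
            x = rng.integers(0, 5, 60) + (rng.random(60) < 0.3)
            y = rng.integers(0, 5, 50)
            r = cliffs_delta(x, y)
            deltas.append(r.delta)
            ses.append(r.se)
        assert np.std(deltas) == pytest.approx(np.mean(ses), rel=0.2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cliffs_delta([], [1])


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_identical_multisets_give_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_most_extreme_split_of_six(self):
        # most extreme of C(6,3)=20 equally likely splits, doubled -> 0.1
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_exact_branch_matches_enumeration(self, rng):
        for _ in range(40):
            n1, n2 = rng.integers(2, 7), rng.integers(2, 7)
            x = rng.integers(0, 4, n1)
            y = rng.integers(0, 4, n2)
            assert wilcoxon_rank_sum(x, y) == pytest.approx(
                wilcoxon_enumeration(x, y)
            )

    def test_approx_branch_matches_scipy(self, rng):
        for _ in range(25):
            x = rng.integers(0, 5, rng.integers(15, 60))
            y = rng.integers(0, 5, rng.integers(15, 60)) + rng.integers(0, 2)
            if len(x) + len(y) <= 20:
                continue
            expected = mannwhitneyu(x, y, method="asymptotic").pvalue
            assert wilcoxon_rank_sum(x, y) == pytest.approx(expected, rel=1e-10)

    def test_large_shift_detected(self, rng):
        x = rng.normal(1.0, 1, 200)
        y = rng.normal(0.0, 1, 200)
        assert wilcoxon_rank_sum(x, y) < 1e-6

    def test_constant_pooled_sample_warns_p_one(self):
        with pytest.warns(UserWarning):
            assert wilcoxon_rank_sum([2, 2, 2], [2, 2]) == 1.0


class TestVerdicts:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.001, Verdict.SIGNIFICANT),
            (0.0049, Verdict.SIGNIFICANT),
            (0.006, Verdict.SUGGESTIVE),
            (0.005, Verdict.SUGGESTIVE),
            (0.0499, Verdict.SUGGESTIVE),
            (0.05, Verdict.NULL),
            (0.9, Verdict.NULL),
        ],
    )
    def test_convention(self, p, expected):
        assert classify_p(p) is expected

    def test_compare_groups_combines_all_parts(self, rng):
        x = rng.integers(2, 5, 80)
        y = rng.integers(0, 3, 80)
        res = compare_groups(x, y)
        assert res.p_value is not None and res.verdict is not None
        assert res.delta > 0


# ---------------------------------------------------------------------------
# Mokken scalability
# ---------------------------------------------------------------------------

class TestLoevingerH:
    def test_perfect_double_monotone_scale_has_h_one(self):
        X = np.array([[0, 0], [1, 1], [2, 2], [0, 0], [1, 1], [2, 2]])
        assert loevinger_h(X).scale_h == pytest.approx(1.0)

    def test_independent_items_have_h_near_zero(self):
        rng = np.random.default_rng(11)
        X = rng.integers(0, 5, size=(5000, 4))
        assert abs(loevinger_h(X).scale_h) < 0.05

    def test_toy_matrix_matches_covmax_derivation(self):
        # 4 items x 10 respondents; pairwise H from the independent
        # cov/covmax formulation must agree with the Guttman-error ratio
        X = np.array(
            [
                [0, 1, 0, 1],
                [1, 1, 0, 0],
                [2, 2, 1, 1],
                [3, 2, 2, 1],
                [4, 3, 2, 2],
                [1, 0, 0, 0],
                [2, 1, 1, 1],
                [3, 3, 2, 2],
                [4, 4, 3, 2],
                [2, 2, 1, 0],
            ]
        )
        res = loevinger_h(X, item_labels=list("abcd"))
        # total-scale H via covmax oracle
        pairs = list(itertools.combinations(range(4), 2))
        cov = sum(np.cov(X[:, i], X[:, j], ddof=0)[0, 1] for i, j in pairs)
        covmax = sum(
            np.mean(np.sort(X[:, i]) * np.sort(X[:, j]))
            - X[:, i].mean() * X[:, j].mean()
            for i, j in pairs
        )
        assert res.scale_h == pytest.approx(cov / covmax)

    def test_pairwise_equivalence_random(self, rng):
        for _ in range(20):
            xi = rng.integers(0, 4, 60)
            xj = np.clip(xi + rng.integers(-2, 3, 60), 0, 3)
            X = np.column_stack([xi, xj])
            assert loevinger_h(X).scale_h == pytest.approx(h_pair_covmax(xi, xj))

    def test_invariant_under_row_and_column_permutation(self, rng):
        X = rng.integers(0, 4, size=(40, 4))
        base = loevinger_h(X, item_labels=list("abcd"))
        rows = rng.permutation(40)
        cols = [2, 0, 3, 1]
        perm = loevinger_h(X[rows][:, cols], item_labels=[list("abcd")[c] for c in cols])
        assert perm.scale_h == pytest.approx(base.scale_h)
        for label in "abcd":
            assert perm.item_h[label] == pytest.approx(base.item_h[label])

    def test_aisp_selects_coherent_scale(self):
        rng = np.random.default_rng(3)
        latent = rng.normal(0, 1.5, 400)
        good = np.clip(
            np.round(latent[:, None] + rng.normal(0, 0.8, (400, 3))), 0, 4
        ).astype(int)
        noise = rng.integers(0, 5, (400, 1))
        X = np.hstack([good, noise])
        res = loevinger_h(X, item_labels=["g1", "g2", "g3", "junk"])
        assert ("g1", "g2", "g3") in res.selected_scales
        assert all("junk" not in s for s in res.selected_scales)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            loevinger_h(np.zeros((2, 4), dtype=int))
        with pytest.raises(ValueError):
            loevinger_h(np.zeros((10, 1), dtype=int))


# ---------------------------------------------------------------------------
# Cronbach's alpha
# ---------------------------------------------------------------------------

class TestCronbachAlpha:
    def test_duplicated_column_gives_one(self):
        col = np.arange(10.0)
        assert cronbach_alpha(np.column_stack([col, col])).alpha == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 5, size=(5000, 4))
        assert abs(cronbach_alpha(X).alpha) < 0.05

    def test_toy_matrix_matches_hand_formula(self):
        X = np.array(
            [
                [3, 4, 3, 4],
                [2, 2, 3, 3],
                [4, 4, 4, 3],
                [1, 2, 1, 2],
                [3, 3, 2, 3],
                [4, 3, 4, 4],
            ],
            dtype=float,
        )
        # spreadsheet-style arithmetic, written out
        k = 4
        item_vars = [np.var(X[:, j], ddof=1) for j in range(k)]
        total_var = np.var(X.sum(axis=1), ddof=1)
        expected = k / (k - 1) * (1 - sum(item_vars) / total_var)
        assert cronbach_alpha(X).alpha == pytest.approx(expected)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin

        rng = np.random.default_rng(8)
        latent = rng.normal(0, 1, 200)
        X = latent[:, None] + rng.normal(0, 1, (200, 4))
        expected = pingouin.cronbach_alpha(data=pd.DataFrame(X))[0]
        assert cronbach_alpha(X).alpha == pytest.approx(expected, abs=1e-10)

    @given(st.floats(-10, 10))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_column_shift(self, c):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (30, 4)) + rng.normal(0, 1, 30)[:, None]
        shifted = X.copy()
        shifted[:, 2] += c
        assert cronbach_alpha(shifted).alpha == pytest.approx(cronbach_alpha(X).alpha)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.array([[1.0, 2.0], [2.0, 1.0]]))


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

class TestAcceptabilityRecord:
    def test_total_is_item_sum_and_bounded(self):
        r = AcceptabilityRecord("p1", "fixed_none", (4, 4, 4, 4))
        assert r.total == 16

    def test_item_range_enforced(self):
        with pytest.raises(ValueError):
            AcceptabilityRecord("p1", "fixed_none", (5, 0, 0, 0))

    def test_feedback_seconds_presence_tied_to_condition(self):
        with pytest.raises(ValueError):
            AcceptabilityRecord("p1", "fixed_none", (1, 1, 1, 1), feedback_seconds=10.0)
        with pytest.raises(ValueError):
            AcceptabilityRecord("p1", "cat_graphical", (1, 1, 1, 1), feedback_seconds=None)
        ok = AcceptabilityRecord("p1", "cat_graphical", (1, 1, 1, 1), feedback_seconds=12.5)
        assert ok.feedback_seconds == 12.5
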