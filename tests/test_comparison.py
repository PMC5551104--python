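import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coarsesdm import (area_ratio, compute_auc, predicted_area, relative_rank,
                       schoener_D, similarity_I,
                       threshold_min_training_presence, threshold_sens_eq_spec,
                       wilcoxon_signed_rank)


# ---------------------------------------------------------------------------
# brute-force oracles


def auc_oracle(pres, bg):
    wins = sum(1.0 if p > b else 0.5 if p == b else 0.0
               for p in pres for b in bg)
    return wins / (len(pres) * len(bg))


def ses_oracle(pres, bg):
    pres, bg = np.asarray(pres), np.asarray(bg)
    best, best_gap = None, np.inf
    for t in np.unique(np.r_[pres, bg]):
        gap = abs(np.mean(pres >= t) - np.mean(bg < t))
        if gap < best_gap - 1e-15:
            best, best_gap = t, gap
    return best


def rr_oracle(a, b):
    a, b = np.ravel(a), np.ravel(b)
    score = n_pairs = 0.0
    for i, j in itertools.combinations(range(a.size), 2):
        n_pairs += 1
        tie_a, tie_b = a[i] == a[j], b[i] == b[j]
        if tie_a and tie_b:
            score += 1.0
        elif tie_a or tie_b:
            score += 0.5
        elif (a[i] - a[j]) * (b[i] - b[j]) > 0:
            score += 1.0
    return score / n_pairs


def overlap_oracles(a, b):
    pa, pb = a / a.sum(), b / b.sum()
    D = 1.0 - 0.5 * np.abs(pa - pb).sum()
    I = 1.0 - 0.5 * ((np.sqrt(pa) - np.sqrt(pb)) ** 2).sum()
    return D, I


# ---------------------------------------------------------------------------


class TestAUC:
    def test_perfect_and_uninformative(self):
        assert compute_auc([0.9, 0.8], [0.1, 0.2]) == 1.0
        assert compute_auc([0.5, 0.5], [0.5, 0.5]) == 0.5

    def test_enumerated_pairs(self):
        assert compute_auc([0.9, 0.4], [0.5, 0.1]) == pytest.approx(0.75)

    def test_matches_oracle_and_monotone_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(rng.integers(2, 15))
            b = np.round(rng.random(rng.integers(2, 20)), 1)  # ties likely
            auc = compute_auc(p, b)
            assert auc == pytest.approx(auc_oracle(p, b), abs=1e-12)
            assert compute_auc(np.exp(5 * p), np.exp(5 * b)) == \
                pytest.approx(auc, abs=1e-12)


class TestThresholds:
    def test_min_training_presence(self):
        assert threshold_min_training_presence([0.3, 0.7, 0.5]) == 0.3
        assert threshold_min_training_presence([0.42]) == 0.42
        base = threshold_min_training_presence([0.3, 0.7])
        assert threshold_min_training_presence([0.3, 0.7, 0.1]) <= base

    def test_sens_eq_spec_enumerated(self):
        pres, bg = [0.9, 0.8, 0.2], [0.7, 0.3, 0.1]
        assert threshold_sens_eq_spec(pres, bg) == ses_oracle(pres, bg)

    def test_sens_eq_spec_matches_scan_oracle_on_fuzz(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            p = np.round(rng.random(rng.integers(2, 12)), 2)
            b = np.round(rng.random(rng.integers(2, 20)), 2)
            t = threshold_sens_eq_spec(p, b)
            gap = abs(np.mean(p >= t) - np.mean(b < t))
            best = min(abs(np.mean(p >= c) - np.mean(b < c))
                       for c in np.r_[p, b])
            assert gap == pytest.approx(best, abs=1e-12)
            assert t == ses_oracle(p, b)

    def test_separable_case_sens_equals_spec_one(self):
        t = threshold_sens_eq_spec([0.8, 0.9], [0.1, 0.2])
        assert np.mean(np.array([0.8, 0.9]) >= t) == 1.0
        assert np.mean(np.array([0.1, 0.2]) < t) == 1.0


class TestAreas:
    def test_hand_counts_and_extremes(self):
        g = np.array([0.1, 0.4, 0.6])
        assert predicted_area(g, 0.35) == 2
        assert predicted_area(g, 0.61) == 0
        assert predicted_area(g, 0.1) == 3

    def test_non_increasing_in_threshold(self):
        g = np.random.default_rng(2).random(100)
        areas = [predicted_area(g, t) for t in np.linspace(0, 1, 25)]
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_ratios(self):
        assert area_ratio(115, 100) == pytest.approx(1.15)
        assert area_ratio(100, 100) == 1.0
        with pytest.raises(ValueError):
            area_ratio(10, 0)


class TestOverlap:
    def test_identical_and_disjoint(self):
        g = np.random.default_rng(3).random(50)
        assert schoener_D(g, g) == pytest.approx(1.0)
        assert similarity_I(g, g) == pytest.approx(1.0)
        assert relative_rank(g, g) == 1.0
        a = np.array([1.0, 2.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 3.0, 1.0])
        assert schoener_D(a, b) == pytest.approx(0.0)
        assert similarity_I(a, b) == pytest.approx(0.0)

    def test_hand_values(self):
        a, b = np.array([0.5, 0.5]), np.array([1.0, 0.0])
        assert schoener_D(a, b) == pytest.approx(0.5)
        expect_I = 1.0 - 0.5 * ((np.sqrt(0.5) - 1.0) ** 2 + 0.5)
        assert similarity_I(a, b) == pytest.approx(expect_I)
        assert expect_I == pytest.approx(0.70710678, abs=1e-6)

    def test_symmetry_and_normalization_invariance(self):
        rng = np.random.default_rng(4)
        a, b = rng.random(40), rng.random(40)
        assert schoener_D(a, b) == pytest.approx(schoener_D(b, a), abs=1e-15)
        assert similarity_I(a, b) == pytest.approx(similarity_I(b, a), abs=1e-15)
        assert schoener_D(7.0 * a, b) == pytest.approx(schoener_D(a, b), abs=1e-12)

    def test_d_never_exceeds_i(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a, b = rng.random(30), rng.random(30)
            assert schoener_D(a, b) <= similarity_I(a, b) + 1e-12


class TestRelativeRank:
    def test_three_cell_example(self):
        assert relative_rank([1.0, 2.0, 3.0], [1.0, 3.0, 2.0]) == \
            pytest.approx(2.0 / 3.0)

    def test_reversed_ranking_is_zero(self):
        a = np.arange(10.0)
        assert relative_rank(a, a[::-1]) == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        for n, quantize in [(20, False), (50, True), (300, True), (120, False)]:
            a = rng.random(n)
            b = rng.random(n)
            if quantize:   # force plenty of ties
                a = np.round(a, 1)
                b = np.round(b, 1)
            assert relative_rank(a, b) == pytest.approx(rr_oracle(a, b),
                                                        abs=1e-12)

    def test_symmetric(self):
        rng = np.random.default_rng(7)
        a, b = np.round(rng.random(60), 1), rng.random(60)
        assert relative_rank(a, b) == relative_rank(b, a)


_grid_pair = st.integers(2, 25).flatmap(lambda n: st.tuples(
    st.lists(st.floats(1e-6, 1.0, allow_nan=False), min_size=n, max_size=n),
    st.lists(st.floats(1e-6, 1.0, allow_nan=False), min_size=n, max_size=n)))


class TestOverlapProperties:
    @given(_grid_pair)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounds_and_hellinger_l1_inequality(self, pair):
        a, b = np.asarray(pair[0]), np.asarray(pair[1])
        d, i = schoener_D(a, b), similarity_I(a, b)
        assert -1e-12 <= d <= 1 + 1e-12
        assert -1e-12 <= i <= 1 + 1e-12
        assert d <= i + 1e-12

    @given(_grid_pair)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_relative_rank_bounds_and_symmetry(self, pair):
        a, b = np.asarray(pair[0]), np.asarray(pair[1])
        rr = relative_rank(a, b)
        assert 0.0 <= rr <= 1.0
        assert rr == relative_rank(b, a)


class TestWilcoxon:
    def test_all_equal_pairs(self):
        stat, p = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_exact_six_positive_differences(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = a - np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        _, p = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(2.0 / 64.0)   # 0.03125

    def test_pair_order_invariance(self):
        rng = np.random.default_rng(8)
        a, b = rng.random(15), rng.random(15)
        perm = rng.permutation(15)
        assert wilcoxon_signed_rank(a, b)[1] == \
            pytest.approx(wilcoxon_signed_rank(a[perm], b[perm])[1])

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(9)
        a = rng.random(60)
        b = a + rng.normal(0.2, 0.1, size=60)
        _, p = wilcoxon_signed_rank(a, b)
        assert p < 0.001
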