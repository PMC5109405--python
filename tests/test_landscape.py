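"""Stable-pair mining, the binomial tail, and cross-set concordance."""

import math

import numpy as np
import pytest
from scipy.stats import binom

from reoresp.core import ExpressionMatrix
from reoresp.landscape import (
    binomial_upper_tail,
    cross_set_concordance,
    find_stable_pairs,
    hoeffding_log10_bound,
)

from conftest import brute_force_stable_pairs, make_matrix


class TestFindStablePairs:
    def test_single_sample_gives_total_order(self):
        m = make_matrix([[5.0], [3.0], [1.0]])
        stable = find_stable_pairs([m])
        assert stable.pairs == {("g1", "g2"), ("g1", "g3"), ("g2", "g3")}
        assert stable.n_pairs == 3

    def test_disagreeing_pair_absent_in_both_orientations(self):
        m = make_matrix([[5.0, 1.0], [3.0, 3.5]])
        stable = find_stable_pairs([m])
        assert not stable.has_pair("g1", "g2")
        assert not stable.has_pair("g2", "g1")

    def test_tie_disqualifies_at_full_support(self):
        m = make_matrix([[2.0, 2.0], [2.0, 1.0]])
        stable = find_stable_pairs([m])
        assert stable.n_pairs == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = make_matrix(rng.normal(size=(20, 10)))
        stable = find_stable_pairs([m])
        assert stable.pairs == brute_force_stable_pairs([m])

    @pytest.mark.parametrize("threshold", [0.8, 0.9])
    def test_partial_support_matches_oracle(self, threshold):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(size=(10, 12)))
        stable = find_stable_pairs([m], threshold)
        oracle = brute_force_stable_pairs([m], threshold)
        # below full support the oracle may keep both orientations of a
        # near-balanced pair; the implementation keeps the majority one
        assert stable.pairs <= oracle
        assert {frozenset(p) for p in stable.pairs} == {frozenset(p) for p in oracle}

    def test_monotone_transform_leaves_pairs_unchanged(self):
        rng = np.random.default_rng(4)
        a = make_matrix(rng.normal(size=(15, 6)), label="a")
        b = make_matrix(rng.normal(size=(15, 5)), label="b", prefix="t")
        base = find_stable_pairs([a, b])
        warped = ExpressionMatrix(
            np.exp(0.7 * b.values + 2.0), b.groups, "b_warped"
        )
        assert find_stable_pairs([a, warped]).pairs == base.pairs

    def test_restrict_commutes_with_mining(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.normal(size=(12, 8)))
        subset = ["g2", "g5", "g7", "g11"]
        mined_then_restricted = find_stable_pairs([m]).restrict(subset)
        restricted_then_mined = find_stable_pairs([m.restrict(subset)])
        assert mined_then_restricted.pairs == restricted_then_mined.pairs

    def test_sample_and_dataset_order_invariance(self):
        rng = np.random.default_rng(6)
        a = make_matrix(rng.normal(size=(10, 4)), label="a")
        b = make_matrix(rng.normal(size=(10, 3)), label="b", prefix="t")
        forward = find_stable_pairs([a, b])
        shuffled = a.select_samples(reversed(a.sample_ids))
        backward = find_stable_pairs([b, shuffled])
        assert forward.pairs == backward.pairs

    def test_pooled_equals_per_dataset_intersection_at_full_support(self):
        rng = np.random.default_rng(7)
        a = make_matrix(rng.normal(size=(12, 5)), label="a")
        b = make_matrix(rng.normal(size=(12, 6)), label="b", prefix="t")
        pooled = find_stable_pairs([a, b])
        intersected = find_stable_pairs([a]).intersect(find_stable_pairs([b]))
        assert pooled.pairs == intersected.pairs

    def test_rejects_bad_threshold_and_empty_intersection(self):
        m = make_matrix([[1.0], [2.0]])
        with pytest.raises(ValueError):
            find_stable_pairs([m], support_threshold=0.4)
        with pytest.raises(ValueError):
            find_stable_pairs([m], support_threshold=1.2)
        other = make_matrix([[1.0], [2.0]])
        other.values.index = ["h1", "h2"]
        with pytest.raises(ValueError):
            find_stable_pairs([m, other])


class TestBinomialTail:
    @pytest.mark.parametrize(
        "s, k, p_e, expected",
        [
            (0, 10, 0.5, 1.0),
            (1, 1, 0.5, 0.5),
            (8, 10, 0.5, 0.0546875),  # (C(10,8)+C(10,9)+C(10,10)) / 2^10
        ],
    )
    def test_exact_values(self, s, k, p_e, expected):
        assert binomial_upper_tail(s, k, p_e).p == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_scipy_where_representable(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            k = int(rng.integers(1, 500))
            s = int(rng.integers(0, k + 1))
            p_e = float(rng.uniform(0.05, 0.95))
            ours = binomial_upper_tail(s, k, p_e).p
            assert ours == pytest.approx(float(binom.sf(s - 1, k, p_e)), rel=1e-9)

    def test_non_increasing_in_s(self):
        values = [binomial_upper_tail(s, 40, 0.3).p for s in range(41)]
        assert all(a >= b - 1e-15 for a, b in zip(values, values[1:]))

    def test_hoeffding_bound_dominates_exact_tail(self):
        for s, k in [(60, 100), (900, 1000), (70, 120)]:
            exact = binomial_upper_tail(s, k, 0.5)
            assert hoeffding_log10_bound(s, k, 0.5) >= exact.log10_p

    def test_log_domain_survives_extreme_tails(self):
        tail = binomial_upper_tail(9_000_000, 10_000_000, 0.5)
        assert tail.p == 0.0  # underflow of a finite log value
        assert tail.log10_p < -1e5
        assert math.isfinite(tail.log10_p)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            binomial_upper_tail(5, 4, 0.5)
        with pytest.raises(ValueError):
            binomial_upper_tail(1, 4, 1.0)


class TestCrossSetConcordance:
    def test_identical_sets_fully_concordant(self):
        m = make_matrix([[5.0], [3.0], [1.0]])
        stable = find_stable_pairs([m])
        result = cross_set_concordance(stable, stable)
        assert result.score == 1.0
        assert result.k == stable.n_pairs

    def test_hand_computed_small_case(self):
        # 10 shared pairs, 8 concordant -> p = 56/1024
        rng = np.random.default_rng(9)
        m = make_matrix(rng.normal(size=(5, 1)))
        a = find_stable_pairs([m])
        flipped = m.values.copy()
        order = np.argsort(-m.values.iloc[:, 0].to_numpy())
        top_two = [m.values.index[order[0]], m.values.index[order[1]]]
        flipped.loc[top_two] = flipped.loc[top_two[::-1]].to_numpy()
        b = find_stable_pairs(
            [ExpressionMatrix(flipped, m.groups, "flipped")]
        )
        result = cross_set_concordance(a, b)
        assert result.k == 10
        # swapping adjacent top genes reverses exactly one of the ten pairs
        assert result.s == 9
        assert result.p_value == pytest.approx(11 / 1024)

    def test_no_shared_pairs_flagged_undefined(self):
        a = find_stable_pairs([make_matrix([[2.0], [1.0]])])
        c = make_matrix([[2.0], [1.0]])
        c.values.index = ["h1", "h2"]
        b = find_stable_pairs([c])
        result = cross_set_concordance(a, b)
        assert not result.defined
        assert result.p_value == 1.0
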