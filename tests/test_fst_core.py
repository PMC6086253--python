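"""Cultural F_ST estimators: exact identities, bounds, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cultscope import (
    cultural_fst,
    cultural_fst_corrected,
    fst_oracle,
    group_frequencies,
    pairwise_fst,
    permutation_test,
)
from cultscope.fst_core import GroupFrequencies, InsufficientGroupsError

from conftest import make_adoption


class TestGroupFrequencies:
    def test_counts_weights_and_grand_mean(self):
        m = make_adoption({"A": [1, 1, 0, 0], "B": [1, 0]})
        f = group_frequencies(m, "p1")
        assert f.group_ids == ("A", "B")
        assert f.n.tolist() == [4, 2]
        assert f.p.tolist() == [0.5, 0.5]
        assert f.w.tolist() == [4 / 6, 2 / 6]
        assert f.p_bar == pytest.approx(0.5)

    def test_missing_excluded_per_practice(self):
        m = make_adoption({"A": [1, None, 0], "B": [1, 1]})
        f = group_frequencies(m, "p1")
        assert f.n.tolist() == [2, 2]
        assert f.p.tolist() == [0.5, 1.0]

    def test_single_observed_group_is_an_error(self):
        m = make_adoption({"A": [1, 0], "B": [None, None]})
        with pytest.raises(InsufficientGroupsError, match="insufficient groups"):
            group_frequencies(m, "p1")

    def test_unknown_practice(self):
        m = make_adoption({"A": [1], "B": [0]})
        with pytest.raises(KeyError):
            group_frequencies(m, "nope")


class TestCulturalFst:
    def test_no_between_group_variance(self):
        f = GroupFrequencies("x", ("A", "B", "C"), [10, 10, 10], [0.3, 0.3, 0.3])
        assert cultural_fst(f).fst == 0.0

    def test_complete_differentiation(self):
        f = GroupFrequencies("x", ("A", "B"), [5, 5], [0.0, 1.0])
        assert cultural_fst(f).fst == 1.0

    def test_two_groups_of_five(self, adoption_two_groups):
        # frozen from the raw-data variance decomposition over the ten
        # indicators: between = 0.09, total = 0.25 -> 0.36
        f = group_frequencies(adoption_two_groups, "p1")
        assert cultural_fst(f).fst == pytest.approx(0.36, rel=1e-12)

    def test_undefined_when_no_total_variance(self):
        f = GroupFrequencies("x", ("A", "B"), [5, 5], [0.0, 0.0])
        res = cultural_fst(f)
        assert not res.defined
        assert math.isnan(res.fst)

    def test_recoding_invariance(self, adoption_two_groups):
        # swapping the 0/1 coding (p -> 1-p) leaves F_ST unchanged
        flipped = make_adoption({"A": [0, 1, 1, 1, 1], "B": [0, 0, 0, 0, 1]})
        f1 = cultural_fst(group_frequencies(adoption_two_groups, "p1")).fst
        f2 = cultural_fst(group_frequencies(flipped, "p1")).fst
        assert f1 == pytest.approx(f2, rel=1e-14)

    def test_grower_order_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.integers(0, 2, 24).tolist()
        m1 = make_adoption({"A": vals[:12], "B": vals[12:]})
        perm = rng.permutation(12)
        m2 = make_adoption(
            {"A": [vals[:12][i] for i in perm], "B": [vals[12:][i] for i in perm]}
        )
        assert (
            cultural_fst(group_frequencies(m1, "p1")).fst
            == cultural_fst(group_frequencies(m2, "p1")).fst
        )

    def test_equal_weighting_option(self):
        f = GroupFrequencies("x", ("A", "B"), [9, 1], [0.2, 0.8])
        size_w = cultural_fst(f, "size").fst
        equal_w = cultural_fst(f, "equal").fst
        # equal weights: p_bar = 0.5, between = 0.09, total = 0.25
        assert equal_w == pytest.approx(0.36, rel=1e-12)
        assert size_w != equal_w


class TestOracleIdentity:
    """The naive estimator must equal the raw-data variance decomposition."""

    @given(
        st.integers(2, 5).flatmap(
            lambda n_grp: st.lists(
                st.tuples(
                    st.integers(2, 30),
                    st.floats(0.0, 1.0, allow_nan=False),
                ),
                min_size=n_grp,
                max_size=n_grp,
            )
        ),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=200)
    def test_matches_raw_data_decomposition(self, groups, seed):
        rng = np.random.default_rng(seed)
        data = {
            f"g{k}": (rng.random(n) < p).astype(float).tolist()
            for k, (n, p) in enumerate(groups)
        }
        m = make_adoption(data)
        labels = m.groups.to_numpy()
        vals = m.adoption["p1"].to_numpy()
        oracle = fst_oracle(vals, labels)
        res = cultural_fst(group_frequencies(m, "p1"))
        if math.isnan(oracle):
            assert not res.defined
        else:
            assert res.defined
            assert abs(res.fst - oracle) <= 1e-12
            assert 0.0 <= res.fst <= 1.0

    def test_oracle_rejects_mismatched_lengths(self):
        with pytest.raises(ValueError, match="matching lengths"):
            fst_oracle([1, 0, 1], ["A", "B"])

    def test_oracle_rejects_single_group(self):
        with pytest.raises(InsufficientGroupsError):
            fst_oracle([1, 0], ["A", "A"])


class TestCorrectedEstimator:
    def test_floors_at_zero_without_between_variance(self):
        f = GroupFrequencies("x", ("A", "B"), [10, 10], [0.4, 0.4])
        assert cultural_fst_corrected(f).fst_corrected == 0.0

    def test_fixed_differences_give_one(self):
        f = GroupFrequencies("x", ("A", "B"), [10, 10], [0.0, 1.0])
        assert cultural_fst_corrected(f).fst_corrected == 1.0

    def test_requires_two_observations_per_group(self):
        f = GroupFrequencies("x", ("A", "B"), [1, 10], [0.0, 0.5])
        with pytest.raises(ValueError, match="n_g >= 2"):
            cultural_fst_corrected(f)

    def test_undefined_propagates(self):
        f = GroupFrequencies("x", ("A", "B"), [5, 5], [1.0, 1.0])
        res = cultural_fst_corrected(f)
        assert not res.defined and res.fst_corrected is None

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = rng.integers(2, 40, size=3)
            p = rng.random(3)
            f = GroupFrequencies("x", ("A", "B", "C"), n, p)
            res = cultural_fst_corrected(f)
            if res.defined:
                assert 0.0 <= res.fst_corrected <= 1.0

    def test_less_biased_than_naive_at_low_differentiation(self):
        # 200 replicates at true F = 0.05, G = 3, n_g = 270
        rng = np.random.default_rng(2024)
        target, mu, n = 0.05, 0.4, 270
        scale = (1 - target) / target
        naive, corr = [], []
        for _ in range(200):
            p_g = rng.beta(mu * scale, (1 - mu) * scale, 3)
            p_hat = rng.binomial(n, p_g) / n
            f = GroupFrequencies("x", ("A", "B", "C"), [n] * 3, p_hat)
            res = cultural_fst_corrected(f)
            naive.append(res.fst)
            corr.append(res.fst_corrected)
        assert abs(np.mean(corr) - target) < abs(np.mean(naive) - target)


class TestPermutationTest:
    def test_extreme_differentiation_gives_minimal_p(self):
        m = make_adoption({"A": [1] * 20, "B": [0] * 20})
        res = permutation_test(m, "p1", n_perm=200, seed=3)
        assert res.fst == 1.0
        assert res.permutation_p <= 2 / 201

    def test_undefined_fst_leaves_p_undefined(self):
        m = make_adoption({"A": [1, 1], "B": [1, 1]})
        res = permutation_test(m, "p1", n_perm=50, seed=0)
        assert not res.defined and res.permutation_p is None

    def test_reproducible_given_seed(self):
        m = make_adoption({"A": [1, 0, 1, 0, 1], "B": [0, 0, 1, 0, 0]})
        p1 = permutation_test(m, "p1", 99, seed=7).permutation_p
        p2 = permutation_test(m, "p1", 99, seed=7).permutation_p
        assert p1 == p2

    def test_rejects_zero_permutations(self):
        m = make_adoption({"A": [1, 0], "B": [0, 1]})
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(m, "p1", 0, seed=0)

    def test_p_value_uses_add_one_correction(self):
        m = make_adoption({"A": [1, 0, 1], "B": [0, 1, 0]})
        res = permutation_test(m, "p1", n_perm=19, seed=1)
        assert res.permutation_p >= 1 / 20
        assert res.permutation_p <= 1.0


class TestPairwiseFst:
    def test_identical_pair_is_zero(self):
        m = make_adoption({"A": [1, 0], "B": [1, 0], "C": [1, 1]})
        assert pairwise_fst(m, "p1", ("A", "B")).fst == 0.0

    def test_fixed_pair_is_one(self):
        m = make_adoption({"A": [0, 0], "B": [1, 1], "C": [1, 0]})
        assert pairwise_fst(m, "p1", ("A", "B")).fst == 1.0

    def test_two_groups_of_five(self):
        m = make_adoption(
            {"A": [1, 0, 0, 0, 0], "B": [1, 1, 1, 1, 0], "C": [1, 1, 1, 1, 1]}
        )
        assert pairwise_fst(m, "p1", ("A", "B")).fst == pytest.approx(0.36, rel=1e-12)

    def test_unknown_group_label(self):
        m = make_adoption({"A": [1, 0], "B": [0, 1]})
        with pytest.raises(KeyError, match="unknown group"):
            pairwise_fst(m, "p1", ("A", "Z"))
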