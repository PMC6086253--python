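"""Synthetic generator: moments, determinism, study composition."""

import numpy as np
import pandas as pd
import pytest

from cultscope import (
    SyntheticStudyConfig,
    generate_study,
    inject_missingness,
    sample_adoption,
    sample_group_frequencies,
    sample_likert,
)

from conftest import make_adoption


class TestSampleGroupFrequencies:
    def test_zero_target_returns_grand_mean_exactly(self):
        p = sample_group_frequencies(0.37, 0.0, 5, seed=0)
        assert (p == 0.37).all()

    def test_beta_moments(self):
        # Balding-Nichols: mean p_bar, variance F * p_bar * (1 - p_bar)
        p = sample_group_frequencies(0.4, 0.15, 10_000, seed=42)
        assert p.mean() == pytest.approx(0.4, abs=0.01)
        assert p.var() == pytest.approx(0.15 * 0.4 * 0.6, rel=0.10)

    def test_deterministic_given_seed(self):
        a = sample_group_frequencies(0.3, 0.2, 50, seed=9)
        b = sample_group_frequencies(0.3, 0.2, 50, seed=9)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize(
        "p_bar, fst", [(0.0, 0.1), (1.0, 0.1), (0.4, 1.0), (0.4, -0.1)]
    )
    def test_degenerate_parameters_rejected(self, p_bar, fst):
        with pytest.raises(ValueError):
            sample_group_frequencies(p_bar, fst, 3, seed=0)


class TestSampleAdoption:
    def test_degenerate_probabilities(self):
        m = sample_adoption([0.0, 1.0], [3, 3], seed=0)
        by_group = m.adoption["p01"].groupby(m.groups).mean()
        assert by_group.tolist() == [0.0, 1.0]

    def test_frequency_concentrates(self):
        m = sample_adoption([0.5, 0.5], [10_000, 5], seed=1)
        freq = m.adoption["p01"][m.groups == "region_1"].mean()
        assert freq == pytest.approx(0.5, abs=0.015)

    def test_deterministic_and_length_checked(self):
        a = sample_adoption([0.3, 0.7], [10, 10], seed=5)
        b = sample_adoption([0.3, 0.7], [10, 10], seed=5)
        pd.testing.assert_frame_equal(a.adoption, b.adoption)
        with pytest.raises(ValueError, match="matching lengths"):
            sample_adoption([0.3], [10, 10], seed=0)


class TestSampleLikert:
    def test_degenerate_dispersion_collapses_to_mean(self):
        vals = sample_likert(5.0, 1e-9, 100, seed=0)
        assert (vals == 5).all()

    def test_symmetric_mean_recovered(self):
        vals = sample_likert(4.0, 1.0, 10_000, seed=3)
        assert vals.mean() == pytest.approx(4.0, abs=0.05)

    def test_clamped_to_scale(self):
        vals = sample_likert(7.0, 5.0, 1000, seed=2)
        assert vals.min() >= 1 and vals.max() <= 7


class TestInjectMissingness:
    def test_zero_rate_is_identity(self):
        m = make_adoption({"A": [1, 0, 1], "B": [0, 0, 1]})
        out = inject_missingness(m, 0.0, seed=0)
        pd.testing.assert_frame_equal(out.adoption, m.adoption)

    def test_rate_recovered_on_large_matrix(self):
        m = sample_adoption([0.5, 0.5], [5000, 5000], seed=0)
        out = inject_missingness(m, 0.2, seed=1)
        frac = out.adoption["p01"].isna().mean()
        assert frac == pytest.approx(0.2, abs=0.015)

    def test_group_labels_untouched_and_deterministic(self):
        m = sample_adoption([0.5, 0.5], [50, 50], seed=0)
        a = inject_missingness(m, 0.3, seed=7)
        b = inject_missingness(m, 0.3, seed=7)
        pd.testing.assert_frame_equal(a.adoption, b.adoption)
        pd.testing.assert_series_equal(a.groups, m.groups)


class TestGenerateStudy:
    def test_default_config_matches_study_scale(self):
        adoption, ratings, truth = generate_study(SyntheticStudyConfig(seed=0))
        assert adoption.n_growers == 822
        assert len(adoption.group_ids) == 3
        assert len(adoption.practice_ids) == 44
        assert ratings["expert_id"].nunique() == 120
        assert len(truth) == 44

    def test_same_seed_reproduces_exactly(self):
        a1, r1, t1 = generate_study(SyntheticStudyConfig(seed=123, n_practices=4))
        a2, r2, t2 = generate_study(SyntheticStudyConfig(seed=123, n_practices=4))
        pd.testing.assert_frame_equal(a1.adoption, a2.adoption)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_adding_a_practice_preserves_earlier_draws(self):
        small = generate_study(SyntheticStudyConfig(seed=5, n_practices=3))[0]
        large = generate_study(SyntheticStudyConfig(seed=5, n_practices=5))[0]
        pd.testing.assert_frame_equal(
            small.adoption, large.adoption[small.practice_ids]
        )

    def test_null_structure_yields_low_fst(self):
        from cultscope import cultural_fst, group_frequencies

        cfg = SyntheticStudyConfig(
            seed=2,
            n_practices=1,
            p_bar=[0.5],
            target_fst=[0.0],
            missing_rate=0.0,
            group_sizes=(200, 200, 200),
        )
        adoption, _, _ = generate_study(cfg)
        res = cultural_fst(group_frequencies(adoption, "p01"))
        assert res.fst < 0.02  # sampling noise only

    def test_ground_truth_carries_generating_parameters(self):
        cfg = SyntheticStudyConfig(
            seed=1, n_practices=2, p_bar=[0.3, 0.6], target_fst=[0.1, 0.2],
            cost_mean=[5.0, 2.0], private_benefit_mean=[2.0, 5.0],
            public_benefit_mean=[6.0, 3.0],
        )
        _, _, truth = generate_study(cfg)
        assert truth["p_bar"].tolist() == [0.3, 0.6]
        assert truth["net_cost_mean"].tolist() == [3.0, -3.0]
        assert {"true_p_region_1", "true_p_region_2", "true_p_region_3"} <= set(
            truth.columns
        )

    def test_config_validation(self):
        with pytest.raises(ValueError, match="group_sizes"):
            SyntheticStudyConfig(n_groups=3, group_sizes=(10, 10))
        with pytest.raises(ValueError, match="missing_rate"):
            SyntheticStudyConfig(missing_rate=1.0)
        with pytest.raises(ValueError, match="per practice"):
            SyntheticStudyConfig(n_practices=3, p_bar=[0.5])
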