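"""Feature-engineering rules: power transform, quantile binning, rare-level
pooling, binarization, burden score, interaction flags and the matrix
builder."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cifrisk.features import (FeatureSpec, bin_into_segments, binarize,
                              build_feature_matrix, default_feature_specs,
                              group_rare_levels,
                              interaction_randomization_design,
                              max_abs_pairwise_correlation, site_burden_score,
                              yeo_johnson_transform)


class TestYeoJohnson:
    def test_lambda_one_is_identity_for_nonnegative(self, rng):
        x = rng.uniform(0, 5, 50)
        out, lam = yeo_johnson_transform(x, lmbda=1.0, standardize=False)
        assert lam == 1.0
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_lambda_zero_is_log1p_branch(self):
        x = np.array([np.e - 1.0, 0.0, 1.0])
        out, _ = yeo_johnson_transform(x, lmbda=0.0, standardize=False)
        assert out[0] == pytest.approx(1.0, abs=1e-12)
        assert out[1] == pytest.approx(0.0, abs=1e-12)

    def test_right_skew_reduced_and_lambda_below_one(self, rng):
        from scipy.stats import skew
        x = np.exp(rng.normal(0, 1, 500))
        out, lam = yeo_johnson_transform(x)
        assert lam < 1.0
        assert abs(skew(out)) < abs(skew(x))
        assert out.mean() == pytest.approx(0.0, abs=1e-9)
        assert out.std() == pytest.approx(1.0, abs=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            yeo_johnson_transform(np.ones(10))


class TestBinning:
    def test_uniform_ranks_split_evenly(self):
        labels = bin_into_segments(np.arange(1, 101), 5)
        counts = pd.Series(labels).value_counts().sort_index()
        assert counts.tolist() == [20, 20, 20, 20, 20]

    def test_boundaries_of_one_to_ten(self):
        # quantile boundaries fall after elements 2, 4, 6 and 8
        labels = bin_into_segments(np.arange(1, 11), 5)
        assert labels.tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_degenerate_input_collapses_with_warning(self):
        with pytest.warns(UserWarning, match="distinct"):
            labels = bin_into_segments(np.ones(8), 5)
        assert set(labels) == {1}

    def test_labels_are_monotone_in_value(self, rng):
        x = rng.normal(size=200)
        labels = bin_into_segments(x, 5)
        order = np.argsort(x)
        assert (np.diff(labels[order]) >= 0).all()


class TestRareLevels:
    @pytest.mark.parametrize("labels,expected_other", [
        (["A"] * 50 + ["B"] * 47 + ["C"] * 3, {"C"}),
        (["A"] * 96 + ["B"] * 4, {"B"}),
    ])
    def test_rare_levels_pooled(self, labels, expected_other):
        out = group_rare_levels(labels)
        pooled = set(pd.Series(labels)[out == "other"])
        assert pooled == expected_other

    def test_all_rare_levels_pool_to_single_level(self):
        # 21 levels at ~4.8% each: everything is pooled
        labels = [f"L{i}" for i in range(21) for _ in range(10)]
        out = group_rare_levels(labels)
        assert set(out) == {"other"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            group_rare_levels([])


class TestBinarize:
    def test_membership_with_missing_to_no(self):
        out = binarize(["US", "CH", None, "US"], {"US"})
        assert out.tolist() == [1, 0, 0, 1]

    def test_all_levels_positive(self):
        assert binarize(["a", "b"], {"a", "b"}).tolist() == [1, 1]

    def test_top_segment_equals_quantile_threshold(self, rng):
        # yeo-johnson -> bin -> top-segment indicator must agree with a
        # direct empirical-quantile threshold on the raw values
        # (rank monotonicity of the power transform)
        x = rng.lognormal(1.0, 0.8, 500)
        t, _ = yeo_johnson_transform(x)
        top = binarize(bin_into_segments(t, 5), {5})
        direct = (x > np.quantile(x, 0.8)).astype(int)
        np.testing.assert_array_equal(top, direct)


class TestSiteBurden:
    def _frame(self, counts, study="S"):
        return pd.DataFrame({
            "site_id": [f"{study}-{i}" for i in range(len(counts))],
            "study_id": study,
            "parallel_trials_same_ta": counts,
        })

    def test_single_site_scores_one(self):
        out = site_burden_score(self._frame([3]))
        assert out["site_burden_score"].tolist() == [1.0]

    def test_average_rank_ties(self):
        out = site_burden_score(self._frame([0, 2, 2, 5]))
        assert out["site_burden_score"].tolist() == [0.25, 0.625, 0.625, 1.0]

    def test_all_tied_counts(self):
        out = site_burden_score(self._frame([4, 4, 4, 4]))
        assert out["site_burden_score"].tolist() == [0.625] * 4

    def test_scores_in_unit_interval_and_order_invariant(self, rng):
        counts = rng.integers(0, 10, 20)
        frame = self._frame(list(counts))
        shuffled = frame.sample(frac=1.0, random_state=1)
        a = site_burden_score(frame).set_index("site_id")["site_burden_score"]
        b = site_burden_score(shuffled).set_index("site_id")["site_burden_score"]
        assert ((a > 0) & (a <= 1)).all()
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_strictly_increasing_counts_give_strictly_increasing_scores(self):
        out = site_burden_score(self._frame([1, 3, 7, 9]))
        assert (np.diff(out["site_burden_score"]) > 0).all()


class TestInteraction:
    @pytest.mark.parametrize("randomized,design,expected", [
        (True, "parallel", (0, 0)),
        (True, "single_group", (0, 0)),
        (False, "sequential", (1, 0)),
        (False, "parallel", (1, 0)),
        (False, "single_group", (0, 1)),
        (False, "crossover", (0, 0)),
    ])
    def test_truth_table(self, randomized, design, expected):
        assert interaction_randomization_design(randomized, design) == expected

    @given(st.booleans(), st.sampled_from(
        ["parallel", "single_group", "crossover", "sequential"]))
    @settings(max_examples=50, deadline=None)
    def test_at_most_one_flag_set(self, randomized, design):
        ps, sg = interaction_randomization_design(randomized, design)
        assert ps + sg <= 1


class TestBuildMatrix:
    def test_empty_spec_list_gives_zero_columns(self, tiny_triple):
        act, studies, sites = tiny_triple
        m = build_feature_matrix(act, studies, sites, [])
        assert m.values.shape == (4, 0)
        assert m.activity_ids == list(act["activity_id"])

    def test_enrollment_threshold_column(self, tiny_triple):
        act, studies, sites = tiny_triple
        spec = FeatureSpec("enrolled_gt_32", "patients_enrolled", "threshold",
                           {"value": 32, "direction": "gt"})
        m = build_feature_matrix(act, studies, sites, [spec],
                                 rare_threshold=0.0)
        # sites visited: enrollments 10, 33, 40, 5
        assert m.values["enrolled_gt_32"].tolist() == [0, 1, 1, 0]

    def test_screen_failure_threshold_column(self, tiny_triple):
        act, studies, sites = tiny_triple
        spec = FeatureSpec("screen_failure_gt_0.62", "screen_failure_rate",
                           "threshold", {"value": 0.62, "direction": "gt"})
        m = build_feature_matrix(act, studies, sites, [spec],
                                 rare_threshold=0.0)
        assert m.values["screen_failure_gt_0.62"].tolist() == [0, 1, 0, 0]

    def test_unresolvable_spec_names_the_spec(self, tiny_triple):
        act, studies, sites = tiny_triple
        spec = FeatureSpec("bogus", "no_such_column", "threshold", {"value": 1})
        with pytest.raises(KeyError, match="bogus"):
            build_feature_matrix(act, studies, sites, [spec])

    def test_rare_feature_dropped_with_warning(self, default_dataset):
        ds = default_dataset
        spec = FeatureSpec("ta_rare", "therapeutic_area", "binary_level",
                           {"positive_levels": ["no_such_area"]})
        with pytest.warns(UserWarning, match="ta_rare"):
            m = build_feature_matrix(ds.activities, ds.studies, ds.sites, [spec])
        assert "ta_rare" not in m.feature_names

    def test_entries_binary_and_prevalence_reported(self, default_matrix):
        vals = default_matrix.values.to_numpy()
        assert set(np.unique(vals)) <= {0, 1}
        for name in default_matrix.feature_names:
            assert default_matrix.prevalence[name] >= 0.05

    def test_row_order_invariance(self, default_dataset):
        ds = default_dataset
        specs = default_feature_specs()
        m1 = build_feature_matrix(ds.activities, ds.studies, ds.sites, specs)
        shuffled = ds.activities.sample(frac=1.0, random_state=3)
        m2 = build_feature_matrix(shuffled, ds.studies, ds.sites, specs)
        pd.testing.assert_frame_equal(m1.values.sort_index(),
                                      m2.values.sort_index())


class TestCorrelationScreen:
    def test_duplicated_column_gives_one(self, rng):
        x = rng.integers(0, 2, 100)
        frame = pd.DataFrame({"a": x, "b": x,
                              "c": rng.integers(0, 2, 100)})
        value, pair = max_abs_pairwise_correlation(frame)
        assert value == pytest.approx(1.0)
        assert pair == ("a", "b")

    def test_complement_column_gives_one(self, rng):
        x = rng.integers(0, 2, 100)
        frame = pd.DataFrame({"a": x, "b": 1 - x,
                              "c": rng.integers(0, 2, 100)})
        value, pair = max_abs_pairwise_correlation(frame)
        assert value == pytest.approx(1.0)
        assert pair == ("a", "b")

    def test_independent_columns_near_zero(self, rng):
        frame = pd.DataFrame(rng.integers(0, 2, (10_000, 2)),
                             columns=["a", "b"])
        value, _ = max_abs_pairwise_correlation(frame)
        assert value < 0.05

    def test_constant_column_excluded_with_warning(self, rng):
        frame = pd.DataFrame({"a": rng.integers(0, 2, 50),
                              "b": rng.integers(0, 2, 50),
                              "c": np.ones(50, dtype=int)})
        with pytest.warns(UserWarning, match="constant"):
            _, pair = max_abs_pairwise_correlation(frame)
        assert "c" not in pair
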