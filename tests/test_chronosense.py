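"""Median binarization, LDA discrimination, chronosensitivity index, LOOCV."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circapheno import chronosense
from circapheno.exceptions import ConfigurationError


def labelled_data(n_per_class=4, gap=1.0, seed=0):
    rng = np.random.default_rng(seed)
    lo = rng.normal(0.0, 0.1, n_per_class)
    hi = rng.normal(gap, 0.1, n_per_class)
    X = pd.DataFrame({"signal": np.concatenate([lo, hi]),
                      "noise": rng.normal(0, 1, 2 * n_per_class)})
    y = pd.Series(["below"] * n_per_class + ["above"] * n_per_class, index=X.index)
    return X, y


class TestBinarize:
    def test_even_count_splits_at_median(self):
        labels = chronosense.binarize_by_median(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert list(labels) == ["below", "below", "above", "above"]

    def test_odd_count_median_goes_above(self):
        labels = chronosense.binarize_by_median(pd.Series([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert list(labels) == ["below", "below", "above", "above", "above"]

    def test_duplicated_median_values_go_above(self):
        labels = chronosense.binarize_by_median(pd.Series([1.0, 2.0, 2.0, 3.0]))
        assert list(labels) == ["below", "above", "above", "above"]

    def test_identical_values_rejected(self):
        with pytest.raises(ConfigurationError):
            chronosense.binarize_by_median(pd.Series([2.0, 2.0, 2.0, 2.0]))


class TestLDA:
    def test_separating_predictor_takes_all_contribution(self):
        X, y = labelled_data(gap=5.0)
        _, contrib, _ = chronosense.lda_discriminate(X, y)
        assert contrib["signal"] > 80.0
        assert contrib.sum() == pytest.approx(100.0, abs=0.01)

    def test_duplicated_predictors_share_contribution(self):
        X, y = labelled_data(gap=5.0)
        X = X.copy()
        X["signal2"] = X["signal"]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, contrib, _ = chronosense.lda_discriminate(X, y)
        assert contrib.sum() == pytest.approx(100.0, abs=0.01)
        assert contrib["signal"] == pytest.approx(contrib["signal2"], rel=0.05)


class TestIndex:
    def test_hand_computed_example(self):
        scores = pd.Series([-3.0, -1.0, 1.0, 3.0])
        labels = pd.Series(["b", "b", "a", "a"])
        bcd, wcd, index, effective = chronosense.chronosensitivity_index(scores, labels)
        assert (bcd, wcd, index) == (4.0, 1.0, 4.0)
        assert effective

    def test_boundary_configuration_scores_exactly_two(self):
        # constructed so the class-mean separation is twice the member scatter
        scores = pd.Series([-1.0, 1.0, 1.0, 3.0])
        labels = pd.Series(["b", "b", "a", "a"])
        bcd, wcd, index, effective = chronosense.chronosensitivity_index(scores, labels)
        assert bcd == pytest.approx(2.0 * wcd)
        assert index == pytest.approx(2.0)
        assert not effective  # the cut-off demands strictly more than 2

    def test_degenerate_zero_scatter_gives_infinite_index(self):
        scores = pd.Series([-2.0, -2.0, 2.0, 2.0])
        labels = pd.Series(["b", "b", "a", "a"])
        _, wcd, index, _ = chronosense.chronosensitivity_index(scores, labels)
        assert wcd == 0.0 and index == math.inf

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_index_invariant_to_affine_rescaling(self, scale, shift):
        scores = pd.Series([-3.0, -1.0, 1.0, 3.0])
        labels = pd.Series(["b", "b", "a", "a"])
        _, _, base, _ = chronosense.chronosensitivity_index(scores, labels)
        _, _, rescaled, _ = chronosense.chronosensitivity_index(scores * scale + shift, labels)
        assert rescaled == pytest.approx(base, rel=1e-9)

    def test_translating_a_class_away_raises_the_index(self):
        labels = pd.Series(["b", "b", "a", "a"])
        base = pd.Series([-3.0, -1.0, 1.0, 3.0])
        indices = []
        for shift in (0.0, 2.0, 5.0):
            shifted = base.copy()
            shifted[labels == "a"] += shift
            indices.append(chronosense.chronosensitivity_index(shifted, labels)[2])
        assert indices[0] < indices[1] < indices[2]


class TestValidation:
    def test_perfectly_separable_data_classified_exactly(self):
        X, y = labelled_data(gap=10.0, n_per_class=5)
        assert chronosense.validate(X, y, method="lda") == 1.0
        assert chronosense.validate(X, y, method="logistic") == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(1)
        accs = []
        for seed in range(6):
            X, y = labelled_data(gap=5.0, n_per_class=8, seed=seed)
            y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            accs.append(chronosense.validate(X, y_perm, method="lda"))
        assert abs(np.mean(accs) - 0.5) < 0.2

    def test_accuracy_granularity_matches_leave_one_out(self):
        # 7 lines: LOOCV accuracy is a multiple of 1/7
        X, y = labelled_data(gap=1.2, n_per_class=4, seed=3)
        X, y = X.iloc[:7], y.iloc[:7]
        acc = chronosense.validate(X, y, method="lda")
        assert acc == pytest.approx(round(acc * 7) / 7, abs=1e-9)

    def test_regression_agreement_near_one_for_linear_truth(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.uniform(0, 1, 20)})
        y = pd.Series(3.0 * X["a"] + 0.5 + rng.normal(0, 0.01, 20), index=X.index)
        assert chronosense.validate(X, y, method="ridge") > 0.8
        assert chronosense.validate(X, y, method="lasso") > 0.5


class TestDrugRanking:
    def test_clock_driven_metric_outranks_random_metric(self):
        rng = np.random.default_rng(5)
        n = 14
        clock = pd.Series(rng.uniform(0, 1, n))
        X = pd.DataFrame({
            "circadian_band": clock + rng.normal(0, 0.05, n),
            "period": rng.normal(24, 1, n),
        })
        sens = pd.DataFrame({
            "clockdep": -clock + rng.normal(0, 0.05, n),
            "random": rng.normal(0, 1, n),
        })
        ranking = chronosense.rank_drugs(X, sens)
        assert ranking.iloc[0]["drug"] == "clockdep"
        assert ranking.iloc[0]["index"] > ranking.iloc[1]["index"]

    def test_full_analysis_reports_class_sizes_and_accuracies(self):
        X, y_metric = labelled_data(gap=3.0, n_per_class=5)
        metric = pd.Series(np.linspace(0, 1, 10), index=X.index)
        res = chronosense.analyze_drug(X, metric)
        assert sum(res.class_sizes.values()) == 10
        assert 0.0 <= res.loocv_accuracy <= 1.0
        assert res.contributions_pct.sum() == pytest.approx(100.0, abs=0.01)
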