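import math
import warnings

import numpy as np
import pandas as pd
import pytest

from ribofold_te.classify import (
    SplitResult,
    compare_models,
    evaluate_auc,
    grouped_importance,
    make_splits,
    run_splits,
    split_table,
    tune_and_train,
)

from _oracles import auc_concordance


def _planted_data(n=60, p=12, seed=0, separation=3.0):
    """Two informative features shifted by class; the rest pure noise."""
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(size=(n, p))
    X[:, 0] += separation * y
    X[:, 1] -= separation * y
    cols = [f"f{i}" for i in range(p)]
    return pd.DataFrame(X, columns=cols), y


class TestMakeSplits:
    def test_seventy_thirty_sizes(self):
        y = np.array([0, 1] * 50)
        (train, test), = make_splits(y, n_splits=1, base_seed=3)
        assert len(train) == 70 and len(test) == 30

    def test_disjoint_exhaustive_and_stratified(self):
        y = np.array([0] * 30 + [1] * 70)
        for train, test in make_splits(y, n_splits=5, base_seed=1):
            assert set(train) | set(test) == set(range(100))
            assert not set(train) & set(test)
            for c in (0, 1):
                assert np.any(y[train] == c) and np.any(y[test] == c)
            # stratification keeps class proportions to within one sample
            assert abs(np.sum(y[train] == 1) - 49) <= 1

    def test_same_seed_reproduces_splits(self):
        y = np.array([0, 1] * 20)
        a = make_splits(y, n_splits=3, base_seed=9)
        b = make_splits(y, n_splits=3, base_seed=9)
        for (ta, sa), (tb, sb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(sa, sb)

    def test_requested_number_of_splits(self):
        y = np.array([0, 1] * 10)
        assert len(make_splits(y, n_splits=100, base_seed=0)) == 100

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError):
            make_splits(np.array([0, 1] * 4), n_splits=1)


class TestAuc:
    def test_perfect_separation(self):
        assert evaluate_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert evaluate_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_hand_counted_concordance(self):
        # concordant pairs: (0.9,0.5), (0.9,0.1), (0.4,0.1) -> 3 of 4
        assert evaluate_auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            evaluate_auc([0.1, 0.2], [1, 1])

    def test_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # rounding forces some ties
            assert evaluate_auc(scores, labels) == pytest.approx(auc_concordance(scores, labels))

    def test_negating_scores_flips_auc(self):
        rng = np.random.default_rng(1)
        scores = rng.random(20)
        labels = rng.integers(0, 2, size=20)
        labels[:2] = [0, 1]
        assert evaluate_auc(-scores, labels) == pytest.approx(1 - evaluate_auc(scores, labels))


class TestTuneAndTrain:
    def test_single_point_grid_is_selected_without_search(self):
        X, y = _planted_data()
        grid = {"n_estimators": [50], "min_samples_leaf": [2]}
        _, params = tune_and_train(X, y, "rf", cv_folds=3, grid=grid, seed=0)
        assert params == {"n_estimators": 50, "min_samples_leaf": 2}

    def test_recovers_planted_separation(self):
        X, y = _planted_data(n=80, separation=3.0)
        pipe, _ = tune_and_train(
            X[:60], y[:60], "rf", cv_folds=5, grid={"n_estimators": [100]}, seed=0
        )
        auc = evaluate_auc(pipe.predict_proba(X[60:])[:, 1], y[60:])
        assert auc >= 0.95

    def test_elastic_net_model_trains(self):
        X, y = _planted_data(n=60)
        pipe, params = tune_and_train(
            X, y, "en", cv_folds=3, grid={"l1_ratio": [0.5], "C": [1.0]}, seed=0
        )
        assert set(params) == {"l1_ratio", "C"}
        assert evaluate_auc(pipe.predict_proba(X)[:, 1], y) > 0.9

    def test_single_class_training_error(self):
        X, _ = _planted_data(n=20)
        with pytest.raises(ValueError):
            tune_and_train(X, np.zeros(20, dtype=int), "rf", grid={"n_estimators": [10]})

    def test_missing_values_are_imputed(self):
        X, y = _planted_data(n=60)
        X.iloc[::5, 3] = np.nan
        pipe, _ = tune_and_train(X, y, "rf", grid={"n_estimators": [50]}, seed=0)
        assert np.isfinite(pipe.predict_proba(X)[:, 1]).all()


class TestRunSplitsAndImportance:
    def test_importances_normalized_and_deterministic(self):
        X, y = _planted_data(n=40, p=6)
        kwargs = dict(n_splits=3, cv_folds=3, base_seed=5, rf_grid={"n_estimators": [30]}, models=("rf",))
        a = run_splits(X, y, **kwargs)
        b = run_splits(X, y, **kwargs)
        for res in a:
            assert res.importances.sum() == pytest.approx(1.0, abs=1e-6)
        assert split_table(a).equals(split_table(b))
        for ra, rb in zip(a, b):
            pd.testing.assert_series_equal(ra.importances, rb.importances)

    def test_group_sums_conserve_total(self):
        imp = pd.Series({"seq_gc_cds": 0.4, "vivo_bin_00": 0.35, "vitro_bin_01": 0.2, "insilico_mfe_whole": 0.05})
        res = SplitResult(0, 0, {}, importances=imp)
        groups = {"seq_gc_cds": "sequence", "vivo_bin_00": "vivo", "vitro_bin_01": "vitro", "insilico_mfe_whole": "insilico"}
        summary = grouped_importance([res], groups)
        row = summary.group_sums.iloc[0]
        assert row.sum() == pytest.approx(1.0, abs=1e-6)
        assert row["vivo"] == pytest.approx(0.35)

    def test_all_mass_on_one_vivo_bin(self):
        imp = pd.Series({"vivo_bin_07": 1.0, "vitro_bin_07": 0.0})
        res = SplitResult(0, 0, {}, importances=imp)
        groups = {"vivo_bin_07": "vivo", "vitro_bin_07": "vitro"}
        summary = grouped_importance([res], groups)
        assert summary.group_sums.iloc[0]["vivo"] == 1.0
        assert summary.bin_means.loc[7, "vivo"] == 1.0

    def test_unregistered_feature_error(self):
        res = SplitResult(0, 0, {}, importances=pd.Series({"mystery": 1.0}))
        with pytest.raises(ValueError):
            grouped_importance([res], {})


class TestCompareModels:
    def test_identical_vectors_warn_with_nan(self):
        with pytest.warns(UserWarning):
            t, p = compare_models([0.9] * 5, [0.9] * 5)
        assert math.isnan(t) and math.isnan(p)

    def test_constant_shift_is_overwhelmingly_significant(self):
        rng = np.random.default_rng(0)
        b = 0.8 + rng.normal(0, 1e-4, size=100)
        t, p = compare_models(b + 0.1, b)
        assert p < 1e-10 and t > 0

    def test_swapping_arguments_negates_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(50), rng.random(50)
        t1, p1 = compare_models(a, b)
        t2, p2 = compare_models(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_zero_variance_nonzero_shift_reports_zero_p(self):
        with pytest.warns(UserWarning):
            t, p = compare_models([0.9] * 5, [0.8] * 5)
        assert p == 0.0 and t == math.inf

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            compare_models([0.9, 0.8], [0.9])
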