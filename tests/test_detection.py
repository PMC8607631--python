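"""The detection engine: splitting, selection, tuning, metrics, transfer."""

import numpy as np
import pytest

import paravox as pv
from paravox import detection as det
from paravox.errors import (
    SelectionError,
    StratificationError,
    UndefinedMetricError,
)

from _oracles import auc_concordance, quartile_count_oracle, student_t_oracle


class TestStratifiedKFold:
    def test_balanced_cohort_exact_folds(self):
        y = np.repeat([0, 1], 30)
        folds = det.stratified_kfold(y, 5, seed=0)
        for f in range(5):
            assert np.sum((folds == f) & (y == 0)) == 6
            assert np.sum((folds == f) & (y == 1)) == 6

    def test_unbalanced_within_one(self):
        y = np.array([0] * 7 + [1] * 5)
        folds = det.stratified_kfold(y, 3, seed=1)
        for cls in (0, 1):
            counts = [np.sum((folds == f) & (y == cls)) for f in range(3)]
            assert max(counts) - min(counts) <= 1

    def test_deterministic(self):
        y = np.repeat([0, 1], 15)
        assert np.array_equal(
            det.stratified_kfold(y, 5, seed=3), det.stratified_kfold(y, 5, seed=3)
        )

    def test_small_class_rejected(self):
        with pytest.raises(StratificationError):
            det.stratified_kfold(np.array([0, 0, 0, 1, 1]), 3, seed=0)


class TestStratifiedSplit:
    def test_quarter_split_of_balanced_sixty(self):
        y = np.repeat([0, 1], 30)
        seen = set()
        for i in range(4):
            rng = np.random.default_rng(i)
            train, test = det.stratified_split(y, 0.25, rng, parity=i % 2)
            assert test.size == 15
            c0 = int(np.sum(y[test] == 0))
            seen.add(c0)
            assert c0 in (7, 8)
            assert np.intersect1d(train, test).size == 0
        assert seen == {7, 8}  # the extra subject's class alternates


class TestQuartileRule:
    def test_constant_vector(self):
        assert det.first_quartile_count([7] * 100) == 7

    def test_constructed_vector_matches_oracle(self):
        counts = [5, 5, 5, 5] + [20] * 96
        assert det.first_quartile_count(counts) == quartile_count_oracle(counts)

    def test_random_vectors_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.integers(1, 34, size=rng.integers(3, 120)).tolist()
            assert det.first_quartile_count(counts) == quartile_count_oracle(counts)

    def test_floor_at_one(self):
        assert det.first_quartile_count([1, 1, 1, 1]) == 1


class TestRocAuc:
    def test_perfect_scores(self):
        labels = np.array([0, 1, 0, 1, 1])
        (_, _), auc = det.roc_auc(labels.astype(float), labels)
        assert auc == 1.0

    def test_all_tied_scores_chance(self):
        labels = np.array([0, 1] * 10)
        (_, _), auc = det.roc_auc(np.ones(20), labels)
        assert auc == pytest.approx(0.5, abs=1e-12)

    def test_matches_concordance_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(10, 200))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # half the instances get heavily tied scores
            scores = (
                rng.integers(0, 4, n).astype(float)
                if rng.random() < 0.5
                else rng.standard_normal(n)
            )
            (_, _), auc = det.roc_auc(scores, labels)
            assert auc == pytest.approx(auc_concordance(scores, labels), abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            det.roc_auc(np.array([0.3, 0.7]), np.array([1, 1]))


class TestSelection:
    def test_strong_feature_always_selected(self):
        found = 0
        for seed in range(5):
            t = pv.synth_cohort(
                pv.CohortSpec(
                    n_per_class=30, n_features=10, informative=(3,),
                    effect_sizes=(4.0,), seed=seed,
                )
            )
            sel = det.rfecv_select(t, "logistic", n_iterations=10, seed=seed)
            found += "f04" in sel.selected_features
        assert found == 5

    def test_single_class_rejected(self, informative_cohort):
        import pandas as pd

        df = informative_cohort.df.copy()
        df["label"] = "PD"
        t = pv.FeatureTable(df, feature_names=informative_cohort.feature_names)
        with pytest.raises(SelectionError):
            det.rfecv_select(t, "logistic", n_iterations=2, seed=0)

    def test_selection_result_invariants(self, informative_cohort):
        sel = det.rfecv_select(informative_cohort, "logistic", n_iterations=5, seed=1)
        assert len(sel.per_iteration_optimal_counts) == 5
        assert sel.final_count == det.first_quartile_count(
            sel.per_iteration_optimal_counts
        )
        assert sel.selected_features == sel.aggregated_ranking[: sel.final_count]
        assert sorted(sel.aggregated_ranking) == sorted(
            informative_cohort.feature_names
        )


class TestGridSearch:
    def test_single_combination_returned(self, informative_cohort):
        best = det.grid_search(
            informative_cohort, "logistic", grid={"C": [0.5]}, seed=0
        )
        assert best == {"C": 0.5}

    def test_separable_data_prefers_working_regularization(self):
        t = pv.synth_cohort(
            pv.CohortSpec(
                n_per_class=30, n_features=5, informative=(0,),
                effect_sizes=(20.0,), seed=2,
            )
        )
        # a linear margin separates this cohort; an absurdly narrow RBF
        # kernel memorizes the training folds and fails in CV
        best = det.grid_search(
            t, "svm",
            grid={"kernel": ["rbf", "linear"], "C": [1.0], "gamma": [1000.0]},
            seed=0,
        )
        assert best["kernel"] == "linear"

    def test_deterministic(self, informative_cohort):
        a = det.grid_search(informative_cohort, "logistic", seed=5)
        b = det.grid_search(informative_cohort, "logistic", seed=5)
        assert a == b

    def test_failing_combination_scored_zero(self, informative_cohort):
        with pytest.warns(UserWarning):
            best = det.grid_search(
                informative_cohort,
                "svm",
                grid={"kernel": ["definitely_invalid", "linear"], "C": [1.0]},
                seed=0,
            )
        assert best["kernel"] == "linear"


class TestEvaluate:
    def test_separable_cohort_perfect(self):
        t = pv.synth_cohort(
            pv.CohortSpec(
                n_per_class=30, n_features=5, informative=(1,),
                effect_sizes=(20.0,), seed=3,
            )
        )
        rep = det.evaluate(t, None, "logistic", n_iterations=50, seed=0)
        assert rep.accuracy.mean() == 1.0
        assert rep.auc.mean() == 1.0

    def test_metric_bounds_and_summary(self, informative_cohort):
        rep = det.evaluate(informative_cohort, None, "perceptron",
                           n_iterations=30, seed=0)
        for name in ("accuracy", "sensitivity", "specificity", "auc"):
            v = getattr(rep, name)
            assert np.all((0.0 <= v) & (v <= 1.0))
        summ = rep.metric_summary()
        assert set(summ) == {"accuracy", "sensitivity", "specificity", "auc"}

    def test_roc_band_monotone(self, informative_cohort):
        rep = det.evaluate(informative_cohort, None, "logistic",
                           n_iterations=30, seed=0)
        assert np.all(np.diff(rep.mean_tpr) >= -1e-12)
        assert rep.mean_tpr[-1] == 1.0

    def test_no_test_leakage_in_scaling(self):
        # an extreme outlier in the test rows must not move the transform
        x_train = np.array([[0.0], [2.0], [4.0]])
        x_test = np.array([[1e6], [2.0]])
        tr, te = det._scale_impute(x_train, x_test)
        mu, sd = 2.0, np.std([0.0, 2.0, 4.0])
        assert te[1, 0] == pytest.approx((2.0 - mu) / sd)
        assert tr.mean() == pytest.approx(0.0, abs=1e-12)

    def test_imputation_uses_train_mean_only(self):
        x_train = np.array([[1.0], [3.0], [np.nan]])
        x_test = np.array([[np.nan]])
        tr, te = det._scale_impute(x_train, x_test)
        # scaled train mean of observed cells is 0: missing cells become 0
        assert te[0, 0] == pytest.approx(tr[:2].mean(), abs=1e-12)


class TestTransfer:
    def test_self_transfer_identical_to_evaluate(self, informative_cohort):
        feats = ["f01", "f06", "f11"]
        a = det.evaluate(informative_cohort, feats, "logistic",
                         {"C": 1.0}, n_iterations=25, seed=7)
        b = det.transfer_evaluate(feats, {"C": 1.0}, informative_cohort,
                                  "logistic", n_iterations=25, seed=7)
        assert np.array_equal(a.accuracy, b.accuracy)

    def test_missing_feature_is_schema_error(self, informative_cohort):
        from paravox.errors import SchemaError

        with pytest.raises(SchemaError):
            det.transfer_evaluate(["nope"], None, informative_cohort,
                                  "logistic", n_iterations=2, seed=0)

    def test_frozen_transfer_degrades_under_shift(self):
        wins = 0
        for seed in range(6):
            src, tgt = pv.synth_cohort(
                pv.CohortSpec(
                    n_per_class=30, n_features=33,
                    informative=(0, 5, 10, 20, 30), effect_sizes=(1.5,) * 5,
                    shift_mean=1.0, shift_scale=2.0,
                    shift_informative_only=True, seed=seed,
                )
            )
            feats = ["f01", "f06", "f11", "f21", "f31"]
            ind = det.evaluate(src, feats, "logistic", n_iterations=40, seed=seed)
            tr = det.transfer_evaluate(
                feats, None, tgt, "logistic", n_iterations=40, seed=seed,
                source=src, retrain_on_target=False,
            )
            wins += ind.accuracy.mean() > tr.accuracy.mean()
        assert wins >= 5

    def test_null_target_chance_level(self):
        accs = []
        for seed in range(5):
            t = pv.synth_cohort(
                pv.CohortSpec(n_per_class=30, n_features=10, seed=300 + seed)
            )
            rep = det.transfer_evaluate(
                ["f01", "f02"], None, t, "logistic", n_iterations=100, seed=seed
            )
            accs.append(rep.accuracy.mean())
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)


class TestCompareReports:
    def test_identical_reports_not_significant(self, informative_cohort):
        rep = det.evaluate(informative_cohort, None, "logistic",
                           n_iterations=20, seed=0)
        out = det.compare_reports(rep, rep)
        assert out["accuracy"]["t"] == 0.0
        assert not out["accuracy"]["significant"]

    def test_separated_samples_significant(self, informative_cohort):
        rng = np.random.default_rng(0)
        a = det.evaluate(informative_cohort, None, "logistic",
                         n_iterations=20, seed=0)
        b = det.evaluate(informative_cohort, None, "logistic",
                         n_iterations=20, seed=0)
        a.accuracy = rng.normal(0.9, 0.07, 1000)
        b.accuracy = rng.normal(0.7, 0.10, 1000)
        out = det.compare_reports(a, b)
        assert out["accuracy"]["p"] < 1e-3

    def test_matches_textbook_t_oracle(self, informative_cohort):
        rng = np.random.default_rng(1)
        rep1 = det.evaluate(informative_cohort, None, "logistic",
                            n_iterations=10, seed=0)
        rep2 = det.evaluate(informative_cohort, None, "logistic",
                            n_iterations=10, seed=1)
        for _ in range(10):
            rep1.auc = rng.normal(0.8, 0.05, 200)
            rep2.auc = rng.normal(0.78, 0.06, 150)
            out = det.compare_reports(rep1, rep2)
            t_ref, p_ref = student_t_oracle(rep1.auc, rep2.auc)
            assert out["auc"]["t"] == pytest.approx(t_ref, abs=1e-10)
            assert out["auc"]["p"] == pytest.approx(p_ref, abs=1e-10)


class TestFamilies:
    @pytest.mark.parametrize("family", det.FAMILIES)
    def test_every_family_fits_and_scores(self, family, informative_cohort):
        hp = None
        if family in ("random_forest", "gradient_boosting"):
            hp = {"n_estimators": 20}
        rep = det.evaluate(informative_cohort, None, family, hp,
                           n_iterations=5, seed=0)
        assert rep.accuracy.size == 5
        assert np.all(rep.auc >= 0.0)
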