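"""Classifier registry, validation schemes, and the experiment harness."""

import numpy as np
import pandas as pd
import pytest

from vasomap.classify import (
    ClassifierSpec,
    ExperimentSpec,
    RUSBoostClassifier,
    ValidationScheme,
    accuracy,
    build_classifier,
    compare_rules,
    run_experiment,
    train_eval,
)
from vasomap.features import FEATURE_NAMES


def _separable(n=60, p=17, gap=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    X[y == "b", 0] += gap
    return X, y


class TestAccuracy:
    def test_direct_formula(self):
        pred = [1, 1, 1, 1, 1, 1, 1, 1, 1, 0]  # 9 of 10 correct
        truth = [1] * 10
        assert accuracy(pred, truth) == 90.0

    def test_all_correct(self):
        assert accuracy(["x", "y"], ["x", "y"]) == 100.0

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = rng.integers(1, 30)
            p = rng.integers(0, 2, n)
            t = rng.integers(0, 2, n)
            naive = 100.0 * sum(int(a == b) for a, b in zip(p, t)) / n
            assert accuracy(p, t) == pytest.approx(naive)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy([], [])


class TestRegistry:
    @pytest.mark.parametrize(
        "family,kernel",
        [
            ("svm", "linear"), ("svm", "quadratic"), ("svm", "cubic"), ("svm", "gaussian"),
            ("knn", "euclidean"), ("knn", "cosine"), ("knn", "minkowski"),
            ("decision_tree", None), ("linear_discriminant", None),
            ("quadratic_discriminant", None), ("logistic_regression", None),
            ("feedforward_nn", (10, 8)), ("ensemble", "adaboost"),
            ("ensemble", "bagged_trees"), ("ensemble", "rusboost"),
        ],
    )
    def test_every_grid_entry_fits_and_predicts(self, family, kernel):
        X, y = _separable(n=40, seed=2)
        clf = build_classifier(ClassifierSpec(family, kernel))
        clf.fit(X, y)
        assert accuracy(clf.predict(X), y) > 80.0

    def test_illegal_kernel_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("svm", "cosine")

    def test_rusboost_handles_imbalance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(110, 5))
        y = np.array(["maj"] * 100 + ["min"] * 10)
        X[y == "min"] += 3.0
        clf = RUSBoostClassifier(random_state=0).fit(X, y)
        pred = clf.predict(X)
        minority_recall = (pred[y == "min"] == "min").mean()
        assert minority_recall >= 0.8


class TestTrainEval:
    def test_separable_holdout_is_perfect(self):
        X, y = _separable(gap=8.0, seed=4)
        acc, recs = train_eval(
            X, y, ClassifierSpec("svm", "linear"),
            ValidationScheme("holdout", holdout_fraction=0.2, rng_seed=0),
        )
        assert acc == 100.0
        assert len(recs) == 1

    def test_loo_accuracy_is_mean_of_single_sample_folds(self):
        X, y = _separable(n=30, gap=2.0, seed=5)
        acc, recs = train_eval(
            X, y, ClassifierSpec("knn", "euclidean"), ValidationScheme("leave_one_out")
        )
        assert len(recs) == len(y)
        assert acc == pytest.approx(np.mean([r["fold_accuracy"] for r in recs]))

    def test_duplicated_points_classified_by_their_twins(self):
        # each point appears 6 times, so leave-one-out nearest neighbors are
        # exact copies with the same label
        rng = np.random.default_rng(6)
        base = rng.normal(size=(8, 5))
        X = np.repeat(base, 6, axis=0)
        y = np.repeat(np.array(["a", "b"] * 4), 6)
        acc, _ = train_eval(
            X, y, ClassifierSpec("knn", "euclidean"), ValidationScheme("leave_one_out")
        )
        assert acc == 100.0

    def test_permuted_labels_score_at_chance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 17))
        accs = []
        for seed in range(20):
            y = np.array(["a", "b"] * 30)
            rng.shuffle(y)
            acc, _ = train_eval(
                X, y, ClassifierSpec("logistic_regression"),
                ValidationScheme("kfold", k=5, rng_seed=seed),
            )
            accs.append(acc)
        assert np.mean(accs) == pytest.approx(50.0, abs=7.0)

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        y = np.array(["a"] * 10)
        with pytest.raises(ValueError):
            train_eval(X, y, ClassifierSpec("svm"), ValidationScheme("holdout"))


def _cohort_frame(n_normo=68, n_hyper=48, seed=0):
    rng = np.random.default_rng(seed)
    n = n_normo + n_hyper
    X = rng.normal(size=(n, 17))
    labels = np.array(["normotensive"] * n_normo + ["hypertensive"] * n_hyper)
    X[labels == "hypertensive", 1] += 3.0
    df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    df["label_systolic"] = labels
    return df


class TestExperiments:
    def test_single_cell_grid_gives_one_row(self):
        df = _cohort_frame()
        spec = ExperimentSpec(
            labeling_rule="systolic",
            classifiers=(ClassifierSpec("svm", "linear"),),
            validations=(ValidationScheme("holdout", holdout_fraction=0.25, rng_seed=1),),
        )
        table = run_experiment(spec, df)
        assert len(table) == 1
        assert table.loc[0, "n_subjects"] == 116

    def test_balanced_experiment_reports_designed_size(self):
        df = _cohort_frame()
        spec = ExperimentSpec(
            labeling_rule="systolic",
            classifiers=(ClassifierSpec("knn", "euclidean"),),
            validations=(ValidationScheme("kfold", k=5, rng_seed=2),),
            balance=True,
        )
        table = run_experiment(spec, df)
        assert (table["n_subjects"] == 136).all()

    def test_rerun_is_identical(self):
        df = _cohort_frame()
        spec = ExperimentSpec(
            labeling_rule="systolic",
            classifiers=(ClassifierSpec("svm", "gaussian"), ClassifierSpec("decision_tree")),
            validations=(ValidationScheme("kfold", k=4, rng_seed=3),),
            balance=True,
        )
        a = run_experiment(spec, df)
        b = run_experiment(spec, df)
        pd.testing.assert_frame_equal(a, b)

    def test_rows_sorted_by_accuracy(self):
        df = _cohort_frame()
        spec = ExperimentSpec(
            labeling_rule="systolic",
            classifiers=(ClassifierSpec("svm", "linear"), ClassifierSpec("knn", "euclidean"),
                         ClassifierSpec("decision_tree")),
            validations=(ValidationScheme("holdout", holdout_fraction=0.2, rng_seed=4),),
        )
        table = run_experiment(spec, df)
        assert list(table["accuracy"]) == sorted(table["accuracy"], reverse=True)

    def test_target_below_majority_rejected(self):
        df = _cohort_frame()
        spec = ExperimentSpec(
            labeling_rule="systolic",
            classifiers=(ClassifierSpec("svm", "linear"),),
            validations=(ValidationScheme("holdout"),),
            balance=True,
            target_per_class=10,
        )
        with pytest.raises(ValueError):
            run_experiment(spec, df)

    def test_balance_before_split_runs(self):
        df = _cohort_frame()
        spec = ExperimentSpec(
            labeling_rule="systolic",
            classifiers=(ClassifierSpec("svm", "linear"),),
            validations=(ValidationScheme("kfold", k=5, rng_seed=5),),
            balance=True,
            target_per_class=100,
            balance_before_split=True,
        )
        table = run_experiment(spec, df)
        assert (table["n_subjects"] == 200).all()
        assert 0 <= table.loc[0, "accuracy"] <= 100


class TestCompareRules:
    def test_three_rules_three_rows(self):
        tables = {
            r: pd.DataFrame(
                {"classifier": ["svm"], "kernel_or_parameter": ["linear"],
                 "validation": ["10-fold"], "accuracy": [80.0 + i]}
            )
            for i, r in enumerate(["systolic", "diastolic", "map"])
        }
        out = compare_rules(tables)
        assert len(out) == 3
        assert not out["tie"].any()

    def test_exact_tie_reported_and_flagged(self):
        t = pd.DataFrame(
            {"classifier": ["svm", "knn"], "kernel_or_parameter": ["linear", "cosine"],
             "validation": ["5-fold", "5-fold"], "accuracy": [88.0, 88.0]}
        )
        out = compare_rules({"map": t})
        assert len(out) == 2
        assert out["tie"].all()
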