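"""Classifier benchmark harness for the hypertension experiments.

A registry of classifier families (SVM with several kernels, KNN with
several metrics, decision tree, linear/quadratic discriminant, logistic
regression, a small feed-forward network, and boosting/bagging ensembles
including a random-undersampling booster), evaluated under hold-out,
k-fold or leave-one-out validation.  Accuracy is the fraction of correctly
classified held-out samples, in percent.

``run_experiment`` executes one labeled sub-experiment: select the rule's
labels, optionally SMOTE-balance, then evaluate a classifier × validation
grid into a results table sorted by accuracy.  By default balancing is
*leakage-safe* — synthetic samples are generated from training folds only
and held-out samples are always original — while ``balance_before_split=True``
balances the whole cohort before splitting (the historically common but
optimistic ordering).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .balance import SmoteParams, smote

FAMILIES = (
    "svm",
    "knn",
    "decision_tree",
    "linear_discriminant",
    "quadratic_discriminant",
    "logistic_regression",
    "feedforward_nn",
    "ensemble",
)


@dataclass(frozen=True)
class ClassifierSpec:
    family: str
    kernel_or_metric: Optional[object] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        legal = {
            "svm": {"linear", "quadratic", "cubic", "gaussian", None},
            "knn": {"euclidean", "cosine", "minkowski", None},
            "ensemble": {"adaboost", "bagged_trees", "rusboost", None},
        }
        if self.family in legal and self.kernel_or_metric not in legal[self.family]:
            if not (self.family not in legal):
                raise ValueError(
                    f"{self.kernel_or_metric!r} is not a legal kernel/metric for {self.family}"
                )

    @property
    def label(self) -> str:
        k = self.kernel_or_metric
        return f"{self.family}" + (f"/{k}" if k is not None else "")


@dataclass(frozen=True)
class ValidationScheme:
    kind: str  # holdout | kfold | leave_one_out
    holdout_fraction: float = 0.2
    k: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("holdout", "kfold", "leave_one_out"):
            raise ValueError(f"unknown validation kind {self.kind!r}")
        if self.kind == "holdout" and not (0.0 < self.holdout_fraction < 1.0):
            raise ValueError("holdout fraction must be in (0, 1)")
        if self.kind == "kfold" and self.k < 2:
            raise ValueError("k must be >= 2")

    @property
    def label(self) -> str:
        if self.kind == "holdout":
            return f"{self.holdout_fraction:.0%} holdout"
        if self.kind == "kfold":
            return f"{self.k}-fold"
        return "leave-one-out"


class RUSBoostClassifier(BaseEstimator, ClassifierMixin):
    """Boosting with per-round random undersampling of the majority class.

    A compact SAMME loop: each round fits a decision stump on a class-
    balanced, weight-proportional subsample, then reweights the full
    training set as in discrete AdaBoost.
    """

    def __init__(self, n_estimators: int = 30, max_depth: int = 1, random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, yi = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("binary problems only")
        rng = np.random.default_rng(self.random_state)
        n = len(y)
        w = np.full(n, 1.0 / n)
        self.estimators_, self.alphas_ = [], []
        n_min = min(np.bincount(yi))
        for _ in range(self.n_estimators):
            # weight-proportional undersample of each class to minority size
            idx = []
            for c in (0, 1):
                members = np.nonzero(yi == c)[0]
                p = w[members] / w[members].sum()
                take = min(n_min, len(members))
                idx.append(rng.choice(members, size=take, replace=False, p=p))
            sub = np.concatenate(idx)
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth,
                random_state=int(rng.integers(0, 2**31 - 1)),
            ).fit(X[sub], yi[sub])
            pred = tree.predict(X)
            err = float(w[pred != yi].sum())
            if err >= 0.5:
                continue
            err = max(err, 1e-10)
            alpha = 0.5 * np.log((1 - err) / err)
            w = w * np.exp(alpha * np.where(pred == yi, -1.0, 1.0))
            w = w / w.sum()
            self.estimators_.append(tree)
            self.alphas_.append(alpha)
        if not self.estimators_:  # nothing beat chance; fall back to one stump
            tree = DecisionTreeClassifier(max_depth=self.max_depth, random_state=0).fit(X, yi)
            self.estimators_, self.alphas_ = [tree], [1.0]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        score = np.zeros(len(X))
        for tree, a in zip(self.estimators_, self.alphas_):
            score += a * (2.0 * tree.predict(X) - 1.0)
        return self.classes_[(score > 0).astype(int)]


def build_classifier(spec: ClassifierSpec):
    """Instantiate the scikit-learn (or local) estimator for a spec."""
    seed = spec.rng_seed
    fam, k = spec.family, spec.kernel_or_metric
    if fam == "svm":
        kernels = {
            "linear": dict(kernel="linear"),
            "quadratic": dict(kernel="poly", degree=2),
            "cubic": dict(kernel="poly", degree=3),
            "gaussian": dict(kernel="rbf"),
            None: dict(kernel="rbf"),
        }
        return SVC(random_state=seed, **kernels[k])
    if fam == "knn":
        metric = k or "euclidean"
        kwargs = dict(metric=metric, n_neighbors=5)
        if metric == "minkowski":
            kwargs["p"] = 3  # distinct from the Euclidean (p = 2) entry
        return KNeighborsClassifier(**kwargs)
    if fam == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if fam == "linear_discriminant":
        return LinearDiscriminantAnalysis()
    if fam == "quadratic_discriminant":
        return QuadraticDiscriminantAnalysis(reg_param=1e-3)
    if fam == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if fam == "feedforward_nn":
        hidden = k if isinstance(k, tuple) else (10, 8)
        return MLPClassifier(
            hidden_layer_sizes=hidden, max_iter=400, random_state=seed
        )
    if fam == "ensemble":
        if k == "adaboost" or k is None:
            return AdaBoostClassifier(random_state=seed)
        if k == "bagged_trees":
            return BaggingClassifier(
                DecisionTreeClassifier(random_state=seed),
                n_estimators=30,
                random_state=seed,
            )
        return RUSBoostClassifier(random_state=seed)
    raise ValueError(fam)


def accuracy(predictions: Sequence, truth: Sequence) -> float:
    """Percent of correctly classified samples: 100 · correct / total."""
    p = np.asarray(predictions)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError("prediction and truth lengths differ")
    if p.size == 0:
        raise ValueError("empty label sequences")
    return 100.0 * float((p == t).mean())


def _smote_augment_train(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    smote_params: Optional[SmoteParams],
    target_per_class: Optional[int],
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Oversample a training split so classes are balanced (optionally up
    to a per-class target scaled to the split size)."""
    if smote_params is None:
        return X_tr, y_tr
    classes, counts = np.unique(y_tr, return_counts=True)
    target = counts.max() if target_per_class is None else max(target_per_class, counts.max())
    Xs, ys = [X_tr], [y_tr]
    for c, n in zip(classes, counts):
        need = int(target - n)
        if need <= 0:
            continue
        members = X_tr[y_tr == c]
        k = min(smote_params.k_neighbors, len(members) - 1)
        if k < 1:
            continue
        pars = SmoteParams(
            k_neighbors=k, variant=smote_params.variant, rng_seed=smote_params.rng_seed
        )
        synth = smote(members, pars, n_synthetic=need, rng=rng)
        Xs.append(synth)
        ys.append(np.full(need, c, dtype=y_tr.dtype))
    return np.vstack(Xs), np.concatenate(ys)


def train_eval(
    features: np.ndarray,
    labels: np.ndarray,
    clf: ClassifierSpec,
    val: ValidationScheme,
    smote_params: Optional[SmoteParams] = None,
    target_per_class: Optional[int] = None,
    max_refolds: int = 5,
) -> Tuple[float, List[dict]]:
    """Train on the training portion only and score held-out samples.

    Returns (accuracy percent, per-fold records).  When ``smote_params`` is
    given, synthetic balancing is fitted inside each training portion
    (leakage-safe).  A fold whose training part degenerates to one class is
    re-split with a new seed, up to ``max_refolds`` times.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    est = build_classifier(clf)
    rng = np.random.default_rng(val.rng_seed)

    def folds(seed: int):
        if val.kind == "holdout":
            idx = np.arange(len(y))
            tr, te = train_test_split(
                idx, test_size=val.holdout_fraction, random_state=seed, stratify=y
            )
            return [(tr, te)]
        if val.kind == "kfold":
            kf = StratifiedKFold(n_splits=min(val.k, min(np.bincount(pd.factorize(y)[0]))),
                                 shuffle=True, random_state=seed)
            return list(kf.split(X, y))
        return [(np.delete(np.arange(len(y)), i), np.array([i])) for i in range(len(y))]

    records: List[dict] = []
    correct = total = 0
    for fold_id, (tr, te) in enumerate(folds(val.rng_seed)):
        seed = val.rng_seed
        for _attempt in range(max_refolds):
            if len(np.unique(y[tr])) >= 2:
                break
            seed += 1  # degenerate training fold: re-split with a new seed
            resplit = folds(seed)
            tr, te = resplit[min(fold_id, len(resplit) - 1)]
        else:
            raise ValueError("could not form a training fold with both classes")
        X_tr, y_tr = _smote_augment_train(X[tr], y[tr], smote_params, target_per_class, rng)
        model = clone(est) if hasattr(est, "get_params") else build_classifier(clf)
        model.fit(X_tr, y_tr)
        pred = model.predict(X[te])
        n_ok = int((pred == y[te]).sum())
        correct += n_ok
        total += len(te)
        records.append(
            {
                "fold": fold_id,
                "n_train": len(y_tr),
                "n_test": len(te),
                "fold_accuracy": 100.0 * n_ok / len(te),
                "seed": seed,
            }
        )
    return 100.0 * correct / total, records


@dataclass(frozen=True)
class ExperimentSpec:
    """One sub-experiment: a labeling rule, a balancing plan, and a
    classifier × validation grid."""

    labeling_rule: str  # systolic | diastolic | map
    classifiers: Tuple[ClassifierSpec, ...]
    validations: Tuple[ValidationScheme, ...]
    balance: bool = False
    target_per_class: Optional[int] = None  # None = balance to majority
    smote_params: SmoteParams = field(default_factory=SmoteParams)
    balance_before_split: bool = False  # balance before splitting (leaks; fidelity only)

    def __post_init__(self) -> None:
        if self.labeling_rule not in ("systolic", "diastolic", "map"):
            raise ValueError("labeling_rule must be systolic, diastolic or map")


def run_experiment(
    spec: ExperimentSpec,
    cohort: pd.DataFrame,
    feature_cols: Optional[List[str]] = None,
) -> pd.DataFrame:
    """Execute one experiment over a labeled feature table.

    ``cohort`` must contain the 17 feature columns plus a
    ``label_<rule>`` column; rows labeled "excluded" are dropped.  Returns
    one row per (classifier, validation) pair, sorted by accuracy
    descending, with the designed number of subjects reported.
    """
    label_col = f"label_{spec.labeling_rule}"
    if label_col not in cohort.columns:
        raise ValueError(f"cohort lacks column {label_col}")
    if feature_cols is None:
        from .features import FEATURE_NAMES

        feature_cols = [c for c in FEATURE_NAMES if c in cohort.columns]
    data = cohort[cohort[label_col] != "excluded"]
    X = data[feature_cols].to_numpy(float)
    y = data[label_col].to_numpy()
    counts = pd.Series(y).value_counts()
    if len(counts) < 2:
        raise ValueError("fewer than two classes after exclusion")
    if spec.target_per_class is not None and spec.target_per_class < counts.max():
        raise ValueError(
            f"target {spec.target_per_class} per class is below the largest "
            f"original class ({counts.max()})"
        )
    if spec.balance:
        designed_n = 2 * (spec.target_per_class or counts.max())
    else:
        designed_n = int(counts.sum())

    smote_params = spec.smote_params if spec.balance else None
    if spec.balance and spec.balance_before_split:
        # historical ordering: balance the whole set, then split
        rng = np.random.default_rng(spec.smote_params.rng_seed)
        X, y = _smote_augment_train(X, y, spec.smote_params, spec.target_per_class, rng)
        smote_params = None

    rows = []
    for clf, val in itertools.product(spec.classifiers, spec.validations):
        acc, recs = train_eval(
            X,
            y,
            clf,
            val,
            smote_params=smote_params,
            target_per_class=spec.target_per_class,
        )
        rows.append(
            {
                "classifier": clf.family,
                "kernel_or_parameter": str(clf.kernel_or_metric),
                "validation": val.label,
                "n_subjects": designed_n,
                "accuracy": acc,
                "n_folds": len(recs),
            }
        )
    table = pd.DataFrame(rows).sort_values("accuracy", ascending=False, kind="stable")
    return table.reset_index(drop=True)


def compare_rules(results: Dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Best accuracy per labeling rule, one summary row each.

    ``results`` maps rule name → results table from :func:`run_experiment`.
    Exact ties for the best row within a rule are all reported and flagged.
    """
    rows = []
    for rule, table in results.items():
        best = table["accuracy"].max()
        winners = table[table["accuracy"] == best]
        tie = len(winners) > 1
        for _, r in winners.iterrows():
            rows.append(
                {
                    "rule": rule,
                    "classifier": r["classifier"],
                    "kernel_or_parameter": r["kernel_or_parameter"],
                    "validation": r["validation"],
                    "best_accuracy": best,
                    "tie": tie,
                }
            )
    return pd.DataFrame(rows)
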