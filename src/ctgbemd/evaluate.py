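"""Classifier training and the repeated hold-out evaluation harness.

Three classifier families are supported: a coarse Gini decision tree, a
Gaussian-kernel SVM (box constraint and kernel scale tuned by validation
accuracy on an inner split), and AdaBoost over 20 decision stumps. Evaluation
is a stratified 80/20 hold-out repeated over independent seeded runs; the
per-run pipeline is

    split -> impute (train medians) -> [SMOTE balance, training rows only]
          -> normalize (fit on training rows) -> train -> score test rows

and the four reported metrics are sensitivity (cesarean recall), specificity
(vaginal recall), trapezoidal ROC AUC with cesarean as the positive class,
and MSE of the 0/1 labels (= misclassification fraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .pipeline import (CESAREAN, FeatureMatrix, apply_normalization,
                       impute_train_median, normalize, smote_balance)

_SVM_C_GRID = (0.1, 1.0, 10.0, 100.0)
_SVM_GAMMA_GRID = (0.01, 0.1, 1.0)


@dataclass(frozen=True)
class ClassifierSpec:
    """Configuration of one classifier family.

    tree: Gini split criterion with a coarse complexity cap (few leaves).
    svm: Gaussian (RBF) kernel; box constraint / kernel scale searched over a
    small logarithmic grid by inner-validation accuracy. adaboost: SAMME
    boosting of depth-1 trees (stumps).
    """

    kind: str = "adaboost"                 # tree | svm | adaboost
    tree_max_leaf_nodes: int = 4
    svm_c_grid: tuple[float, ...] = _SVM_C_GRID
    svm_gamma_grid: tuple[float, ...] = _SVM_GAMMA_GRID
    n_weak_learners: int = 20
    learning_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("tree", "svm", "adaboost"):
            raise ValueError(f"unknown classifier kind: {self.kind!r}")
        if self.n_weak_learners < 1:
            raise ValueError("n_weak_learners must be >= 1")


class FittedModel:
    """Thin wrapper exposing labels and a continuous cesarean score."""

    def __init__(self, est, search_log: dict | None = None):
        self.est = est
        self.search_log = search_log or {}

    def predict(self, X) -> np.ndarray:
        return self.est.predict(X)

    def score_positive(self, X) -> np.ndarray:
        if hasattr(self.est, "decision_function"):
            return np.asarray(self.est.decision_function(X), float)
        return np.asarray(self.est.predict_proba(X)[:, 1], float)


def train(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, seed: int = 0) -> FittedModel:
    """Fit the configured classifier; deterministic for a fixed seed."""
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    if spec.kind == "tree":
        est = DecisionTreeClassifier(criterion="gini",
                                     max_leaf_nodes=spec.tree_max_leaf_nodes,
                                     random_state=seed)
        return FittedModel(est.fit(X, y))
    if spec.kind == "adaboost":
        est = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=spec.n_weak_learners,
            learning_rate=spec.learning_rate,
            random_state=seed,
        )
        return FittedModel(est.fit(X, y))
    # Gaussian SVM with inner validation search for (C, gamma)
    Xtr, Xval, ytr, yval = train_test_split(X, y, test_size=0.25,
                                            random_state=seed, stratify=y)
    best, best_acc = None, -1.0
    for c in spec.svm_c_grid:
        for g in spec.svm_gamma_grid:
            acc = SVC(kernel="rbf", C=c, gamma=g).fit(Xtr, ytr).score(Xval, yval)
            if acc > best_acc:
                best, best_acc = (c, g), acc
    c, g = best
    est = SVC(kernel="rbf", C=c, gamma=g).fit(X, y)
    return FittedModel(est, {"C": c, "gamma": g, "val_accuracy": best_acc})


def holdout_split(X: np.ndarray, y: np.ndarray, test_frac: float = 0.2,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random hold-out split; returns (train_idx, test_idx).

    Stratification keeps both classes on both sides even under heavy
    imbalance (an unstratified 20% test set can easily contain zero minority
    rows).
    """
    idx = np.arange(np.asarray(y).size)
    tr, te = train_test_split(idx, test_size=test_frac, random_state=seed,
                              stratify=y)
    return np.sort(tr), np.sort(te)


def evaluate(y_true: np.ndarray, y_pred: np.ndarray,
             scores: np.ndarray) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, auc, mse), cesarean (1) positive."""
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    if np.unique(y_true).size < 2:
        raise ValueError("metrics undefined: y_true contains one class")
    pos = y_true == CESAREAN
    sens = float(np.mean(y_pred[pos] == CESAREAN))
    spec = float(np.mean(y_pred[~pos] != CESAREAN))
    auc = float(roc_auc_score(y_true, scores))
    mse = float(np.mean((y_true - y_pred) ** 2))
    return sens, spec, auc, mse


@dataclass
class EvalResult:
    """Per-run and aggregated metrics of a repeated hold-out experiment."""

    per_run: list[tuple[float, float, float, float]]
    seeds: list[int]
    config: dict = field(default_factory=dict)

    _METRICS = ("sensitivity", "specificity", "auc", "mse")

    @property
    def n_runs(self) -> int:
        return len(self.per_run)

    def mean(self) -> dict[str, float]:
        arr = np.asarray(self.per_run)
        return dict(zip(self._METRICS, arr.mean(axis=0)))

    def stderr(self) -> dict[str, float]:
        arr = np.asarray(self.per_run)
        se = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 \
            else np.zeros(4)
        return dict(zip(self._METRICS, se))

    def to_dict(self) -> dict:
        return {
            "per_run": [dict(zip(self._METRICS, r)) for r in self.per_run],
            "mean": self.mean(),
            "stderr": self.stderr(),
            "n_runs": self.n_runs,
            "seeds": self.seeds,
            "config": self.config,
        }


def run_experiment(fm: FeatureMatrix, spec: ClassifierSpec | None = None,
                   n_runs: int = 30, balance: bool = True, seed0: int = 0,
                   test_frac: float = 0.2, over_pct: int = 400,
                   under_pct: int = 100) -> EvalResult:
    """Repeated stratified hold-out evaluation.

    Every run re-splits, re-balances (training rows only) and re-normalizes
    (parameters fit on the training rows, then applied to the untouched test
    rows); per-run seeds are ``seed0 + run``. The input matrix is never
    mutated.
    """
    spec = spec or ClassifierSpec()
    per_run: list[tuple[float, float, float, float]] = []
    seeds: list[int] = []
    for r in range(n_runs):
        seed = int(seed0) + r
        seeds.append(seed)
        tr, te = holdout_split(fm.X, fm.y, test_frac=test_frac, seed=seed)
        X = impute_train_median(fm.X, tr)
        Xtr, ytr = X[tr], fm.y[tr]
        if balance:
            Xtr, ytr = smote_balance(Xtr, ytr, over_pct=over_pct,
                                     under_pct=under_pct, seed=seed)
        train_fm = normalize(FeatureMatrix(Xtr, ytr, fm.feature_names))
        keep = [fm.feature_names.index(n) for n in train_fm.feature_names]
        Xte = apply_normalization(X[te][:, keep], train_fm.normalization_params)
        model = train(spec, train_fm.X, train_fm.y, seed=seed)
        y_pred = model.predict(Xte)
        scores = model.score_positive(Xte)
        per_run.append(evaluate(fm.y[te], y_pred, scores))
    return EvalResult(per_run=per_run, seeds=seeds,
                      config={"classifier": spec.kind, "balance": balance,
                              "test_frac": test_frac, "n_runs": n_runs,
                              "over_pct": over_pct, "under_pct": under_pct,
                              "seed0": int(seed0)})
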