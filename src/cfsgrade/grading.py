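"""Training and applying the six grade classifiers.

The experimental protocol: stratified 8:2 train/test split, ten-fold
cross-validation on the training split, final evaluation on the held-out
test split.  Six model kinds share one interface: SVM with a Gaussian
(RBF) kernel, decision tree limited to 4 splits, boosted trees with 30
cycles, Gaussian naive Bayes, k-nearest neighbors with k = 10, and a
100-tree random forest.  Feature scaling is always fitted on the training
side only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .evaluation import MetricReport, confusion_matrix_counts, confusion_metrics, roc_auc

__all__ = [
    "MODEL_KINDS",
    "ModelSpec",
    "SplitPlan",
    "split",
    "make_model",
    "cross_validate",
    "fit_predict",
    "evaluate_grid",
]

MODEL_KINDS = ("SVM", "DT", "BT", "NB", "KNN", "RF")


@dataclass(frozen=True)
class ModelSpec:
    """One classifier kind with its protocol hyperparameters.

    Defaults: Gaussian-kernel SVM (C=1, gamma = 1/(n_features * var)); DT
    with at most 4 splits; boosted trees, 30 cycles; KNN with k=10; RF with
    100 trees.
    """

    kind: str = "SVM"
    seed: int = 0
    dt_max_splits: int = 4
    bt_cycles: int = 30
    knn_k: int = 10
    rf_trees: int = 100
    svm_c: float = 1.0

    def validate(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; expected one of {MODEL_KINDS}")


@dataclass(frozen=True)
class SplitPlan:
    train_fraction: float = 0.8
    cv_folds: int = 10
    stratified: bool = True
    seed: int = 0


def make_model(spec: ModelSpec):
    """Instantiate the scikit-learn estimator for a model spec."""
    spec.validate()
    if spec.kind == "SVM":
        return SVC(kernel="rbf", C=spec.svm_c, gamma="scale", random_state=spec.seed)
    if spec.kind == "DT":
        # "maximum split criterion of 4": at most 4 internal splits
        return DecisionTreeClassifier(max_leaf_nodes=spec.dt_max_splits + 1,
                                      random_state=spec.seed)
    if spec.kind == "BT":
        base = DecisionTreeClassifier(max_leaf_nodes=spec.dt_max_splits + 1)
        return AdaBoostClassifier(estimator=base, n_estimators=spec.bt_cycles,
                                  random_state=spec.seed)
    if spec.kind == "NB":
        return GaussianNB()
    if spec.kind == "KNN":
        return KNeighborsClassifier(n_neighbors=spec.knn_k)
    if spec.kind == "RF":
        return RandomForestClassifier(n_estimators=spec.rf_trees, random_state=spec.seed)
    raise AssertionError


def split(
    X: np.ndarray, y: np.ndarray, plan: SplitPlan | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic stratified train/test split: (X_tr, X_te, y_tr, y_te)."""
    plan = plan or SplitPlan()
    y = np.asarray(y)
    strat = y if plan.stratified else None
    return train_test_split(
        np.asarray(X), y,
        train_size=plan.train_fraction,
        stratify=strat,
        random_state=plan.seed,
    )


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    plan: SplitPlan | None = None,
) -> dict:
    """Stratified k-fold CV on the training split; per-fold scaling is
    fitted on the fold-train side only.  Degenerate single-class folds are
    skipped with a warning; folds are reduced when a class is rarer than
    the fold count."""
    plan = plan or SplitPlan()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    counts = np.bincount(y.astype(int))
    min_class = counts[counts > 0].min()
    folds = plan.cv_folds
    if min_class < folds:
        warnings.warn(f"reducing folds from {folds} to {min_class} (rarest class)")
        folds = max(2, int(min_class))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=plan.seed)
    fold_acc: list[float] = []
    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    for tr, va in skf.split(X, y):
        if len(np.unique(y[tr])) < 2:
            warnings.warn("skipping degenerate single-class fold")
            continue
        scaler = StandardScaler().fit(X[tr])
        model = make_model(spec)
        model.fit(scaler.transform(X[tr]), y[tr])
        pred = model.predict(scaler.transform(X[va]))
        fold_acc.append(float((pred == y[va]).mean()))
        pooled_true.append(y[va])
        pooled_pred.append(pred)
    yt = np.concatenate(pooled_true)
    yp = np.concatenate(pooled_pred)
    classes = np.unique(y)
    report = confusion_metrics(confusion_matrix_counts(yt, yp, classes))
    return {"fold_accuracy": fold_acc, "pooled": report}


def fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    spec: ModelSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit on the training split, score the test split.

    Returns (predicted labels, class scores with one column per class,
    class order).  Scores are class-membership probabilities where the
    model provides them and softmax-normalized one-vs-rest decision values
    for the margin-based SVM; both are valid ROC orderings.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if X_train.ndim != 2 or X_train.shape[1] == 0:
        raise ValueError("empty signature: at least one feature column is required")
    scaler = StandardScaler().fit(X_train)
    model = make_model(spec)
    model.fit(scaler.transform(X_train), y_train)
    Xs = scaler.transform(X_test)
    pred = model.predict(Xs)
    if hasattr(model, "predict_proba"):
        scores = model.predict_proba(Xs)
    else:
        d = model.decision_function(Xs)
        if d.ndim == 1:
            d = np.column_stack([-d, d])
        d = d - d.max(axis=1, keepdims=True)
        scores = np.exp(d) / np.exp(d).sum(axis=1, keepdims=True)
    return pred, scores, model.classes_


def evaluate_grid(
    X_train, y_train, X_test, y_test,
    signatures: dict[str, list[str]],
    feature_names: list[str],
    seed: int = 0,
    kinds=MODEL_KINDS,
) -> dict[str, dict[str, MetricReport]]:
    """Metrics for every (model kind x signature) combination.

    `signatures` maps signature name -> feature-name list; `feature_names`
    gives the column order of X.  Output maps kind -> signature -> report.
    """
    name_to_col = {n: i for i, n in enumerate(feature_names)}
    out: dict[str, dict[str, MetricReport]] = {}
    y_test = np.asarray(y_test)
    for kind in kinds:
        out[kind] = {}
        for sig_name, names in signatures.items():
            cols = [name_to_col[n] for n in names]
            pred, scores, classes = fit_predict(
                np.asarray(X_train)[:, cols], y_train,
                np.asarray(X_test)[:, cols], ModelSpec(kind=kind, seed=seed),
            )
            cm = confusion_matrix_counts(y_test, pred, np.unique(y_train))
            report = confusion_metrics(cm)
            aucs = roc_auc(scores, y_test, classes)
            report.auc_per_class = aucs["per_class"]
            report.auc_micro = aucs["micro"]
            out[kind][sig_name] = report
    return out
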