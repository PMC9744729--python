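"""Eight-classifier stratified cross-validation benchmark.

Binary classification of subjects from the 41 pulse indices with eight
supervised methods — SVM, MLP, GNB, DT, RF, LR, LDA, KNN — under
stratified k-fold (default threefold) cross-validation. Features are
standardized inside each fold (fit on the training split only). Per fold
and on average, the harness reports accuracy (percent), sensitivity,
specificity and AUC with the possible-sarcopenia class positive.

Hyperparameters are fixed and documented rather than searched, so runs
are reproducible: RBF SVM with unit cost, one-hidden-layer 100-unit MLP,
100-tree random forest, k=5 nearest neighbours, defaults elsewhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .exceptions import ValidationError

METHODS = ("SVM", "MLP", "GNB", "DT", "RF", "LR", "LDA", "KNN")
POSITIVE_LABEL = "possible_sarcopenia"


def make_estimator(method: str, seed: int = 0) -> Pipeline:
    """A standardizing pipeline around one of the eight classifiers."""
    if method == "SVM":
        clf = SVC(kernel="rbf", C=1.0)
    elif method == "MLP":
        clf = MLPClassifier(hidden_layer_sizes=(100,), max_iter=500, random_state=seed)
    elif method == "GNB":
        clf = GaussianNB()
    elif method == "DT":
        clf = DecisionTreeClassifier(random_state=seed)
    elif method == "RF":
        clf = RandomForestClassifier(n_estimators=100, random_state=seed)
    elif method == "LR":
        clf = LogisticRegression(max_iter=1000)
    elif method == "LDA":
        clf = LinearDiscriminantAnalysis()
    elif method == "KNN":
        clf = KNeighborsClassifier(n_neighbors=5)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass
class ClassifierReport:
    """Per-fold and averaged confusion-matrix metrics for one method.

    Accuracy is in percent; sensitivity, specificity and AUC are fractions.
    The averages are always the arithmetic means of the fold values.
    """

    method: str
    fold_accuracy: np.ndarray
    fold_sensitivity: np.ndarray
    fold_specificity: np.ndarray
    fold_auc: np.ndarray

    def __post_init__(self) -> None:
        for name in ("fold_accuracy", "fold_sensitivity", "fold_specificity", "fold_auc"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        k = self.fold_accuracy.size
        if any(
            getattr(self, n).size != k
            for n in ("fold_sensitivity", "fold_specificity", "fold_auc")
        ):
            raise ValidationError("fold metric arrays must have equal length")
        if np.any((self.fold_accuracy < 0) | (self.fold_accuracy > 100)):
            raise ValidationError("accuracy must lie in [0, 100] percent")
        for n in ("fold_sensitivity", "fold_specificity", "fold_auc"):
            v = getattr(self, n)
            if np.any((v[~np.isnan(v)] < 0) | (v[~np.isnan(v)] > 1)):
                raise ValidationError(f"{n} must lie in [0, 1]")

    @property
    def average_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def average_sensitivity(self) -> float:
        return float(np.mean(self.fold_sensitivity))

    @property
    def average_specificity(self) -> float:
        return float(np.mean(self.fold_specificity))

    @property
    def average_auc(self) -> float:
        return float(np.mean(self.fold_auc))


def metrics_from_confusion(
    tp: int, fp: int, tn: int, fn: int
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) as fractions.

    Ratios with a zero denominator are returned as NaN, never as 0.
    """
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise ValidationError("confusion counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise ValidationError("confusion matrix is empty")
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return float(accuracy), float(sensitivity), float(specificity)


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC via the Mann-Whitney rank statistic; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present for AUC")
    ranks = rankdata(scores)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _decision_scores(model: Pipeline, x: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        try:
            return model.predict_proba(x)[:, 1]
        except AttributeError:
            pass
    return model.decision_function(x)


def run_cv(
    features: pd.DataFrame,
    labels: np.ndarray,
    methods: tuple[str, ...] = METHODS,
    k: int = 3,
    seed: int = 7,
    positive_label=POSITIVE_LABEL,
) -> list[ClassifierReport]:
    """Stratified k-fold benchmark of the requested methods.

    The same seeded fold split is reused for every method. AUC per fold is
    computed from each method's continuous decision score (probability or
    decision value), not from hard labels.
    """
    x = features.to_numpy(dtype=float)
    y = np.asarray(labels) == positive_label
    if not y.any() or y.all():
        raise ValidationError("both classes must be present")
    if min(int(y.sum()), int((~y).sum())) < k:
        raise ValidationError(
            f"need at least {k} subjects per class for {k} stratified folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(x, y))

    reports = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in methods:
            acc, sens, spec, auc = [], [], [], []
            for train, test in folds:
                model = make_estimator(method, seed=seed)
                model.fit(x[train], y[train])
                pred = model.predict(x[test]).astype(bool)
                truth = y[test]
                tp = int(np.sum(pred & truth))
                fp = int(np.sum(pred & ~truth))
                tn = int(np.sum(~pred & ~truth))
                fn = int(np.sum(~pred & truth))
                a, se, sp = metrics_from_confusion(tp, fp, tn, fn)
                acc.append(100.0 * a)
                sens.append(se)
                spec.append(sp)
                auc.append(auc_rank(_decision_scores(model, x[test]), truth))
            reports.append(
                ClassifierReport(
                    method=method,
                    fold_accuracy=np.asarray(acc),
                    fold_sensitivity=np.asarray(sens),
                    fold_specificity=np.asarray(spec),
                    fold_auc=np.asarray(auc),
                )
            )
    return reports


def reports_to_frame(reports: list[ClassifierReport]) -> pd.DataFrame:
    """Tabular report: one row per method and fold, plus an average row."""
    rows = []
    for r in reports:
        for i in range(r.fold_accuracy.size):
            rows.append(
                {
                    "method": r.method,
                    "fold": i + 1,
                    "accuracy_pct": r.fold_accuracy[i],
                    "sensitivity": r.fold_sensitivity[i],
                    "specificity": r.fold_specificity[i],
                    "auc": r.fold_auc[i],
                }
            )
        rows.append(
            {
                "method": r.method,
                "fold": "average",
                "accuracy_pct": r.average_accuracy,
                "sensitivity": r.average_sensitivity,
                "specificity": r.average_specificity,
                "auc": r.average_auc,
            }
        )
    return pd.DataFrame(rows)
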