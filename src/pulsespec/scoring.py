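"""Bar-calibrated additive scoring classifier.

A transparent alternative to black-box classifiers, built in four steps:

1. *Select* the indices that differ at least marginally (p < 0.1) between
   the two classes on a training set.
2. *Calibrate* each selected index by the two class means ("bars"):
   ``m_r`` for robust and ``m_s`` for possible sarcopenia.
3. *Score* a subject on each index with the symmetric piecewise-linear
   map: with ``u = clamp((x - m_s) / (m_r - m_s), 0, 1)``,
   ``score1 = 10 u`` (similarity to the robust bar) and
   ``score2 = 10 (1 - u)``; both lie in [0, 10] and sum to 10, each class
   mean is a fixed point scoring 10 on its own bar, and both orderings of
   the bars are handled by the sign of ``m_r - m_s``.
4. *Average* the per-index score differences (score1 - score2); a positive
   average characterizes the subject as robust, a nonpositive one as
   possible sarcopenia (ties favour the screening-positive class).

Evaluation is in-sample by default (calibrate and score on the same
cohort); :func:`cross_validated_scoring` re-selects and re-calibrates
inside each stratified fold for an optimism-free estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .exceptions import NoInformativeIndicesError, ValidationError
from .groupstats import IndexComparison, compare_two_groups
from .ml import auc_rank, metrics_from_confusion

logger = logging.getLogger(__name__)

ROBUST_LABEL = "robust"
POSSIBLE_LABEL = "possible_sarcopenia"
SELECTED_TIERS = ("significant", "marginal")


@dataclass
class IndexCalibration:
    """Class-mean bars for one selected index."""

    index_name: str
    robust_mean: float
    sarcopenia_mean: float

    @property
    def orientation(self) -> int:
        return 1 if self.robust_mean > self.sarcopenia_mean else -1


@dataclass
class ScoreResult:
    """Per-index scores and the averaged score difference for one subject."""

    score1: dict
    score2: dict
    diff: dict
    average_diff: float
    predicted_class: str


def select_indices(comparisons: list[IndexComparison]) -> list[str]:
    """Indices that differ significantly or marginally between classes."""
    selected = [c.index_name for c in comparisons if c.tier in SELECTED_TIERS]
    if not selected:
        raise NoInformativeIndicesError("no index reaches even marginal significance")
    return selected


def calibrate(
    features: pd.DataFrame,
    labels: np.ndarray,
    selected: list[str],
    *,
    negative_label=ROBUST_LABEL,
    positive_label=POSSIBLE_LABEL,
) -> list[IndexCalibration]:
    """Class-mean bars for each selected index on the training table.

    Indices whose class means coincide carry no orientation and are
    dropped with a logged warning.
    """
    labels = np.asarray(labels)
    neg = features.loc[labels == negative_label]
    pos = features.loc[labels == positive_label]
    if neg.empty or pos.empty:
        raise ValidationError("both classes must be present for calibration")
    calibrations = []
    for name in selected:
        if name not in features.columns:
            raise ValidationError(f"selected index {name!r} missing from features")
        m_r = float(neg[name].mean())
        m_s = float(pos[name].mean())
        if m_r == m_s:
            logger.warning("dropping degenerate index %s (equal class means)", name)
            continue
        calibrations.append(IndexCalibration(name, m_r, m_s))
    if not calibrations:
        raise NoInformativeIndicesError("all selected indices are degenerate")
    return calibrations


def score_subject(x, calibrations: list[IndexCalibration]) -> ScoreResult:
    """Score one subject's feature vector against the calibrated bars."""
    score1, score2, diff = {}, {}, {}
    for cal in calibrations:
        try:
            value = float(x[cal.index_name])
        except (KeyError, IndexError, TypeError) as exc:
            raise ValidationError(
                f"subject lacks calibrated index {cal.index_name!r}"
            ) from exc
        if np.isnan(value):
            raise ValidationError(f"index {cal.index_name!r} is NaN")
        u = (value - cal.sarcopenia_mean) / (cal.robust_mean - cal.sarcopenia_mean)
        u = float(np.clip(u, 0.0, 1.0))
        score1[cal.index_name] = 10.0 * u
        score2[cal.index_name] = 10.0 * (1.0 - u)
        diff[cal.index_name] = score1[cal.index_name] - score2[cal.index_name]
    average = float(np.mean(list(diff.values())))
    predicted = ROBUST_LABEL if average > 0 else POSSIBLE_LABEL
    return ScoreResult(score1, score2, diff, average, predicted)


def score_table(
    features: pd.DataFrame, calibrations: list[IndexCalibration]
) -> pd.DataFrame:
    """Average score difference and predicted class per feature row."""
    rows = []
    for _, row in features.iterrows():
        res = score_subject(row, calibrations)
        rows.append(
            {"average_diff": res.average_diff, "predicted_class": res.predicted_class}
        )
    return pd.DataFrame(rows, index=features.index)


def evaluate_scoring(
    results: list[ScoreResult],
    labels: np.ndarray,
    *,
    positive_label=POSSIBLE_LABEL,
) -> dict:
    """Confusion-matrix metrics and rank AUC with possible sarcopenia
    positive.

    The continuous score for the AUC is the negated average score
    difference (more negative = more robust-like).
    """
    labels = np.asarray(labels)
    if len(results) != labels.shape[0]:
        raise ValidationError("results and labels must align")
    y = labels == positive_label
    if not y.any() or y.all():
        raise ValidationError("both classes must be present for evaluation")
    pred = np.array([r.predicted_class == POSSIBLE_LABEL for r in results])
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    accuracy, sensitivity, specificity = metrics_from_confusion(tp, fp, tn, fn)
    avg = np.array([r.average_diff for r in results])
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "auc": auc_rank(-avg, y),
        "n": int(labels.shape[0]),
    }


def fit_and_score(
    features: pd.DataFrame,
    labels: np.ndarray,
    *,
    negative_label=ROBUST_LABEL,
    positive_label=POSSIBLE_LABEL,
    equal_var: bool = False,
) -> tuple[list[IndexCalibration], list[ScoreResult], dict]:
    """In-sample pipeline: select, calibrate, score and evaluate on one
    table."""
    comparisons = compare_two_groups(features, labels, equal_var=equal_var)
    selected = select_indices(comparisons)
    calibrations = calibrate(
        features,
        labels,
        selected,
        negative_label=negative_label,
        positive_label=positive_label,
    )
    results = [score_subject(row, calibrations) for _, row in features.iterrows()]
    report = evaluate_scoring(results, labels, positive_label=positive_label)
    return calibrations, results, report


def cross_validated_scoring(
    features: pd.DataFrame,
    labels: np.ndarray,
    *,
    k: int = 3,
    seed: int = 0,
    negative_label=ROBUST_LABEL,
    positive_label=POSSIBLE_LABEL,
) -> dict:
    """Fold-honest evaluation: selection and calibration are refit inside
    each stratified fold and only held-out subjects are scored.

    A fold in which no index reaches marginal significance contributes
    zero score differences (no evidence; the tie rule then predicts the
    screening-positive class).
    """
    labels = np.asarray(labels)
    y = labels == positive_label
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    results: list[ScoreResult | None] = [None] * labels.shape[0]
    for train, test in skf.split(features.to_numpy(), y):
        sub = features.iloc[train]
        try:
            comparisons = compare_two_groups(sub, labels[train])
            selected = select_indices(comparisons)
            calibrations = calibrate(
                sub,
                labels[train],
                selected,
                negative_label=negative_label,
                positive_label=positive_label,
            )
        except NoInformativeIndicesError:
            logger.warning("fold without informative indices; scoring zeros")
            for i in test:
                results[i] = ScoreResult({}, {}, {}, 0.0, POSSIBLE_LABEL)
            continue
        for i in test:
            results[i] = score_subject(features.iloc[i], calibrations)
    return evaluate_scoring(results, labels, positive_label=positive_label)


def calibrations_to_frame(calibrations: list[IndexCalibration]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "index": [c.index_name for c in calibrations],
            "robust_mean": [c.robust_mean for c in calibrations],
            "sarcopenia_mean": [c.sarcopenia_mean for c in calibrations],
        }
    )


def calibrations_from_frame(frame: pd.DataFrame) -> list[IndexCalibration]:
    return [
        IndexCalibration(str(r["index"]), float(r["robust_mean"]), float(r["sarcopenia_mean"]))
        for _, r in frame.iterrows()
    ]
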