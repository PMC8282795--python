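"""Confusion matrix, classification metrics, k-fold aggregation, McNemar.

Conventions
-----------
* The confusion matrix uses rows = predicted class, columns = true class.
* Accuracy is trace / total.  Per-class precision is the diagonal over
  the row sum (how often a predicted class is right); per-class recall
  is the diagonal over the column sum (how often a true class is found);
  a zero denominator yields 0.  Reported precision/recall/F1 are
  macro-averages (unweighted class means) by default, with micro and
  support-weighted averaging available — micro-averaging in multiclass
  collapses precision, recall and F1 to the accuracy.
* K-fold summaries report mean and population standard deviation
  (divisor n) over folds.
* McNemar's paired test uses the exact two-sided binomial when the
  discordant count n01 + n10 is below 25, otherwise the chi-square
  approximation with continuity correction (|n01 - n10| - 1)^2 /
  (n01 + n10) on 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .baselines import (
    align_truth,
    average_prob,
    grid_search_weights,
    majority_vote,
    weighted_average,
)
from .fusion import fuse
from .scores_io import LabelVector, ScoreBundle, ValidationError

#: discordant-pair threshold below which the exact binomial test is used.
MCNEMAR_EXACT_THRESHOLD = 25

METRIC_NAMES = ("accuracy", "precision", "recall", "f1")

FUSION_METHODS = ("fuzzy_rank", "majority_vote", "average_prob", "weighted_average")


@dataclass
class ConfusionMatrix:
    """C x C count matrix; rows = predicted class, columns = true class."""

    counts: np.ndarray
    class_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValidationError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValidationError("confusion matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricReport:
    """Accuracy plus averaged precision/recall/F1 and per-class values."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: list[tuple[float, float, float]]
    confusion: ConfusionMatrix
    average: str = "macro"

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_NAMES}


@dataclass
class FoldSummary:
    """Per-fold metric reports with mean and population std per metric."""

    per_fold: list[MetricReport]
    mean: dict[str, float]
    std: dict[str, float]


@dataclass
class McNemarResult:
    """Discordant counts, test statistic and two-sided p-value."""

    n01: int  # model A correct, model B wrong
    n10: int  # model A wrong, model B correct
    statistic: float
    p_value: float
    method: str  # exact_binomial | chi2_continuity


def confusion_matrix(
    predicted: Sequence[int],
    truth,
    n_classes: int,
    class_names: Optional[list[str]] = None,
) -> ConfusionMatrix:
    """Count (predicted, true) pairs into a C x C matrix.

    ``truth`` is either a sequence of 0-based class indices or a
    :class:`LabelVector` (then ``class_names`` is required to map it).
    """
    predicted = np.asarray(predicted, dtype=int)
    if isinstance(truth, LabelVector):
        if class_names is None:
            raise ValidationError("class_names required to map a LabelVector")
        truth = truth.to_indices(class_names)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise ValidationError(
            f"{predicted.shape[0]} predictions but {truth.shape[0]} truth labels"
        )
    if np.any((predicted < 0) | (predicted >= n_classes)):
        raise ValidationError("predicted class index out of range")
    if np.any((truth < 0) | (truth >= n_classes)):
        raise ValidationError("true class index out of range")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (predicted, truth), 1)
    return ConfusionMatrix(counts=counts, class_names=class_names)


def metric_report(cm: ConfusionMatrix, average: str = "macro") -> MetricReport:
    """Compute accuracy, precision, recall and F1 from a confusion matrix.

    ``average`` is ``"macro"`` (default), ``"micro"`` or ``"weighted"``
    (per-class values weighted by true-class support).
    """
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    if average not in ("macro", "micro", "weighted"):
        raise ValidationError(f"unknown averaging mode {average!r}")
    counts = cm.counts.astype(float)
    diag = np.diag(counts)
    pred_totals = counts.sum(axis=1)  # row sums: times each class predicted
    true_totals = counts.sum(axis=0)  # column sums: true support
    accuracy = float(diag.sum() / cm.total)

    with np.errstate(invalid="ignore", divide="ignore"):
        prec_c = np.where(pred_totals > 0, diag / pred_totals, 0.0)
        rec_c = np.where(true_totals > 0, diag / true_totals, 0.0)
        f1_c = np.where(
            prec_c + rec_c > 0, 2 * prec_c * rec_c / (prec_c + rec_c), 0.0
        )
    per_class = list(zip(prec_c.tolist(), rec_c.tolist(), f1_c.tolist()))

    if average == "micro":
        # pooled counts: in single-label multiclass all three equal accuracy
        precision = recall = f1 = accuracy
    elif average == "weighted":
        w = true_totals / true_totals.sum()
        precision = float(np.dot(w, prec_c))
        recall = float(np.dot(w, rec_c))
        f1 = float(np.dot(w, f1_c))
    else:
        precision = float(prec_c.mean())
        recall = float(rec_c.mean())
        f1 = float(f1_c.mean())
    return MetricReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        per_class=per_class,
        confusion=cm,
        average=average,
    )


def predict_with_method(
    bundle: ScoreBundle,
    method: str,
    weights: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Run one fusion method on a bundle and return 0-based predictions."""
    if method == "fuzzy_rank":
        return fuse(bundle).predicted
    if method == "majority_vote":
        return majority_vote(bundle).predicted
    if method == "average_prob":
        return average_prob(bundle).predicted
    if method == "weighted_average":
        if weights is None:
            weights = grid_search_weights(bundle)
        return weighted_average(bundle, weights).predicted
    raise ValidationError(f"unknown fusion method {method!r}; choose from {FUSION_METHODS}")


def stratified_folds(truth: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified partition of sample indices into k folds.

    Within each class, indices are shuffled and dealt round-robin, so
    fold class counts differ by at most one.
    """
    if k < 2:
        raise ValidationError("k must be at least 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(truth):
        idx = np.flatnonzero(truth == cls)
        if len(idx) < k:
            raise ValidationError(
                f"class {cls} has {len(idx)} samples, fewer than k={k}"
            )
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def kfold_evaluate(
    bundle: ScoreBundle,
    k: int = 5,
    seed: int = 0,
    method: str = "fuzzy_rank",
    average: str = "macro",
    weights: Optional[Sequence[float]] = None,
) -> FoldSummary:
    """Evaluate a fusion method per stratified fold and aggregate mean +/- std.

    The base learners are fixed external score producers, so folding
    partitions the evaluation samples only; predictions are computed
    once on the whole bundle and metrics are taken per fold.  For
    ``weighted_average`` without explicit weights, weights are fitted by
    grid search on the complement of each fold (never on the fold
    itself).
    """
    if bundle.labels is None:
        raise ValidationError("k-fold evaluation requires ground-truth labels")
    truth = bundle.truth_indices()
    folds = stratified_folds(truth, k, seed)
    C = bundle.n_classes

    fit_per_fold = method == "weighted_average" and weights is None
    if not fit_per_fold:
        predicted = predict_with_method(bundle, method, weights)

    reports = []
    for fold in folds:
        if fit_per_fold:
            train_idx = np.setdiff1d(np.arange(bundle.n_samples), fold)
            train_bundle = _subset_bundle(bundle, train_idx)
            w = grid_search_weights(train_bundle)
            fold_pred = predict_with_method(_subset_bundle(bundle, fold), method, w)
            reports.append(
                metric_report(confusion_matrix(fold_pred, truth[fold], C), average)
            )
        else:
            reports.append(
                metric_report(
                    confusion_matrix(predicted[fold], truth[fold], C), average
                )
            )
    mean = {m: float(np.mean([r.as_dict()[m] for r in reports])) for m in METRIC_NAMES}
    std = {m: float(np.std([r.as_dict()[m] for r in reports])) for m in METRIC_NAMES}
    return FoldSummary(per_fold=reports, mean=mean, std=std)


def _subset_bundle(bundle: ScoreBundle, idx: np.ndarray) -> ScoreBundle:
    from .scores_io import DecisionScoreSet

    ids = [bundle.sample_ids[i] for i in idx]
    learners = [
        DecisionScoreSet(
            learner_id=ls.learner_id,
            sample_ids=ids,
            class_names=ls.class_names,
            probs=ls.probs[idx].copy(),
        )
        for ls in bundle.learners
    ]
    labels = None
    if bundle.labels is not None:
        labels = LabelVector(ids, [bundle.labels.labels[i] for i in idx])
    return ScoreBundle(learners=learners, labels=labels)


def mcnemar_test(correct_a: Sequence[bool], correct_b: Sequence[bool]) -> McNemarResult:
    """McNemar's paired test on two models' per-sample correctness.

    A small p-value indicates the two models' error patterns differ;
    the conventional rejection rule is p < 0.05.
    """
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError("correctness vectors must have equal length")
    n01 = int(np.sum(a & ~b))
    n10 = int(np.sum(~a & b))
    n = n01 + n10
    if n == 0:
        return McNemarResult(n01=0, n10=0, statistic=0.0, p_value=1.0, method="exact_binomial")
    if n < MCNEMAR_EXACT_THRESHOLD:
        k = min(n01, n10)
        p = min(1.0, 2.0 * float(stats.binom.cdf(k, n, 0.5)))
        return McNemarResult(n01=n01, n10=n10, statistic=float(k), p_value=p, method="exact_binomial")
    statistic = (abs(n01 - n10) - 1) ** 2 / n
    p = float(stats.chi2.sf(statistic, df=1))
    return McNemarResult(n01=n01, n10=n10, statistic=float(statistic), p_value=p, method="chi2_continuity")
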