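"""Baseline late-fusion rules: majority voting and probability averaging.

These are the standard ensemble combiners the fuzzy rank fusion is
benchmarked against.  All operate on the same :class:`ScoreBundle`
interface and break argmax ties toward the lowest class index.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .scores_io import LabelVector, ScoreBundle, ValidationError


@dataclass
class BaselinePrediction:
    """Outcome of one baseline fusion rule on a bundle."""

    method: str  # majority_vote | average_prob | weighted_average
    predicted: np.ndarray  # 0-based class indices
    weights: Optional[np.ndarray] = None
    combined_scores: Optional[np.ndarray] = None


def _check_bundle(bundle: ScoreBundle) -> None:
    if bundle.n_learners < 1:
        raise ValidationError("bundle needs at least one learner")


def majority_vote(bundle: ScoreBundle) -> BaselinePrediction:
    """Each learner votes its argmax class; most votes wins.

    Vote ties are broken by the highest probability summed over learners
    among the tied classes, then by the lowest class index.
    """
    _check_bundle(bundle)
    stacked = bundle.stacked()  # (L, n, C)
    L, n, C = stacked.shape
    votes = np.argmax(stacked, axis=2)  # (L, n)
    counts = np.zeros((n, C), dtype=int)
    for i in range(L):
        np.add.at(counts, (np.arange(n), votes[i]), 1)
    summed = stacked.sum(axis=0)  # (n, C) tie-break key
    # lexicographic: vote count first, then summed probability; argmax
    # itself resolves remaining ties toward the lowest index.
    top = counts == counts.max(axis=1, keepdims=True)
    key = np.where(top, summed, -np.inf)
    predicted = np.argmax(key, axis=1)
    return BaselinePrediction(method="majority_vote", predicted=predicted)


def average_prob(bundle: ScoreBundle) -> BaselinePrediction:
    """Unweighted mean of the learner probability matrices, argmax winner."""
    _check_bundle(bundle)
    combined = bundle.stacked().mean(axis=0)
    return BaselinePrediction(
        method="average_prob",
        predicted=np.argmax(combined, axis=1),
        combined_scores=combined,
    )


def weighted_average(bundle: ScoreBundle, weights: Sequence[float]) -> BaselinePrediction:
    """Convex combination of learner matrices with the given weights.

    Weights must be non-negative with a positive sum; they are
    normalized to sum to 1 internally.
    """
    _check_bundle(bundle)
    w = np.asarray(list(weights), dtype=float)
    if w.shape != (bundle.n_learners,):
        raise ValidationError(
            f"need {bundle.n_learners} weights, got {w.shape[0] if w.ndim == 1 else w.shape}"
        )
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValidationError("weights must be finite and non-negative")
    total = w.sum()
    if total <= 0:
        raise ValidationError("weights must not all be zero")
    w = w / total
    combined = np.tensordot(w, bundle.stacked(), axes=1)
    return BaselinePrediction(
        method="weighted_average",
        predicted=np.argmax(combined, axis=1),
        weights=w,
        combined_scores=combined,
    )


def _simplex_grid(L: int, step: float):
    """All weight vectors on the unit simplex with coordinates k*step."""
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9:
        raise ValidationError(f"step {step} must divide 1")
    for combo in itertools.product(range(m + 1), repeat=L - 1):
        rest = m - sum(combo)
        if rest >= 0:
            yield np.array(combo + (rest,), dtype=float) / m


def grid_search_weights(
    bundle: ScoreBundle,
    labels: Optional[LabelVector] = None,
    step: float = 0.1,
) -> np.ndarray:
    """Exhaustive simplex grid search for accuracy-maximizing weights.

    Ties are broken toward the vector closest to uniform weighting (and
    deterministically by enumeration order beyond that).
    """
    if labels is None:
        labels = bundle.labels
    if labels is None:
        raise ValidationError("grid search requires ground-truth labels")
    truth = align_truth(bundle, labels)
    uniform = np.full(bundle.n_learners, 1.0 / bundle.n_learners)
    best_w, best_acc, best_dist = None, -1.0, np.inf
    # the exact uniform vector is always a candidate even when the grid
    # step cannot represent it, so ties resolve to uniform weighting
    candidates = itertools.chain([uniform], _simplex_grid(bundle.n_learners, step))
    for w in candidates:
        pred = weighted_average(bundle, w).predicted
        acc = float(np.mean(pred == truth))
        dist = float(np.sum((w - uniform) ** 2))
        if acc > best_acc + 1e-12 or (abs(acc - best_acc) <= 1e-12 and dist < best_dist - 1e-12):
            best_w, best_acc, best_dist = w, acc, dist
    return best_w


def align_truth(bundle: ScoreBundle, labels: LabelVector) -> np.ndarray:
    """Truth labels as 0-based indices in the bundle's sample order."""
    pos = {s: i for i, s in enumerate(labels.sample_ids)}
    try:
        ordered = [labels.labels[pos[s]] for s in bundle.sample_ids]
    except KeyError as exc:
        raise ValidationError(f"no label for sample {exc.args[0]!r}") from None
    return LabelVector(bundle.sample_ids, ordered).to_indices(bundle.class_names)
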