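"""Fuzzy rank transforms and the rank-product fusion rule.

Each class probability ``p`` from each base learner is mapped through
two non-linear transforms of opposite concavity:

* the tanh-based rank ``1 - tanh((p-1)^2 / 2)``, increasing in ``p``,
  measuring closeness of the prediction to full confidence, and
* the exponential rank ``1 - exp(-(p-1)^2 / 2)``, decreasing in ``p``,
  measuring deviation from full confidence.

Their product, the *rank score*, decreases strictly with ``p`` and is 0
exactly at ``p = 1``.  Summing rank scores across learners gives the
per-class *fused score*; the class with the smallest fused score is the
ensemble prediction.  Despite the name, no sorting or ordinal ranking
takes place: the ranks are pointwise transforms of the probabilities,
so fusing a sample costs O(L * C) for L learners and C classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .scores_io import DecisionScoreSet, ScoreBundle, ValidationError

PathLike = Union[str, Path]

#: value of the tanh rank at p = 0 (its minimum over [0, 1]).
TANH_RANK_MIN = 1.0 - np.tanh(0.5)
#: value of the exponential rank at p = 0 (its maximum over [0, 1]).
EXP_RANK_MAX = 1.0 - np.exp(-0.5)
#: largest possible rank score, attained at p = 0.
RANK_SCORE_MAX = TANH_RANK_MIN * EXP_RANK_MAX


class DomainError(ValueError):
    """An input probability lies outside [0, 1]."""


def _check_domain(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
        bad = p[(p < -1e-9) | (p > 1 + 1e-9)].flat[0]
        raise DomainError(f"probability {bad} outside [0, 1]")
    return np.clip(p, 0.0, 1.0)


def tanh_rank(p):
    """Tanh-based fuzzy rank ``1 - tanh((p-1)^2 / 2)``.

    Strictly increasing on [0, 1], from ``1 - tanh(0.5)`` at ``p = 0``
    to exactly 1 at ``p = 1``.  Accepts scalars or arrays.
    """
    p = _check_domain(p)
    out = 1.0 - np.tanh((p - 1.0) ** 2 / 2.0)
    return float(out) if out.ndim == 0 else out


def exp_rank(p):
    """Exponential fuzzy rank ``1 - exp(-(p-1)^2 / 2)``.

    Strictly decreasing on [0, 1], from ``1 - exp(-0.5)`` at ``p = 0``
    to exactly 0 at ``p = 1``.  Accepts scalars or arrays.
    """
    p = _check_domain(p)
    out = 1.0 - np.exp(-((p - 1.0) ** 2) / 2.0)
    return float(out) if out.ndim == 0 else out


def rank_score(p):
    """Product of the two fuzzy ranks: strictly decreasing, 0 iff ``p = 1``."""
    p = _check_domain(p)
    d = (p - 1.0) ** 2 / 2.0
    out = (1.0 - np.tanh(d)) * (1.0 - np.exp(-d))
    return float(out) if out.ndim == 0 else out


@dataclass
class FuzzyRankTable:
    """Per-learner fuzzy ranks and rank scores for every sample and class."""

    learner_id: str
    rank_tanh: np.ndarray
    rank_exp: np.ndarray
    rank_score: np.ndarray


@dataclass
class FusedResult:
    """Fused per-class scores and the argmin decision for every sample.

    ``predicted`` holds 0-based class indices; user-facing reports print
    1-based indices or class names.
    """

    sample_ids: list[str]
    class_names: list[str]
    fused_scores: np.ndarray
    predicted: np.ndarray
    per_learner_ranks: list[FuzzyRankTable]

    @property
    def predicted_names(self) -> list[str]:
        return [self.class_names[k] for k in self.predicted]


def compute_rank_table(scores: DecisionScoreSet) -> FuzzyRankTable:
    """Apply both rank transforms elementwise to one learner's matrix."""
    try:
        rt = tanh_rank(scores.probs)
        re_ = exp_rank(scores.probs)
    except DomainError as exc:
        raise DomainError(f"learner {scores.learner_id!r}: {exc}") from None
    return FuzzyRankTable(
        learner_id=scores.learner_id,
        rank_tanh=rt,
        rank_exp=re_,
        rank_score=rt * re_,
    )


def fuse(bundle: ScoreBundle) -> FusedResult:
    """Fuse a bundle: sum rank scores across learners, predict by argmin.

    Ties at the minimum are broken toward the lowest class index, which
    ``np.argmin`` guarantees.
    """
    if bundle.n_learners < 1:
        raise ValidationError("cannot fuse an empty bundle")
    tables = [compute_rank_table(ls) for ls in bundle.learners]
    fused = np.sum([t.rank_score for t in tables], axis=0)
    predicted = np.argmin(fused, axis=1)
    return FusedResult(
        sample_ids=bundle.sample_ids,
        class_names=bundle.class_names,
        fused_scores=fused,
        predicted=predicted,
        per_learner_ranks=tables,
    )


def fusion_report(result: FusedResult, path: PathLike, verbose: bool = False) -> Path:
    """Write per-sample fused scores and the winning class as CSV.

    Columns: ``sample_id``, one ``FS_<class>`` per class, the 1-based
    ``predicted_index`` and the ``predicted_class`` name.  With
    ``verbose`` a companion ``<stem>_ranks.csv`` dumps every learner's
    rank tables.
    """
    if len(result.sample_ids) == 0:
        raise ValidationError("cannot report an empty fusion result")
    path = Path(path)
    df = pd.DataFrame(
        result.fused_scores, columns=[f"FS_{c}" for c in result.class_names]
    )
    df.insert(0, "sample_id", result.sample_ids)
    df["predicted_index"] = result.predicted + 1
    df["predicted_class"] = result.predicted_names
    df.to_csv(path, index=False)
    if verbose:
        rows = []
        for t in result.per_learner_ranks:
            for s, sid in enumerate(result.sample_ids):
                for k, cname in enumerate(result.class_names):
                    rows.append(
                        {
                            "learner_id": t.learner_id,
                            "sample_id": sid,
                            "class": cname,
                            "rank_tanh": t.rank_tanh[s, k],
                            "rank_exp": t.rank_exp[s, k],
                            "rank_score": t.rank_score[s, k],
                        }
                    )
        rank_path = path.with_name(path.stem + "_ranks.csv")
        pd.DataFrame(rows).to_csv(rank_path, index=False, float_format="%.17g")
    return path
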