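"""Decision-score data model and delimited score-table I/O.

A *decision score set* is one base learner's samples x classes matrix of
class probabilities (each row a softmax output summing to 1), together
with sample identifiers and class names.  Several learners evaluated on
the same samples form a *score bundle*, optionally carrying ground-truth
labels.  Tables are exchanged as comma-delimited UTF-8 text with a
header row: a ``sample_id`` column, an optional ``label`` column, and
one column per class named by the class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

PathLike = Union[str, Path]

#: rows whose sum deviates from 1 by at most this much are renormalized;
#: larger deviations are treated as corrupt data.
RENORM_BAND = 1e-3

#: row sums must hold to this tolerance after ingestion.
ROW_SUM_TOL = 1e-6


class ValidationError(ValueError):
    """A score table violates the probability contract (range or row sum)."""


class SchemaError(ValueError):
    """Learners in a bundle disagree on sample ids or class names."""


@dataclass
class DecisionScoreSet:
    """One learner's row-stochastic probability matrix with identifiers.

    Parameters
    ----------
    learner_id : str
        Name of the base learner that produced the scores.
    sample_ids : list of str
        Unique, ordered sample identifiers (one per matrix row).
    class_names : list of str
        Unique, ordered class names (one per matrix column).
    probs : ndarray of shape (n_samples, n_classes)
        Class probabilities; every row sums to 1.
    """

    learner_id: str
    sample_ids: list[str]
    class_names: list[str]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.class_names = [str(c) for c in self.class_names]
        validate_scores(self)

    @property
    def n_samples(self) -> int:
        return self.probs.shape[0]

    @property
    def n_classes(self) -> int:
        return self.probs.shape[1]


@dataclass
class LabelVector:
    """Ground-truth class labels aligned with a score set's samples."""

    sample_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = [str(l) for l in self.labels]
        if len(self.sample_ids) != len(self.labels):
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids but {len(self.labels)} labels"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in label vector")

    def to_indices(self, class_names: Sequence[str]) -> np.ndarray:
        """Map labels to 0-based class indices given an ordered class list."""
        lookup = {c: k for k, c in enumerate(class_names)}
        try:
            return np.array([lookup[l] for l in self.labels], dtype=int)
        except KeyError as exc:
            raise ValidationError(
                f"label {exc.args[0]!r} is not one of the classes {list(class_names)}"
            ) from None


@dataclass
class ScoreBundle:
    """An ordered collection of learners sharing samples and classes."""

    learners: list[DecisionScoreSet]
    labels: Optional[LabelVector] = None

    @property
    def n_learners(self) -> int:
        return len(self.learners)

    @property
    def n_samples(self) -> int:
        return self.learners[0].n_samples

    @property
    def n_classes(self) -> int:
        return self.learners[0].n_classes

    @property
    def class_names(self) -> list[str]:
        return self.learners[0].class_names

    @property
    def sample_ids(self) -> list[str]:
        return self.learners[0].sample_ids

    def stacked(self) -> np.ndarray:
        """All probability matrices as one (L, n_samples, n_classes) array."""
        return np.stack([ls.probs for ls in self.learners])

    def truth_indices(self) -> np.ndarray:
        if self.labels is None:
            raise ValidationError("bundle carries no ground-truth labels")
        return self.labels.to_indices(self.class_names)


def validate_scores(scores: DecisionScoreSet) -> None:
    """Check ranges, uniqueness and row sums; renormalize within the band.

    Rows off by at most ``RENORM_BAND`` are divided by their sum (softmax
    outputs serialized at low precision drift by this much); a larger
    deviation raises :class:`ValidationError` naming the offending row.
    """
    p = scores.probs
    if p.ndim != 2:
        raise ValidationError(f"probability matrix must be 2-D, got {p.ndim}-D")
    if p.shape[0] != len(scores.sample_ids):
        raise ValidationError(
            f"{p.shape[0]} rows but {len(scores.sample_ids)} sample ids"
        )
    if p.shape[1] != len(scores.class_names):
        raise ValidationError(
            f"{p.shape[1]} columns but {len(scores.class_names)} class names"
        )
    if p.shape[1] < 2:
        raise ValidationError("need at least 2 class columns")
    if p.shape[0] == 0:
        raise ValidationError("score set has no samples")
    if len(set(scores.sample_ids)) != len(scores.sample_ids):
        raise ValidationError(f"duplicate sample ids in learner {scores.learner_id!r}")
    if len(set(scores.class_names)) != len(scores.class_names):
        raise ValidationError(f"duplicate class names in learner {scores.learner_id!r}")
    if not np.all(np.isfinite(p)):
        raise ValidationError("non-finite probability entries")
    if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
        bad = np.argwhere((p < -1e-9) | (p > 1 + 1e-9))[0]
        raise ValidationError(
            f"probability out of [0, 1] at sample {scores.sample_ids[bad[0]]!r}, "
            f"class {scores.class_names[bad[1]]!r}: {p[bad[0], bad[1]]}"
        )
    np.clip(p, 0.0, 1.0, out=p)
    sums = p.sum(axis=1)
    off = np.abs(sums - 1.0)
    if np.any(off > RENORM_BAND):
        i = int(np.argmax(off))
        raise ValidationError(
            f"row for sample {scores.sample_ids[i]!r} sums to {sums[i]:.6g} "
            f"(deviation {off[i]:.2g} exceeds the {RENORM_BAND} renormalization band)"
        )
    p /= sums[:, None]


def read_score_table(path: PathLike, learner_id: Optional[str] = None) -> DecisionScoreSet:
    """Read one learner's score table from a CSV file.

    The header must name a ``sample_id`` column; an optional ``label``
    column is ignored here (use :func:`read_labels` for truth).  All
    remaining columns are class probabilities in header order.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: missing required 'sample_id' column")
    class_cols = [c for c in df.columns if c not in ("sample_id", "label")]
    if len(class_cols) < 2:
        raise ValidationError(f"{path}: need at least 2 class columns, found {class_cols}")
    return DecisionScoreSet(
        learner_id=learner_id or path.stem,
        sample_ids=df["sample_id"].tolist(),
        class_names=class_cols,
        probs=df[class_cols].to_numpy(dtype=float),
    )


def write_score_table(scores: DecisionScoreSet, path: PathLike) -> Path:
    """Serialize a score set to CSV; round-trips to within 1e-12 per entry."""
    path = Path(path)
    df = pd.DataFrame(scores.probs, columns=scores.class_names)
    df.insert(0, "sample_id", scores.sample_ids)
    df.to_csv(path, index=False)
    return path


def read_labels(path: PathLike) -> LabelVector:
    """Read a two-column ``sample_id,label`` CSV."""
    df = pd.read_csv(path, dtype=str)
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required {col!r} column")
    return LabelVector(sample_ids=df["sample_id"].tolist(), labels=df["label"].tolist())


def write_labels(labels: LabelVector, path: PathLike) -> Path:
    path = Path(path)
    pd.DataFrame({"sample_id": labels.sample_ids, "label": labels.labels}).to_csv(
        path, index=False
    )
    return path


def align_bundle(
    learners: Sequence[DecisionScoreSet],
    labels: Optional[LabelVector] = None,
) -> ScoreBundle:
    """Assemble learners into a bundle, aligning rows to the first learner.

    All learners must present exactly the same class names in the same
    order (class index is the unit of fusion, so no silent column
    reordering) and the same set of sample ids; rows are reordered to
    the first learner's sample order, as is the label vector.
    """
    learners = list(learners)
    if not learners:
        raise SchemaError("bundle needs at least one learner")
    ref = learners[0]
    ref_ids = ref.sample_ids
    ref_pos = {s: i for i, s in enumerate(ref_ids)}
    aligned = [ref]
    for ls in learners[1:]:
        if ls.class_names != ref.class_names:
            raise SchemaError(
                f"class names of learner {ls.learner_id!r} {ls.class_names} "
                f"differ from {ref.learner_id!r} {ref.class_names}"
            )
        if set(ls.sample_ids) != set(ref_ids):
            raise SchemaError(
                f"sample ids of learner {ls.learner_id!r} do not match {ref.learner_id!r}"
            )
        if ls.sample_ids != ref_ids:
            order = np.array([ref_pos[s] for s in ls.sample_ids])
            perm = np.empty(len(ref_ids), dtype=int)
            perm[order] = np.arange(len(ref_ids))
            ls = DecisionScoreSet(
                learner_id=ls.learner_id,
                sample_ids=ref_ids,
                class_names=ls.class_names,
                probs=ls.probs[perm],
            )
        aligned.append(ls)
    if labels is not None:
        if set(labels.sample_ids) != set(ref_ids):
            raise SchemaError("label sample ids do not match the learners")
        pos = {s: i for i, s in enumerate(labels.sample_ids)}
        labels = LabelVector(
            sample_ids=ref_ids,
            labels=[labels.labels[pos[s]] for s in ref_ids],
        )
        for l in labels.labels:
            if l not in ref.class_names:
                raise ValidationError(
                    f"label {l!r} is not one of the classes {ref.class_names}"
                )
    return ScoreBundle(learners=aligned, labels=labels)
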