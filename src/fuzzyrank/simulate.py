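"""Seeded synthetic decision-score bundles for end-to-end testing.

The generator emulates the softmax outputs of several image classifiers
evaluated on the same samples, with three controllable knobs per study:

* ``target_accuracy`` — the probability that a learner's argmax lands on
  the true class (per learner);
* ``confidence`` — the Dirichlet concentration placed on the intended
  class, controlling how peaked the probability rows are;
* ``error_correlation`` — the probability that a sample's mistakes are
  shared across learners (a common latent confusion) rather than drawn
  independently.  At 0 the learners err independently and an ensemble
  can correct them; at 1 every learner makes the same mistake on the
  same samples and no fusion rule can improve on a single learner.

All randomness flows from a single seed through ``numpy``'s
``SeedSequence`` spawning, so learner streams are independent yet the
whole bundle is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .scores_io import (
    DecisionScoreSet,
    LabelVector,
    ScoreBundle,
    ValidationError,
    align_bundle,
)


@dataclass
class LearnerSpec:
    """Accuracy and sharpness of one simulated base learner."""

    learner_id: str
    target_accuracy: float = 0.8
    confidence: float = 6.0  # Dirichlet concentration on the intended class


@dataclass
class SimulationConfig:
    """Full specification of a synthetic score bundle."""

    n_samples: int = 1000
    n_classes: int = 5
    learners: list[LearnerSpec] = field(
        default_factory=lambda: [
            LearnerSpec("sim_a"),
            LearnerSpec("sim_b"),
            LearnerSpec("sim_c"),
        ]
    )
    class_proportions: Optional[Sequence[float]] = None  # default uniform
    error_correlation: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be positive")
        if self.n_classes < 2:
            raise ValidationError("need at least 2 classes")
        if not self.learners:
            raise ValidationError("need at least one learner spec")
        if not 0.0 <= self.error_correlation <= 1.0:
            raise ValidationError("error_correlation must lie in [0, 1]")
        if self.class_proportions is not None:
            p = np.asarray(self.class_proportions, dtype=float)
            if p.shape != (self.n_classes,) or np.any(p < 0):
                raise ValidationError("class_proportions must be a length-C simplex vector")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValidationError("class_proportions must sum to 1")
        chance = 1.0 / self.n_classes
        for spec in self.learners:
            if not chance < spec.target_accuracy <= 1.0:
                raise ValidationError(
                    f"learner {spec.learner_id!r}: target_accuracy "
                    f"{spec.target_accuracy} must exceed chance {chance:.3g} and be <= 1"
                )
            if spec.confidence <= 0:
                raise ValidationError(
                    f"learner {spec.learner_id!r}: confidence must be positive"
                )


def generate_bundle(config: SimulationConfig) -> ScoreBundle:
    """Draw a labelled synthetic score bundle from the configuration.

    For each sample a true class is drawn from ``class_proportions``.
    Each learner independently hits the true class with probability
    ``target_accuracy``; on a miss the intended class is a wrong class —
    the same wrong class (and the same miss event) for all learners with
    probability ``error_correlation``, independent otherwise.  The
    probability row is a Dirichlet draw with concentration ``confidence``
    on the intended class and 1 elsewhere; the largest component is then
    swapped onto the intended class so the row's argmax is exactly the
    intended class and realized argmax accuracy is a Binomial draw at
    the target rate.
    """
    config.validate()
    C = config.n_classes
    n = config.n_samples
    props = (
        np.full(C, 1.0 / C)
        if config.class_proportions is None
        else np.asarray(config.class_proportions, dtype=float)
    )
    root = np.random.SeedSequence(config.seed)
    label_ss, shared_ss, *learner_ss = root.spawn(2 + len(config.learners))

    rng = np.random.default_rng(label_ss)
    truth = rng.choice(C, size=n, p=props)

    shared_rng = np.random.default_rng(shared_ss)
    # latent shared confusion: a miss indicator percentile and a wrong class,
    # adopted by a learner when the coupling coin comes up heads
    shared_u = shared_rng.random(n)
    shared_wrong = _wrong_class(shared_rng, truth, C)
    coupled = shared_rng.random(n) < config.error_correlation

    sample_ids = [f"s{i:06d}" for i in range(n)]
    class_names = [f"class_{k + 1}" for k in range(C)]
    learners = []
    for spec, ss in zip(config.learners, learner_ss):
        lrng = np.random.default_rng(ss)
        own_u = lrng.random(n)
        own_wrong = _wrong_class(lrng, truth, C)
        u = np.where(coupled, shared_u, own_u)
        miss = u >= spec.target_accuracy
        intended = np.where(
            miss, np.where(coupled, shared_wrong, own_wrong), truth
        )
        alpha = np.ones(C)
        probs = np.empty((n, C))
        for i in range(n):
            a = alpha.copy()
            a[intended[i]] = spec.confidence
            row = lrng.dirichlet(a)
            top = int(np.argmax(row))
            if top != intended[i]:
                row[top], row[intended[i]] = row[intended[i]], row[top]
            probs[i] = row
        learners.append(
            DecisionScoreSet(
                learner_id=spec.learner_id,
                sample_ids=sample_ids,
                class_names=class_names,
                probs=probs,
            )
        )
    labels = LabelVector(sample_ids, [class_names[t] for t in truth])
    return align_bundle(learners, labels)


def _wrong_class(rng: np.random.Generator, truth: np.ndarray, C: int) -> np.ndarray:
    """A uniform draw over the C-1 classes other than each sample's truth."""
    offset = rng.integers(1, C, size=truth.shape[0])
    return (truth + offset) % C


# Reconstructed 4-class, 3-learner probability grid for the documented
# single-image walkthrough.  SYNTHETIC: only the learner-1/class-1
# probability (0.261) is given; the remaining entries were solved
# numerically so that each row sums to 1, the class-1 rank scores are
# 0.175 / 0.134 / 0.148, the fused scores are close to
# (0.458, 0.426, 0.594, 0.588), learners 1 and 3 individually favour
# class 2 while learner 2 favours class 1, and the fused argmin is
# class 2.
_WORKED_EXAMPLE_PROBS = {
    "inception_v3": [0.2610000000, 0.5451098494, 0.0464168915, 0.1474732591],
    "xception": [0.4044017320, 0.1634118959, 0.2251983963, 0.2069879758],
    "densenet169": [0.3592868023, 0.3792868018, 0.1351879563, 0.1262384396],
}


def worked_example_bundle() -> ScoreBundle:
    """The packaged 1-sample, 4-class, 3-learner walkthrough bundle.

    Probabilities are a synthetic reconstruction (see module source)
    anchored to the documented quantities: learner-1 class-1 probability
    0.261 with rank score 0.175, per-learner class-1 rank scores
    0.175 / 0.134 / 0.148, class-1 fused score ~0.458, and the fused
    winner class 2.
    """
    class_names = ["class_1", "class_2", "class_3", "class_4"]
    learners = [
        DecisionScoreSet(
            learner_id=lid,
            sample_ids=["img_0001"],
            class_names=class_names,
            probs=np.array([row]),
        )
        for lid, row in _WORKED_EXAMPLE_PROBS.items()
    ]
    labels = LabelVector(["img_0001"], ["class_2"])
    return align_bundle(learners, labels)
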