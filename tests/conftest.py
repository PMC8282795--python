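import numpy as np
import pytest

from fuzzyrank import DecisionScoreSet, LabelVector, align_bundle


def random_bundle(rng, n_learners=3, n_samples=20, n_classes=4, with_labels=True):
    """A bundle of Dirichlet-random learners on shared samples."""
    ids = [f"s{i}" for i in range(n_samples)]
    classes = [f"c{k}" for k in range(n_classes)]
    learners = [
        DecisionScoreSet(
            learner_id=f"L{j}",
            sample_ids=ids,
            class_names=classes,
            probs=rng.dirichlet(np.ones(n_classes), size=n_samples),
        )
        for j in range(n_learners)
    ]
    labels = None
    if with_labels:
        labels = LabelVector(ids, [classes[k] for k in rng.integers(0, n_classes, n_samples)])
    return align_bundle(learners, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bundle(rng):
    return random_bundle(rng)
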