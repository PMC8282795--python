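import numpy as np
import pytest
from scipy import stats

from fuzzyrank import (
    ConfusionMatrix,
    confusion_matrix,
    kfold_evaluate,
    mcnemar_test,
    metric_report,
)
from fuzzyrank.evaluation import stratified_folds
from fuzzyrank.scores_io import ValidationError
from tests.conftest import random_bundle


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        truth = [0] * 6 + [1] * 4
        cm = confusion_matrix(truth, truth, 2)
        np.testing.assert_array_equal(cm.counts, [[6, 0], [0, 4]])

    def test_constant_predictor_rows(self):
        truth = [0, 0, 0, 0, 1, 1, 1, 1]
        cm = confusion_matrix([0] * 8, truth, 2)
        np.testing.assert_array_equal(cm.counts, [[4, 4], [0, 0]])

    def test_conservation(self, rng):
        pred = rng.integers(0, 5, 100)
        truth = rng.integers(0, 5, 100)
        assert confusion_matrix(pred, truth, 5).total == 100

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            confusion_matrix([0, 1], [0], 2)


class TestMetricReport:
    def test_perfect_matrix(self):
        rep = metric_report(ConfusionMatrix(np.diag([3, 5, 2])))
        assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 1.0

    def test_hand_computed_two_class(self):
        # rows = predicted, columns = true
        rep = metric_report(ConfusionMatrix([[4, 1], [2, 3]]))
        assert rep.accuracy == pytest.approx(0.7)
        p1, r1, _ = rep.per_class[0]
        p2, r2, _ = rep.per_class[1]
        assert p1 == pytest.approx(4 / 5)
        assert r1 == pytest.approx(4 / 6)
        assert p2 == pytest.approx(3 / 5)
        assert r2 == pytest.approx(3 / 4)
        assert rep.precision == pytest.approx(0.7)
        assert rep.recall == pytest.approx((4 / 6 + 3 / 4) / 2)

    def test_micro_average_equals_accuracy(self, rng):
        pred = rng.integers(0, 4, 200)
        truth = rng.integers(0, 4, 200)
        rep = metric_report(confusion_matrix(pred, truth, 4), average="micro")
        assert rep.precision == rep.recall == rep.f1 == rep.accuracy

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import (
            accuracy_score,
            f1_score,
            precision_score,
            recall_score,
        )

        for _ in range(50):
            C = int(rng.integers(2, 6))
            n = int(rng.integers(10, 80))
            pred = rng.integers(0, C, n)
            truth = rng.integers(0, C, n)
            rep = metric_report(confusion_matrix(pred, truth, C))
            labels = list(range(C))
            assert rep.accuracy == pytest.approx(accuracy_score(truth, pred), abs=1e-9)
            assert rep.precision == pytest.approx(
                precision_score(truth, pred, labels=labels, average="macro",
                                zero_division=0), abs=1e-9)
            assert rep.recall == pytest.approx(
                recall_score(truth, pred, labels=labels, average="macro",
                             zero_division=0), abs=1e-9)
            assert rep.f1 == pytest.approx(
                f1_score(truth, pred, labels=labels, average="macro",
                         zero_division=0), abs=1e-9)

    def test_per_class_f1_is_harmonic_mean(self, rng):
        pred = rng.integers(0, 3, 60)
        truth = rng.integers(0, 3, 60)
        rep = metric_report(confusion_matrix(pred, truth, 3))
        for p, r, f in rep.per_class:
            expected = 0.0 if p + r == 0 else 2 * p * r / (p + r)
            assert f == pytest.approx(expected, abs=1e-12)

    def test_zero_denominator_convention(self):
        # class 1 never predicted and never true
        rep = metric_report(ConfusionMatrix([[5, 0], [0, 0]]))
        assert rep.per_class[1] == (0.0, 0.0, 0.0)


class TestStratifiedKFold:
    def test_balanced_two_fold_split(self, rng):
        truth = np.array([0] * 50 + [1] * 50)
        folds = stratified_folds(truth, k=2, seed=3)
        for fold in folds:
            assert np.sum(truth[fold] == 0) == 25
            assert np.sum(truth[fold] == 1) == 25

    def test_determinism(self, rng):
        b = random_bundle(rng, n_samples=60, n_classes=3)
        s1 = kfold_evaluate(b, k=3, seed=11)
        s2 = kfold_evaluate(b, k=3, seed=11)
        assert s1.mean == s2.mean and s1.std == s2.std

    def test_perfect_bundle_all_folds_perfect(self, rng):
        from fuzzyrank import DecisionScoreSet, LabelVector, align_bundle

        n, C = 50, 2
        truth_idx = np.array([0, 1] * 25)
        probs = np.full((n, C), 0.1)
        probs[np.arange(n), truth_idx] = 0.9
        ids = [f"s{i}" for i in range(n)]
        classes = ["a", "b"]
        b = align_bundle(
            [DecisionScoreSet("L", ids, classes, probs)],
            LabelVector(ids, [classes[k] for k in truth_idx]),
        )
        summary = kfold_evaluate(b, k=5, seed=0)
        assert summary.mean["accuracy"] == 1.0
        assert summary.std["accuracy"] == 0.0

    def test_too_few_samples_per_class(self, rng):
        b = random_bundle(rng, n_samples=8, n_classes=4)
        with pytest.raises(ValidationError):
            kfold_evaluate(b, k=5, seed=0)

    def test_population_std(self, rng):
        b = random_bundle(rng, n_samples=60, n_classes=2, n_learners=2)
        summary = kfold_evaluate(b, k=3, seed=5)
        accs = [r.accuracy for r in summary.per_fold]
        assert summary.std["accuracy"] == pytest.approx(np.std(accs), abs=1e-12)


class TestMcNemar:
    def test_identical_models(self):
        v = [True, False, True, True]
        res = mcnemar_test(v, v)
        assert res.n01 == res.n10 == 0
        assert res.p_value == 1.0

    def test_exact_branch_matches_binomial_tail(self):
        a = [True] * 5 + [False] * 15 + [True] * 30
        b = [False] * 5 + [True] * 15 + [True] * 30
        res = mcnemar_test(a, b)
        assert res.method == "exact_binomial"
        expected = 2 * sum(stats.binom.pmf(x, 20, 0.5) for x in range(6))
        assert res.p_value == pytest.approx(expected, abs=1e-12)
        assert res.p_value == pytest.approx(0.0414, abs=1e-4)

    def test_chi2_branch_statistic_and_p(self):
        a = [True] * 10 + [False] * 40 + [True] * 10
        b = [False] * 10 + [True] * 40 + [True] * 10
        res = mcnemar_test(a, b)
        assert res.method == "chi2_continuity"
        assert res.statistic == pytest.approx((abs(10 - 40) - 1) ** 2 / 50, abs=1e-12)
        assert res.p_value == pytest.approx(stats.chi2.sf(16.82, 1), abs=1e-12)
        assert res.p_value == pytest.approx(4.1e-5, rel=0.02)

    def test_symmetry_under_model_swap(self, rng):
        a = rng.random(200) < 0.8
        b = rng.random(200) < 0.7
        assert mcnemar_test(a, b).p_value == mcnemar_test(b, a).p_value

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for exact, n in ((True, 40), (False, 400)):
            a = rng.random(n) < 0.75
            b = rng.random(n) < 0.65
            res = mcnemar_test(a, b)
            table = [
                [int(np.sum(a & b)), res.n01],
                [res.n10, int(np.sum(~a & ~b))],
            ]
            sm = sm_mcnemar(table, exact=res.method == "exact_binomial",
                            correction=True)
            assert res.p_value == pytest.approx(float(sm.pvalue), abs=1e-9)
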