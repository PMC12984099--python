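"""Confusion matrices, classification metrics, AUC and Dice."""
import numpy as np
import pytest

from _oracles import brute_auc, brute_confusion, brute_dice, brute_prf
from imflight.errors import DataError
from imflight.evaluation import (
    ConfusionMatrix,
    confusion,
    dice_coefficient,
    metrics_from_confusion,
    roc_auc,
)


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = [0] * 5 + [1] * 5
        cm = confusion(y, y, ["a", "b"])
        assert np.array_equal(cm.counts, [[5, 0], [0, 5]])

    def test_matches_brute_force_tally(self, rng):
        t = rng.integers(0, 4, size=200)
        p = rng.permutation(t)
        cm = confusion(t, p, list("abcd"))
        assert np.array_equal(cm.counts, brute_confusion(t, p, 4))

    def test_empty_input_all_zero(self):
        cm = confusion([], [], ["a", "b"])
        assert not cm.counts.any()

    def test_unknown_label_rejected(self):
        with pytest.raises(DataError):
            confusion([0, 2], [0, 1], ["a", "b"])


class TestMetrics:
    def test_two_class_worked_example(self):
        """TN=9951, FP=49, FN=71, TP=9929 -> 99.4% overall accuracy."""
        cm = ConfusionMatrix(
            counts=np.array([[9951, 49], [71, 9929]]),
            class_names=["normal", "diseased"],
        )
        report = metrics_from_confusion(cm)
        assert report.accuracy == pytest.approx(0.994, abs=5e-5)
        assert report.per_class["diseased"]["recall"] == pytest.approx(9929 / 10000)

    def test_identity_matrix_is_perfect(self):
        cm = ConfusionMatrix(counts=np.eye(3, dtype=int) * 7,
                             class_names=list("abc"))
        report = metrics_from_confusion(cm)
        assert report.accuracy == 1.0
        assert report.macro_precision == report.macro_recall == report.macro_f1 == 1.0

    def test_matches_definitional_oracle(self, rng):
        counts = rng.integers(0, 30, size=(4, 4))
        counts[0, 0] += 1  # ensure non-zero total
        cm = ConfusionMatrix(counts=counts, class_names=list("abcd"))
        report = metrics_from_confusion(cm)
        ref = brute_prf(counts)
        for i, name in enumerate("abcd"):
            prec, rec, f1 = ref[i]
            assert report.per_class[name]["precision"] == pytest.approx(prec)
            assert report.per_class[name]["recall"] == pytest.approx(rec)
            assert report.per_class[name]["f1"] == pytest.approx(f1)
        assert report.accuracy == pytest.approx(np.trace(counts) / counts.sum())

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import precision_recall_fscore_support

        t = rng.integers(0, 3, size=120)
        p = rng.integers(0, 3, size=120)
        report = metrics_from_confusion(confusion(t, p, list("abc")))
        prec, rec, f1, _ = precision_recall_fscore_support(
            t, p, average="macro", zero_division=0
        )
        assert report.macro_precision == pytest.approx(prec)
        assert report.macro_recall == pytest.approx(rec)
        assert report.macro_f1 == pytest.approx(f1)

    def test_class_permutation_invariance(self, rng):
        counts = rng.integers(1, 20, size=(3, 3))
        perm = [2, 0, 1]
        a = metrics_from_confusion(ConfusionMatrix(counts, list("abc")))
        b = metrics_from_confusion(
            ConfusionMatrix(counts[np.ix_(perm, perm)],
                            [list("abc")[i] for i in perm])
        )
        assert a.accuracy == pytest.approx(b.accuracy)
        assert a.macro_f1 == pytest.approx(b.macro_f1)
        for name in "abc":
            assert a.per_class[name] == pytest.approx(b.per_class[name])

    def test_f1_between_precision_and_recall(self, rng):
        counts = rng.integers(0, 15, size=(3, 3)) + np.eye(3, dtype=int)
        report = metrics_from_confusion(ConfusionMatrix(counts, list("abc")))
        for m in report.per_class.values():
            assert min(m["precision"], m["recall"]) - 1e-12 <= m["f1"]
            assert m["f1"] <= max(m["precision"], m["recall"]) + 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(DataError):
            metrics_from_confusion(
                ConfusionMatrix(np.zeros((2, 2), dtype=int), ["a", "b"])
            )


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_six_pairs_match_all_pairs_oracle(self, rng):
        y = [0, 1, 0, 1, 1, 0]
        s = [0.3, 0.4, 0.4, 0.9, 0.2, 0.1]
        assert roc_auc(y, s) == pytest.approx(brute_auc(y, s))

    def test_random_matches_oracle_and_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        s = rng.random(60).round(1)  # force ties
        ours = roc_auc(y, s)
        assert ours == pytest.approx(brute_auc(y, s))
        assert ours == pytest.approx(roc_auc_score(y, s))

    def test_multiclass_macro_ovr(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 3, size=90)
        y[:3] = [0, 1, 2]
        scores = rng.random((90, 3))
        ours = roc_auc(y, scores)
        ref = np.mean([
            roc_auc_score((y == c).astype(int), scores[:, c]) for c in range(3)
        ])
        assert ours == pytest.approx(ref)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


class TestDice:
    def test_identical_masks(self, rng):
        m = rng.random((10, 10)) > 0.5
        assert dice_coefficient(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, 0] = True
        b[3, 3] = True
        assert dice_coefficient(a, b) == 0.0

    def test_matches_pixel_set_oracle(self, rng):
        a = rng.random((12, 12)) > 0.6
        b = rng.random((12, 12)) > 0.6
        assert dice_coefficient(a, b) == pytest.approx(brute_dice(a, b))

    def test_both_empty_defined_as_one(self):
        assert dice_coefficient(np.zeros((3, 3)), np.zeros((3, 3))) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DataError):
            dice_coefficient(np.zeros((3, 3)), np.zeros((4, 4)))
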