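"""Pixel-level segmentation metrics and slide-level classification scoring."""

import numpy as np
import pytest

from histoweak.seg_metrics import (
    BinaryMaskPair,
    ConfusionCounts,
    accuracy_improvement,
    classification_report,
    confusion_counts,
    evaluate_segmentation_set,
    prf_accuracy,
)


def loop_counts(tau, rho):
    """Independent per-pixel loop oracle for the confusion counts."""
    tp = tn = fp = fn = 0
    for t, r in zip(tau.ravel(), rho.ravel()):
        if t and r:
            tp += 1
        elif t and not r:
            fn += 1
        elif not t and r:
            fp += 1
        else:
            tn += 1
    return tp, tn, fp, fn


class TestConfusionCounts:
    def test_hand_case(self):
        pair = BinaryMaskPair(np.array([[1, 0], [0, 0]]), np.array([[1, 1], [0, 0]]))
        c = confusion_counts(pair)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 2, 0)

    def test_identical_masks(self, rng):
        tau = (rng.random((8, 8)) > 0.5).astype(int)
        c = confusion_counts(BinaryMaskPair(tau, tau))
        assert c.fp == 0 and c.fn == 0 and c.tp == tau.sum()
        assert prf_accuracy(c).accuracy == 1.0

    def test_complement_masks(self, rng):
        tau = (rng.random((8, 8)) > 0.5).astype(int)
        c = confusion_counts(BinaryMaskPair(tau, 1 - tau))
        assert c.tp == 0 and c.tn == 0

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="non-binary"):
            BinaryMaskPair(np.array([[2]]), np.array([[1]]))

    def test_conservation_fuzz(self, rng):
        for _ in range(100):
            d = int(rng.integers(2, 20))
            tau = (rng.random((d, d)) > rng.random()).astype(int)
            rho = (rng.random((d, d)) > rng.random()).astype(int)
            c = confusion_counts(BinaryMaskPair(tau, rho))
            assert c.total == d * d

    def test_matches_loop_oracle(self, rng):
        for _ in range(100):
            tau = (rng.random((16, 16)) > rng.random()).astype(int)
            rho = (rng.random((16, 16)) > rng.random()).astype(int)
            c = confusion_counts(BinaryMaskPair(tau, rho))
            assert (c.tp, c.tn, c.fp, c.fn) == loop_counts(tau, rho)


class TestPRFAccuracy:
    def test_hand_case(self):
        r = prf_accuracy(ConfusionCounts(tp=1, tn=2, fp=1, fn=0))
        assert r.precision == 0.5
        assert r.recall == 1.0
        assert r.f1 == pytest.approx(2 / 3)
        assert r.accuracy == 0.75

    def test_perfect(self):
        r = prf_accuracy(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert (r.precision, r.recall, r.f1, r.accuracy) == (1, 1, 1, 1)

    def test_zero_tp_with_fp(self):
        r = prf_accuracy(ConfusionCounts(tp=0, tn=3, fp=2, fn=1))
        assert r.precision == 0.0 and r.f1 == 0.0

    def test_undefined_marked_nan(self):
        r = prf_accuracy(ConfusionCounts(tp=0, tn=4, fp=0, fn=0))
        assert np.isnan(r.precision) and np.isnan(r.recall) and np.isnan(r.f1)
        assert r.accuracy == 1.0

    def test_matches_loop_oracle_on_random_masks(self, rng):
        for _ in range(100):
            tau = (rng.random((16, 16)) > rng.random()).astype(int)
            rho = (rng.random((16, 16)) > rng.random()).astype(int)
            tp, tn, fp, fn = loop_counts(tau, rho)
            r = prf_accuracy(confusion_counts(BinaryMaskPair(tau, rho)))
            if tp + fp:
                assert r.precision == tp / (tp + fp)
            if tp + fn:
                assert r.recall == tp / (tp + fn)
            assert r.accuracy == (tp + tn) / 256


class TestSegmentationSet:
    def test_single_pair(self):
        pair = BinaryMaskPair(np.eye(4, dtype=int), np.eye(4, dtype=int))
        report, skipped = evaluate_segmentation_set([pair])
        assert report.f1 == 1.0 and skipped["f1"] == 0

    def test_macro_average(self):
        perfect = BinaryMaskPair(np.ones((2, 2), int), np.ones((2, 2), int))
        half = BinaryMaskPair(
            np.array([[1, 1], [0, 0]]), np.array([[1, 0], [0, 1]])
        )
        report, _ = evaluate_segmentation_set([perfect, half])
        assert report.accuracy == pytest.approx(0.75)

    def test_macro_differs_from_micro(self):
        # Small pair scores F1=1; a large noisy pair drags micro down harder.
        small = BinaryMaskPair(np.ones((2, 2), int), np.ones((2, 2), int))
        big_tau = np.zeros((10, 10), int)
        big_tau[0, 0] = 1
        big_rho = np.ones((10, 10), int)
        big = BinaryMaskPair(big_tau, big_rho)
        macro, _ = evaluate_segmentation_set([small, big])
        micro, _ = evaluate_segmentation_set([small, big], average="micro")
        assert macro.f1 != pytest.approx(micro.f1)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            evaluate_segmentation_set([])


class TestClassificationReport:
    def test_perfect_probabilities(self):
        probs = np.eye(3)[[0, 1, 2, 0]]
        rep = classification_report(probs, np.array([0, 1, 2, 0]))
        assert rep.accuracy == 100.0
        assert rep.auc == 100.0
        assert np.all(rep.per_class_sensitivity == 1.0)

    def test_uniform_probabilities_chance_auc(self):
        probs = np.full((60, 3), 1 / 3)
        labels = np.arange(60) % 3
        rep = classification_report(probs, labels)
        assert rep.auc == pytest.approx(50.0, abs=1e-9)  # midrank ties

    def test_hand_built_confusion(self):
        probs = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1], [0.5, 0.4, 0.1]])
        labels = np.array([0, 1, 1])
        rep = classification_report(probs, labels)
        assert rep.confusion_matrix.tolist() == [[1, 0, 0], [1, 1, 0], [0, 0, 0]]
        assert rep.accuracy == pytest.approx(100 * 2 / 3)
        assert rep.per_class_sensitivity[0] == 1.0
        assert rep.per_class_sensitivity[1] == 0.5
        assert np.isnan(rep.per_class_sensitivity[2])

    def test_auc_invariant_to_monotone_transform(self, rng):
        raw = rng.random((40, 3)) + 0.1
        probs = raw / raw.sum(1, keepdims=True)
        labels = rng.integers(0, 3, 40)
        rep1 = classification_report(probs, labels)
        # strictly monotone transform of scores, renormalized rows still rank same
        t = probs**3
        # AUC depends on per-column ranking; cubing preserves it
        from sklearn.metrics import roc_auc_score

        a1 = np.mean(
            [roc_auc_score((labels == c).astype(int), probs[:, c]) for c in range(3)]
        )
        a2 = np.mean(
            [roc_auc_score((labels == c).astype(int), t[:, c]) for c in range(3)]
        )
        assert a1 == pytest.approx(a2)
        assert rep1.auc == pytest.approx(100 * a1)

    def test_label_out_of_range(self):
        with pytest.raises(ValueError):
            classification_report(np.full((2, 3), 1 / 3), np.array([0, 3]))


class TestAccuracyImprovement:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(85.57, 81.16, 4.41), (87.04, 82.21, 4.83), (50.0, 50.0, 0.0)],
    )
    def test_difference_in_points(self, a, b, expected):
        assert accuracy_improvement(a, b) == expected

    def test_range_check(self):
        with pytest.raises(ValueError):
            accuracy_improvement(101.0, 50.0)
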