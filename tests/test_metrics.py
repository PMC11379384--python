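"""Pixel metrics and ROC/AUC against brute-force and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from manet.errors import InvalidInputError, UndefinedMetricError
from manet.metrics import (ConfusionCounts, confusion_counts, roc_auc,
                           segmentation_metrics)


def brute_force_counts(p, g, threshold):
    tp = tn = fp = fn = 0
    for pi, gi in zip(np.ravel(p), np.ravel(g)):
        pred = pi >= threshold
        if pred and gi:
            tp += 1
        elif pred and not gi:
            fp += 1
        elif not pred and gi:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def concordant_pair_auc(p, g):
    """Mann-Whitney statistic: P(random fg pixel outscores random bg pixel)."""
    p = np.ravel(p)
    g = np.ravel(g).astype(bool)
    pos = p[g]
    neg = p[~g]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (pos.size * neg.size)


class TestConfusionCounts:
    def test_perfect_binary_prediction_has_no_errors(self, rng):
        g = (rng.random((9, 9)) > 0.5).astype(np.uint8)
        c = confusion_counts(g.astype(float), g)
        assert c.fp == 0 and c.fn == 0 and c.total == 81

    def test_inverted_prediction_has_no_hits(self, rng):
        g = (rng.random((9, 9)) > 0.5).astype(np.uint8)
        c = confusion_counts(1.0 - g, g)
        assert c.tp == 0 and c.tn == 0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           threshold=st.floats(0.05, 0.95))
    def test_counts_match_brute_force_loop(self, seed, threshold):
        rng = np.random.default_rng(seed)
        p = rng.random((7, 7))
        g = (rng.random((7, 7)) > 0.5).astype(np.uint8)
        assert confusion_counts(p, g, threshold) == brute_force_counts(p, g, threshold)

    def test_validation(self, rng):
        with pytest.raises(InvalidInputError):
            confusion_counts(np.zeros((2, 2)), np.zeros((2, 3), dtype=np.uint8))
        with pytest.raises(InvalidInputError):
            confusion_counts(np.zeros((2, 2)), np.full((2, 2), 2))
        with pytest.raises(InvalidInputError):
            confusion_counts(np.zeros((2, 2)), np.zeros((2, 2), dtype=np.uint8), 1.0)


class TestSegmentationMetrics:
    def test_closed_form_example(self):
        r = segmentation_metrics(ConfusionCounts(tp=3, tn=4, fp=1, fn=2))
        assert r.precision == pytest.approx(0.75)
        assert r.accuracy == pytest.approx(0.7)
        assert r.dice == pytest.approx(2 * 3 / (2 * 3 + 1 + 2))
        assert r.miou == pytest.approx(0.5 * (3 / 6 + 4 / 7))

    def test_perfect_prediction_scores_one_everywhere(self):
        r = segmentation_metrics(ConfusionCounts(tp=50, tn=0, fp=0, fn=0))
        assert (r.precision, r.accuracy, r.dice, r.miou) == (1.0, 1.0, 1.0, 1.0)

    def test_all_false_positives_score_zero(self):
        r = segmentation_metrics(ConfusionCounts(tp=0, tn=0, fp=50, fn=0))
        assert (r.precision, r.accuracy, r.dice, r.miou) == (0.0, 0.0, 0.0, 0.0)

    def test_empty_scene_conventions(self):
        # nothing predicted, nothing to find: vacuously perfect
        r = segmentation_metrics(ConfusionCounts(tp=0, tn=30, fp=0, fn=0))
        assert (r.precision, r.accuracy, r.dice, r.miou) == (1.0, 1.0, 1.0, 1.0)
        # nothing predicted but positives exist: precision 0 by convention
        r = segmentation_metrics(ConfusionCounts(tp=0, tn=20, fp=0, fn=10))
        assert r.precision == 0.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_accuracy_identity_and_ranges(self, seed):
        rng = np.random.default_rng(seed)
        tp, tn, fp, fn = [int(v) for v in rng.integers(0, 40, 4)]
        if tp + tn + fp + fn == 0:
            tp = 1
        c = ConfusionCounts(tp, tn, fp, fn)
        r = segmentation_metrics(c)
        assert r.accuracy == pytest.approx(1.0 - (fp + fn) / c.total)
        for v in (r.precision, r.accuracy, r.dice, r.miou):
            assert 0.0 <= v <= 1.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_global_aggregation_equals_summed_counts(self, seed):
        rng = np.random.default_rng(seed)
        maps = [(rng.random((6, 6)), (rng.random((6, 6)) > 0.5).astype(np.uint8))
                for _ in range(3)]
        summed = ConfusionCounts(0, 0, 0, 0)
        pooled_p, pooled_g = [], []
        for p, g in maps:
            summed = summed + confusion_counts(p, g)
            pooled_p.append(p.ravel())
            pooled_g.append(g.ravel())
        pooled = confusion_counts(np.concatenate(pooled_p), np.concatenate(pooled_g))
        assert pooled == summed

    def test_dice_loss_consistency_on_binary_predictions(self, rng):
        from manet.losses import dice_loss

        p = (rng.random((12, 12)) > 0.5).astype(float)
        g = (rng.random((12, 12)) > 0.5).astype(np.uint8)
        r = segmentation_metrics(confusion_counts(p, g))
        assert float(dice_loss(p, g.astype(float))) == pytest.approx(1.0 - r.dice,
                                                                     abs=1e-6)

    def test_zero_pixels_rejected(self):
        with pytest.raises(InvalidInputError):
            segmentation_metrics(ConfusionCounts(0, 0, 0, 0))


class TestRocAuc:
    def test_perfect_separation(self):
        p = np.array([0.9, 0.8, 0.2, 0.1])
        g = np.array([1, 1, 0, 0])
        _, auc = roc_auc(p, g)
        assert auc == pytest.approx(1.0)

    def test_constant_prediction_is_chance(self):
        p = np.full(50, 0.4)
        g = np.zeros(50, dtype=int)
        g[:20] = 1
        _, auc = roc_auc(p, g)
        assert auc == pytest.approx(0.5)

    def test_four_pixel_hand_case(self):
        _, auc = roc_auc(np.array([0.9, 0.8, 0.3, 0.1]), np.array([1, 0, 1, 0]))
        assert auc == pytest.approx(0.75)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_auc_equals_concordant_pair_statistic(self, seed):
        rng = np.random.default_rng(seed)
        p = np.round(rng.random(400), 2)  # duplicated values exercise tie handling
        g = (rng.random(400) > 0.6).astype(np.uint8)
        if g.sum() in (0, g.size):
            g[0] = 1 - g[0]
        _, auc = roc_auc(p, g)
        assert auc == pytest.approx(concordant_pair_auc(p, g), abs=1e-12)

    def test_matches_reference_implementation(self, rng):
        from sklearn.metrics import roc_auc_score

        p = rng.random((40, 40))
        g = (rng.random((40, 40)) > 0.7).astype(np.uint8)
        _, auc = roc_auc(p, g)
        assert auc == pytest.approx(roc_auc_score(g.ravel(), p.ravel()), abs=1e-10)

    def test_pooling_over_multiple_maps(self, rng):
        ps = [rng.random((5, 5)) for _ in range(3)]
        gs = [(rng.random((5, 5)) > 0.5).astype(np.uint8) for _ in range(3)]
        _, auc_pooled = roc_auc(ps, gs)
        _, auc_flat = roc_auc(np.concatenate([p.ravel() for p in ps]),
                              np.concatenate([g.ravel() for g in gs]))
        assert auc_pooled == auc_flat

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc(np.random.default_rng(0).random(10), np.zeros(10, dtype=np.uint8))

    def test_curve_csv_export(self, tmp_path, rng):
        curve, _ = roc_auc(rng.random(30), (rng.random(30) > 0.5).astype(np.uint8))
        path = curve.to_csv(tmp_path / "roc.csv")
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "threshold,fpr,tpr"
        assert len(lines) == len(curve.thresholds) + 1
        assert curve.fpr[0] == 0.0 and curve.tpr[0] == 0.0
        assert curve.fpr[-1] == 1.0 and curve.tpr[-1] == 1.0
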