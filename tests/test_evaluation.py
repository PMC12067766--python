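"""Metric definitions, empty-mask policies, ROC averaging and R² agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rrseg.evaluation import (NoEvaluableImages, aggregate_metric, dice,
                              evaluate_dataset, jaccard, mean_roc,
                              r2_agreement, roc_curve)
from rrseg.io_formats import ClassMasks, InputError
from rrseg.unet import ProbabilityMaps


def brute_force_auc(scores, truth):
    """Pair-ordering oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[truth]
    neg = scores[~truth]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestDiceJaccard:
    def test_identical_masks(self, rng):
        m = rng.random((8, 8)) > 0.5
        assert dice(m, m) == 1.0
        assert jaccard(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), bool); a[0, 0] = True
        b = np.zeros((4, 4), bool); b[3, 3] = True
        assert dice(a, b) == 0.0
        assert jaccard(a, b) == 0.0

    def test_partial_overlap_by_set_counting(self):
        a = np.zeros((4, 4), bool); a[0, :2] = True       # |P| = 2
        b = np.zeros((4, 4), bool); b[0, 1:3] = True      # |T| = 2, overlap 1
        assert dice(a, b) == pytest.approx(0.5)           # 2*1/(2+2)
        assert jaccard(a, b) == pytest.approx(1 / 3)      # 1/3

    def test_both_empty_is_undefined(self):
        e = np.zeros((4, 4), bool)
        assert dice(e, e) is None
        assert jaccard(e, e) is None

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_dice_jaccard_identity_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random((6, 6)) > rng.uniform(0.2, 0.9)
        t = rng.random((6, 6)) > rng.uniform(0.2, 0.9)
        d, j = dice(p, t), jaccard(p, t)
        assert (d is None) == (j is None)
        if d is not None:
            assert abs(d - 2 * j / (1 + j)) <= 1e-12
        assert dice(p, t) == dice(t, p)
        assert jaccard(p, t) == jaccard(t, p)


class TestAggregate:
    def test_exclude_drops_undefined(self):
        mean, _ = aggregate_metric([0.5, None], "exclude")
        assert mean == pytest.approx(0.5)

    def test_set_to_one_counts_undefined_as_perfect(self):
        mean, _ = aggregate_metric([0.5, None], "set_to_one")
        assert mean == pytest.approx(0.75)

    def test_policies_agree_when_all_defined(self, rng):
        vals = list(rng.random(10))
        assert aggregate_metric(vals, "exclude") == \
            aggregate_metric(vals, "set_to_one")

    def test_all_undefined_under_exclude_signals(self):
        with pytest.raises(NoEvaluableImages):
            aggregate_metric([None, None], "exclude")

    def test_set_to_one_dominates_exclude(self, rng):
        vals = list(rng.uniform(0, 0.9, 8)) + [None, None]
        assert aggregate_metric(vals, "set_to_one")[0] > \
            aggregate_metric(vals, "exclude")[0]


class TestROC:
    def test_perfect_separation(self):
        truth = np.array([[True, True], [False, False]])
        scores = np.array([[0.9, 0.8], [0.2, 0.1]])
        assert roc_curve(scores, truth).auc == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        truth = np.array([[True, False], [False, True]])
        scores = np.full((2, 2), 0.4)
        assert roc_curve(scores, truth).auc == pytest.approx(0.5)

    def test_four_pixel_case_against_pair_counting(self):
        truth = np.array([[True, True], [False, False]])
        scores = np.array([[0.9, 0.4], [0.6, 0.1]])
        # pairs: (.9,.6)+ (.9,.1)+ (.4,.6)- (.4,.1)+ -> 3/4
        assert roc_curve(scores, truth).auc == pytest.approx(0.75)

    def test_single_class_truth_is_undefined(self):
        assert roc_curve(np.random.rand(3, 3), np.zeros((3, 3), bool)) is None
        assert roc_curve(np.random.rand(3, 3), np.ones((3, 3), bool)) is None

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=60, deadline=None)
    def test_trapezoid_auc_equals_pair_ordering_oracle(self, seed):
        rng = np.random.default_rng(seed)
        truth = rng.random((8, 8)) > 0.6
        if truth.all() or not truth.any():
            truth[0, 0] = not truth[0, 0]
        # quantised scores force ties through the oracle's tie term
        scores = np.round(rng.random((8, 8)), 1)
        curve = roc_curve(scores, truth)
        assert curve.auc == pytest.approx(
            brute_force_auc(scores.ravel(), truth.ravel()), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        truth = rng.random((8, 8)) > 0.5
        scores = rng.random((8, 8))
        a = roc_curve(scores, truth).auc
        b = roc_curve(np.exp(3 * scores), truth).auc
        assert a == pytest.approx(b)


class TestMeanROC:
    def test_identical_curves_have_zero_sd(self, rng):
        truth = rng.random((8, 8)) > 0.5
        scores = rng.random((8, 8))
        c = roc_curve(scores, truth)
        avg = mean_roc([c, c, c])
        assert np.allclose(avg.tpr_sd, 0.0)
        assert avg.mean_auc == pytest.approx(c.auc)

    def test_mean_auc_is_average_of_members(self):
        truth = np.array([[True, True], [False, False]])
        perfect = roc_curve(np.array([[0.9, 0.8], [0.2, 0.1]]), truth)
        chance = roc_curve(np.full((2, 2), 0.5), truth)
        assert mean_roc([perfect, chance]).mean_auc == pytest.approx(0.75)

    def test_mean_curve_nondecreasing(self, rng):
        curves = []
        for _ in range(5):
            truth = rng.random((10, 10)) > 0.5
            curves.append(roc_curve(rng.random((10, 10)), truth))
        avg = mean_roc(curves)
        assert np.all(np.diff(avg.tpr_mean) >= -1e-12)


class TestR2:
    def test_identity_is_one(self):
        assert r2_agreement([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_affine_invariance_of_pearson_mode(self):
        t = np.array([1.0, 2.0, 3.0, 5.0])
        assert r2_agreement(t, 3 * t - 2) == pytest.approx(1.0)

    def test_hand_computed_case(self):
        assert r2_agreement([1, 2, 3], [1, 2, 2]) == pytest.approx(0.75)

    def test_identity_mode_penalises_offset(self):
        t = np.array([1.0, 2.0, 3.0])
        assert r2_agreement(t, t + 1, mode="identity") < 1.0
        assert r2_agreement(t, t, mode="identity") == pytest.approx(1.0)

    def test_constant_truth_rejected(self):
        with pytest.raises(InputError):
            r2_agreement([2, 2, 2], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            r2_agreement([1, 2, 3], [1, 2])


def _random_masks(rng, id, p=0.3, size=16):
    return ClassMasks(id=id, rod=rng.random((size, size)) < p,
                      ring=rng.random((size, size)) < p)


class TestEvaluateDataset:
    def test_perfect_predictions(self, rng):
        truths = {f"i{k}": _random_masks(rng, f"i{k}") for k in range(5)}
        maps = {i: ProbabilityMaps(id=i, rod=t.rod.astype(float),
                                   ring=t.ring.astype(float))
                for i, t in truths.items()}
        report = evaluate_dataset(truths, maps, truths, 0.192)
        pix = report.aggregate
        assert (pix.loc[pix.metric == "dice", "mean"] == 1.0).all()
        assert (pix.loc[pix.metric == "jaccard", "mean"] == 1.0).all()
        counts = report.r2.set_index("measurement")
        assert counts.loc["n_rods", "r2"] == pytest.approx(1.0)

    def test_empty_image_policies(self, rng):
        truths = {f"i{k}": _random_masks(rng, f"i{k}") for k in range(3)}
        empty = np.zeros((16, 16), bool)
        truths["empty"] = ClassMasks(id="empty", rod=empty, ring=empty)
        preds = {i: t for i, t in truths.items()}
        rep_ex = evaluate_dataset(preds, None, truths, 0.192, "exclude")
        rep_one = evaluate_dataset(preds, None, truths, 0.192, "set_to_one")
        ex = rep_ex.aggregate.query("metric == 'dice' and `class` == 'rod'")
        one = rep_one.aggregate.query("metric == 'dice' and `class` == 'rod'")
        assert int(ex["n"].iloc[0]) == 3 and int(one["n"].iloc[0]) == 4
        assert one["mean"].iloc[0] == pytest.approx(1.0)

    def test_mismatched_ids_rejected(self, rng):
        truths = {"a": _random_masks(rng, "a")}
        preds = {"b": _random_masks(rng, "b")}
        with pytest.raises(InputError):
            evaluate_dataset(preds, None, truths, 0.192)
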