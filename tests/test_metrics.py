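"""Tversky index/loss and Jaccard evaluation against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sssnet as s
from sssnet.metrics import _loss_and_grad_fast


def _brute_force_jaccard(pred, gt, num_classes=5):
    """Set-arithmetic oracle: JI_c = |pred_c ∩ gt_c| / |pred_c ∪ gt_c|."""
    out = {}
    for c in range(num_classes):
        p = {(i, j) for i, j in zip(*np.nonzero(pred == c))}
        g = {(i, j) for i, j in zip(*np.nonzero(gt == c))}
        union = p | g
        out[c] = len(p & g) / len(union) if union else 1.0
    return out


class TestTverskyParams:
    def test_alpha_beta_must_sum_to_one(self):
        with pytest.raises(ValueError, match="alpha \\+ beta"):
            s.TverskyParams(alpha=0.7, beta=0.4)

    def test_omega_positive(self):
        with pytest.raises(ValueError, match="omega"):
            s.TverskyParams(omega=0.0)


class TestTverskyIndex:
    def test_perfect_prediction_is_one(self):
        gt = np.eye(5, dtype=np.float32)[
            np.random.default_rng(0).integers(0, 5, (8, 8))]
        for alpha in (0.3, 0.5, 0.7):
            tp = s.TverskyParams(alpha=alpha, beta=1 - alpha)
            assert s.tversky_index(gt.astype(np.float64), gt, tp) == \
                pytest.approx(1.0, abs=1e-6)

    def test_disjoint_prediction_is_nearly_zero(self):
        gt = np.zeros((16, 16, 2), dtype=np.float32)
        gt[..., 0] = 1
        pred = 1.0 - gt
        assert s.tversky_index(pred, gt) < 1e-4

    def test_worked_single_class_case(self):
        """Binary single-class mask with TP=4, FN=4, FP=2 at alpha=0.7,
        beta=0.3: index = 4 / (4 + 0.7*4 + 0.3*2) = 4/7.4."""
        gt = np.zeros((4, 4))
        gt[0, :4] = 1
        gt[1, :4] = 1          # 8 foreground pixels
        pred = np.zeros((4, 4))
        pred[0, :4] = 1        # TP = 4 (row 1 of gt missed -> FN = 4)
        pred[2, :2] = 1        # FP = 2
        got = s.tversky_index(pred, gt, s.TverskyParams(0.7, 0.3, 1e-6))
        assert got == pytest.approx(4 / 7.4, abs=1e-5)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        probs = rng.random((6, 6, 5))
        probs /= probs.sum(axis=-1, keepdims=True)
        gt = np.eye(5)[rng.integers(0, 5, (6, 6))]
        base = s.tversky_index(probs, gt)
        perm = rng.permutation(36)
        p2 = probs.reshape(36, 5)[perm].reshape(6, 6, 5)
        g2 = gt.reshape(36, 5)[perm].reshape(6, 6, 5)
        assert s.tversky_index(p2, g2) == pytest.approx(base, abs=1e-12)

    def test_rejects_shape_mismatch_and_nonbinary_gt(self):
        with pytest.raises(ValueError, match="shape"):
            s.tversky_index(np.zeros((2, 2, 5)), np.zeros((2, 3, 5)))
        bad_gt = np.full((2, 2, 5), 0.5)
        with pytest.raises(ValueError, match="binary"):
            s.tversky_index(np.zeros((2, 2, 5)), bad_gt)


class TestTverskyLoss:
    def test_zero_at_perfect_prediction(self):
        gt = np.eye(5)[np.random.default_rng(1).integers(0, 5, (8, 8))]
        assert s.tversky_loss(gt.astype(float), gt) == \
            pytest.approx(0.0, abs=1e-6)

    def test_reducing_a_false_positive_decreases_loss(self):
        rng = np.random.default_rng(2)
        probs = rng.uniform(0.05, 0.95, size=(8, 8, 5))
        probs /= probs.sum(axis=-1, keepdims=True)
        gt = np.eye(5)[rng.integers(0, 5, (8, 8))]
        # pick a pixel where class 2 is a false positive
        ij = next(zip(*np.nonzero((gt[..., 2] == 0) & (probs[..., 2] > 0.1))))
        base = s.tversky_loss(probs, gt)
        probs2 = probs.copy()
        probs2[ij][2] -= 0.05
        assert s.tversky_loss(probs2, gt) < base

    def test_equals_dice_loss_at_balanced_alpha_beta(self):
        rng = np.random.default_rng(4)
        gt = np.eye(5)[rng.integers(0, 5, (16, 16))]
        pred = np.eye(5)[rng.integers(0, 5, (16, 16))].astype(float)
        tp = s.TverskyParams(alpha=0.5, beta=0.5, omega=1e-9)
        loss = s.tversky_loss(pred, gt, tp)
        dices = []
        for c in range(5):
            p, g = pred[..., c], gt[..., c]
            inter = (p * g).sum()
            dices.append(1 - 2 * inter / (p.sum() + g.sum()))
        assert loss == pytest.approx(np.mean(dices), abs=1e-5)

    def test_gradient_finite_on_open_interval(self):
        rng = np.random.default_rng(5)
        probs = rng.uniform(1e-6, 1 - 1e-6, size=(8, 8, 5))
        gt = np.eye(5)[rng.integers(0, 5, (8, 8))]
        g = s.tversky_loss_grad(probs, gt)
        assert np.all(np.isfinite(g))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(6)
        probs = rng.uniform(0.1, 0.9, size=(4, 4, 5))
        gt = np.eye(5)[rng.integers(0, 5, (4, 4))]
        g = s.tversky_loss_grad(probs, gt)
        for _ in range(5):
            idx = tuple(rng.integers(0, d) for d in probs.shape)
            eps = 1e-6
            p2 = probs.copy()
            p2[idx] += eps
            up = s.tversky_loss(p2, gt)
            p2[idx] -= 2 * eps
            down = s.tversky_loss(p2, gt)
            num = (up - down) / (2 * eps)
            assert g[idx] == pytest.approx(num, rel=1e-3, abs=1e-9)

    def test_fast_path_matches_reference(self):
        rng = np.random.default_rng(7)
        probs = rng.random((2, 8, 8, 5)).astype(np.float32)
        probs /= probs.sum(axis=-1, keepdims=True)
        gt = np.eye(5, dtype=np.float32)[rng.integers(0, 5, (2, 8, 8))]
        loss, grad = _loss_and_grad_fast(probs, gt, s.TverskyParams())
        assert loss == pytest.approx(s.tversky_loss(probs, gt), abs=1e-6)
        assert np.allclose(grad, s.tversky_loss_grad(probs, gt), atol=1e-7)


class TestConfusionCounts:
    def test_identity_has_no_errors(self):
        lm = np.random.default_rng(0).integers(0, 5, (10, 10))
        counts = s.confusion_counts(lm, lm)
        assert np.all(counts.fp == 0) and np.all(counts.fn == 0)
        assert counts.tp.sum() == lm.size

    def test_two_by_two_hand_count(self):
        pred = np.array([[0, 1], [1, 1]])
        gt = np.array([[0, 1], [0, 1]])
        counts = s.confusion_counts(pred, gt, num_classes=2)
        assert counts.tp[1] == 2 and counts.fp[1] == 1 and counts.fn[1] == 0

    def test_swapping_pred_and_gt_swaps_fp_and_fn(self):
        rng = np.random.default_rng(1)
        a, b = rng.integers(0, 5, (2, 12, 12))
        c1 = s.confusion_counts(a, b)
        c2 = s.confusion_counts(b, a)
        assert np.array_equal(c1.fp, c2.fn) and np.array_equal(c1.fn, c2.fp)

    def test_tallies_sum_to_total_per_class(self):
        rng = np.random.default_rng(2)
        pred, gt = rng.integers(0, 5, (2, 9, 9))
        counts = s.confusion_counts(pred, gt)
        total = counts.tp + counts.fp + counts.fn + counts.tn
        assert np.all(total == 81)

    def test_rejects_out_of_range_labels(self):
        with pytest.raises(ValueError, match="outside"):
            s.confusion_counts(np.array([[5]]), np.array([[0]]))


class TestJaccard:
    def test_direct_formula(self):
        counts = s.ConfusionCounts(
            tp=np.array([8]), fp=np.array([2]), fn=np.array([2]),
            tn=np.array([88]))
        ji = s.jaccard_per_class(counts)
        assert ji["class0"] == pytest.approx(8 / 12)

    def test_matches_set_arithmetic_oracle_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            pred, gt = rng.integers(0, 5, (2, 16, 16))
            counts = s.confusion_counts(pred, gt)
            ji = s.jaccard_per_class(counts)
            oracle = _brute_force_jaccard(pred, gt)
            for c, name in enumerate(s.CLASS_NAMES):
                assert ji[name] == oracle[c]

    def test_absent_class_scores_one_and_is_flagged(self):
        pred = np.zeros((4, 4), dtype=int)
        gt = np.zeros((4, 4), dtype=int)
        counts = s.confusion_counts(pred, gt)
        ji = s.jaccard_per_class(counts)
        assert all(ji[c] == 1.0 for c in s.CLASS_NAMES)
        assert set(s.absent_classes(counts)) == set(s.CLASS_NAMES[1:])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_jaccard_oracle_property(self, seed):
        rng = np.random.default_rng(seed)
        pred, gt = rng.integers(0, 5, (2, 16, 16))
        ji = s.jaccard_per_class(s.confusion_counts(pred, gt))
        oracle = _brute_force_jaccard(pred, gt)
        assert all(ji[name] == oracle[c]
                   for c, name in enumerate(s.CLASS_NAMES))


class TestMeanJI:
    def test_all_ones(self):
        assert s.mean_ji({c: 1.0 for c in s.CLASS_NAMES}) == 1.0

    def test_published_residual_row(self):
        per_class = {"ZP": 0.8288, "TE": 0.7740, "BL": 0.8839,
                     "ICM": 0.8494, "background": 0.9603}
        assert s.mean_ji(per_class) == pytest.approx(0.8593, abs=0.005)

    def test_published_dense_row(self):
        per_class = {"ZP": 0.8451, "TE": 0.7815, "BL": 0.8868,
                     "ICM": 0.8450, "background": 0.9582}
        assert s.mean_ji(per_class) == pytest.approx(0.8634, abs=0.005)

    def test_missing_class_is_an_error(self):
        with pytest.raises(ValueError, match="missing"):
            s.mean_ji({"ZP": 1.0})


class TestEvalReport:
    def test_from_counts_mean_is_unweighted(self):
        rng = np.random.default_rng(4)
        pred, gt = rng.integers(0, 5, (2, 32, 32))
        report = s.EvalReport.from_counts(s.confusion_counts(pred, gt))
        assert report.mean_ji == pytest.approx(
            np.mean([report.per_class_ji[c] for c in s.CLASS_NAMES]))
        assert report.n_pixels == 32 * 32
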