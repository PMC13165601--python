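"""Loss functions and segmentation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quct import nn
from quct.objectives import (LossConfig, boundary_f1, combined_loss,
                             dice_coefficient, dice_loss, evaluate,
                             focal_loss, hd95, iou, pixel_accuracy, ssim)
from quct.phantoms import DEFAULT_SCHEME, labels_to_onehot, labels_to_sos


def as_probs(arr):
    return nn.Tensor(np.asarray(arr, dtype=np.float32))


def random_pair(seed, shape=(12, 12), C=4):
    rng = np.random.default_rng(seed)
    return rng.integers(0, C, shape), rng.integers(0, C, shape)


class TestFocalLoss:
    def test_perfect_prediction_is_zero_up_to_clip(self):
        oh = np.zeros((1, 2, 2, 2), np.float32)
        oh[0, 0] = 1
        loss = focal_loss(as_probs(oh), as_probs(oh))
        assert loss.item() < 1e-5

    def test_gamma_zero_reduces_to_cross_entropy(self):
        p = np.full((1, 2, 1, 1), 0.5, np.float32)
        oh = np.zeros_like(p)
        oh[0, 0] = 1
        loss = focal_loss(as_probs(p), as_probs(oh), LossConfig(gamma=0.0))
        assert loss.item() == pytest.approx(0.693147, abs=1e-5)

    def test_gamma_two_scalar_value(self):
        p = np.zeros((1, 2, 1, 1), np.float32)
        p[0, 0], p[0, 1] = 0.9, 0.1
        oh = np.zeros_like(p)
        oh[0, 0] = 1
        loss = focal_loss(as_probs(p), as_probs(oh), LossConfig(gamma=2.0))
        # -(1 - 0.9)^2 log(0.9)
        assert loss.item() == pytest.approx(1.0536e-3, rel=1e-3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(as_probs(np.zeros((1, 2, 3, 3))),
                       as_probs(np.zeros((1, 2, 4, 4))))


class TestDiceLoss:
    def test_perfect_prediction_is_zero(self):
        oh = np.transpose(labels_to_onehot(random_pair(0)[0], 4),
                          (2, 0, 1))[None]
        assert dice_loss(as_probs(oh), as_probs(oh)).item() < 1e-6

    def test_fully_disjoint_single_class(self):
        p = np.array([[[[1.0]], [[0.0]]]], np.float32)
        g = np.array([[[[0.0]], [[1.0]]]], np.float32)
        loss = dice_loss(as_probs(p), as_probs(g), LossConfig())
        assert loss.item() == pytest.approx(1 - 1e-5 / (1 + 1e-5), abs=1e-7)

    def test_half_probability_on_balanced_target(self):
        n = 1000
        g = np.zeros((1, 2, 1, n), np.float32)
        g[0, 0, 0, :n // 2] = 1
        g[0, 1, 0, n // 2:] = 1
        p = np.full_like(g, 0.5)
        # closed form per class: 1 - (0.5 n_c + eps) / (0.5 n + n_c + eps)
        assert dice_loss(as_probs(p), as_probs(g)).item() == \
            pytest.approx(0.5, abs=1e-4)


class TestCombinedLoss:
    def test_sum_of_components(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(1, 4, 6, 6)).astype(np.float32)
        p = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
        oh = np.transpose(labels_to_onehot(rng.integers(0, 4, (6, 6)), 4),
                          (2, 0, 1))[None]
        total = combined_loss(as_probs(p), as_probs(oh)).item()
        parts = focal_loss(as_probs(p), as_probs(oh)).item() \
            + dice_loss(as_probs(p), as_probs(oh)).item()
        assert total == pytest.approx(parts, rel=1e-6)

    def test_uniform_predictor_matches_closed_form(self):
        C, H = 4, 8
        rng = np.random.default_rng(2)
        labels = rng.integers(0, C, (H, H))
        oh = np.transpose(labels_to_onehot(labels, C), (2, 0, 1))[None]
        p = np.full_like(oh, 1.0 / C)
        # focal: (1 - 1/C)^gamma * ln C;  dice: per-class closed form
        focal_cf = (1 - 1 / C) ** 2 * np.log(C)
        eps = 1e-5
        n = H * H
        dice_cf = 1 - np.mean([(2 * (labels == c).sum() / C + eps)
                               / (n / C + (labels == c).sum() + eps)
                               for c in range(C)])
        got = combined_loss(as_probs(p), as_probs(oh)).item()
        assert got == pytest.approx(focal_cf + dice_cf, rel=1e-4)

    def test_decreases_when_overfitting_one_sample(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 3, (9, 9))
        oh = np.transpose(labels_to_onehot(labels, 3), (2, 0, 1))[None]
        logits = nn.Parameter(rng.normal(size=(1, 3, 9, 9)) * 0.1)
        opt = nn.Adam([logits], lr=0.05)
        losses = []
        for _ in range(50):
            opt.zero_grad()
            loss = combined_loss(nn.softmax(logits, axis=1), as_probs(oh))
            loss.backward()
            opt.step()
            losses.append(loss.item())
        assert losses[-1] < losses[0] * 0.2
        assert np.all(np.diff(losses) < 1e-3)      # essentially monotone


class TestOverlapMetrics:
    def test_identical_maps(self):
        p, _ = random_pair(4)
        _, d = dice_coefficient(p, p)
        _, i = iou(p, p)
        assert d == 1.0 and i == 1.0 and pixel_accuracy(p, p) == 1.0

    def test_half_overlap_counting(self):
        gt = np.zeros((10, 20), int)
        gt[:, :10] = 1                     # |Y|=100
        pred = np.zeros((10, 20), int)
        pred[:, 5:15] = 1                  # |X|=100, |X∩Y|=50
        per_d, _ = dice_coefficient(pred, gt)
        per_i, _ = iou(pred, gt)
        assert per_d[1] == pytest.approx(0.5)
        assert per_i[1] == pytest.approx(1 / 3)

    def test_disjoint_sets_score_zero(self):
        gt = np.zeros((4, 4), int)
        gt[:2] = 1
        pred = np.zeros((4, 4), int)
        pred[2:] = 1
        per, _ = dice_coefficient(pred, gt)
        assert per[1] == 0.0

    def test_complementary_binary_maps_accuracy_zero(self):
        gt = np.zeros((5, 5), int)
        assert pixel_accuracy(1 - gt, gt) == 0.0

    def test_three_mismatches_on_3x3(self):
        gt = np.zeros((3, 3), int)
        pred = gt.copy()
        pred.flat[:3] = 1
        assert pixel_accuracy(pred, gt) == pytest.approx(6 / 9)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_dice_iou_identity_and_symmetry(self, seed):
        pred, gt = random_pair(seed)
        per_d, _ = dice_coefficient(pred, gt)
        per_i, _ = iou(pred, gt)
        for c in per_d:
            assert per_i[c] == pytest.approx(per_d[c] / (2 - per_d[c]),
                                             abs=1e-12)
        assert dice_coefficient(gt, pred)[1] == dice_coefficient(pred, gt)[1]
        assert iou(gt, pred)[1] == iou(pred, gt)[1]

    def test_absent_class_excluded_from_macro(self):
        pred = np.zeros((4, 4), int)
        gt = np.zeros((4, 4), int)
        per, mac = dice_coefficient(pred, gt, n_classes=8)
        assert set(per) == {0} and mac == 1.0


class TestSSIM:
    def test_self_similarity_is_one(self):
        img = labels_to_sos(random_pair(7)[0] % 8, DEFAULT_SCHEME)
        assert ssim(img, img, DEFAULT_SCHEME.sos_range) == pytest.approx(1.0)

    def test_constant_images_reduce_to_luminance_term(self):
        L = DEFAULT_SCHEME.sos_range
        a = np.full((8, 8), 1500.0)
        b = np.full((8, 8), 1800.0)
        c1 = (0.01 * L) ** 2
        expected = (2 * 1500 * 1800 + c1) / (1500 ** 2 + 1800 ** 2 + c1)
        assert ssim(a, b, L) == pytest.approx(expected, rel=1e-12)

    def test_matches_independent_moment_computation(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(900, 2250, (16, 16))
        y = rng.uniform(900, 2250, (16, 16))
        L = 1350.0
        c1, c2 = (0.01 * L) ** 2, (0.03 * L) ** 2
        mx, my = x.mean(), y.mean()
        vx, vy = ((x - mx) ** 2).mean(), ((y - my) ** 2).mean()
        cov = ((x - mx) * (y - my)).mean()
        oracle = ((2 * mx * my + c1) * (2 * cov + c2)
                  / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))
        assert ssim(x, y, L) == pytest.approx(oracle, abs=1e-10)

    def test_windowed_mode_runs_and_is_bounded(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, (20, 20))
        s = ssim(x, x + rng.normal(0, 0.1, x.shape), 1.0, windowed=True)
        assert -1.0 <= s <= 1.0


class TestBoundaryMetrics:
    def test_identical_maps_zero_distance_full_f1(self):
        m, _ = random_pair(10)
        assert hd95(m, m) == 0.0
        assert boundary_f1(m, m) == 1.0

    def test_two_single_pixels_five_apart(self):
        a = np.zeros((12, 12), int)
        b = np.zeros((12, 12), int)
        a[5, 2] = 1
        b[5, 7] = 1
        # class-1 boundary distance is 5 px both ways; background boundary
        # distances stay below it, so check the class-1 term via n_classes=2
        per = hd95(a, b)
        assert per <= 5.0
        aa = a.astype(bool)
        bb = b.astype(bool)
        # direct check on the foreground class only
        from quct.objectives import _boundary_distances
        d_ab, _, _ = _boundary_distances(aa, bb)
        assert d_ab.max() == pytest.approx(5.0)

    def test_one_pixel_translation(self):
        a = np.zeros((16, 16), int)
        a[4:9, 4:9] = 1
        b = np.roll(a, 1, axis=1)
        assert hd95(a, b) == pytest.approx(1.0)
        assert boundary_f1(a, b, tolerance_px=1.0) == pytest.approx(1.0)

    def test_far_masks_score_zero_f1(self):
        a = np.zeros((20, 20), int)
        b = np.zeros((20, 20), int)
        a[1:3, 1:3] = 1
        b[15:17, 15:17] = 1
        # only the foreground class; background boundaries coincide
        from quct.objectives import _boundary_distances
        d, _, _ = _boundary_distances(a == 1, b == 1)
        assert (d > 1.0).all()

    def test_f1_non_decreasing_in_tolerance(self):
        pred, gt = random_pair(11, shape=(20, 20), C=3)
        scores = [boundary_f1(pred, gt, t) for t in (0.0, 1.0, 2.0, 4.0)]
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_class_missing_from_one_map_warns_and_skips(self):
        a = np.zeros((8, 8), int)
        b = np.zeros((8, 8), int)
        b[2:4, 2:4] = 1
        with pytest.warns(UserWarning):
            hd95(a, b, n_classes=2)

    def test_no_common_class_is_an_error(self):
        a = np.zeros((4, 4), int)
        b = np.ones((4, 4), int)
        with pytest.raises(ValueError):
            hd95(a, b, n_classes=2)


class TestEvaluate:
    def test_perfect_prediction_report(self):
        m, _ = random_pair(12, C=8)
        r = evaluate(m, m, DEFAULT_SCHEME)
        assert (r.dice, r.accuracy, r.iou, r.ssim, r.hd95, r.boundary_f1) == \
            (1.0, 1.0, 1.0, 1.0, 0.0, 1.0)

    def test_fields_within_declared_ranges(self):
        pred, gt = random_pair(13, C=8)
        r = evaluate(pred, gt, DEFAULT_SCHEME)
        assert 0 <= r.dice <= 1 and 0 <= r.accuracy <= 1
        assert 0 <= r.iou <= 1 and -1 <= r.ssim <= 1
        assert r.hd95 >= 0 and 0 <= r.boundary_f1 <= 1

    def test_macro_dice_equals_mean_of_per_class(self):
        pred, gt = random_pair(14, C=8)
        r = evaluate(pred, gt, DEFAULT_SCHEME)
        assert r.dice == pytest.approx(np.mean(list(r.per_class["dice"]
                                                    .values())))
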