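"""Training loss and evaluation metrics for quantized-SoS segmentation.

The training objective is the sum of a focal loss and a soft Dice loss.
Focal loss down-weights well-classified pixels by ``(1 - p_t)^gamma`` so
that rare, hard classes (small discs, thin tissue layers) keep
contributing; the Dice loss directly optimizes region overlap and is
insensitive to the water-background majority.

Evaluation reports per-class and macro Dice, IoU, pixel accuracy, SSIM on
the rendered SoS images, the 95th-percentile symmetric Hausdorff distance
(HD95, pixels) and the boundary F1 score under a distance tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion, distance_transform_edt, uniform_filter

from . import nn
from .phantoms import QuantizationScheme, labels_to_sos

__all__ = [
    "LossConfig", "MetricsReport",
    "focal_loss", "dice_loss", "combined_loss",
    "dice_coefficient", "iou", "pixel_accuracy", "ssim",
    "hd95", "boundary_f1", "evaluate",
]

_PROB_CLIP = 1e-7


@dataclass(frozen=True)
class LossConfig:
    gamma: float = 2.0             # focal focusing parameter
    alpha: float | tuple = 1.0     # class-balance factor (scalar or per-class)
    epsilon: float = 1e-5          # Dice stabilizer
    focal_weight: float = 1.0
    dice_weight: float = 1.0

    def __post_init__(self):
        if self.gamma < 0 or self.epsilon <= 0:
            raise ValueError("gamma must be >= 0 and epsilon > 0")
        if min(self.focal_weight, self.dice_weight) < 0:
            raise ValueError("loss weights must be >= 0")


def _check_shapes(probs, onehot):
    if probs.shape != onehot.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs "
                         f"targets {onehot.shape}")


def focal_loss(probs: nn.Tensor, onehot: nn.Tensor,
               cfg: LossConfig = LossConfig()) -> nn.Tensor:
    """Mean over pixels of ``-alpha (1 - p_t)^gamma log(p_t)``.

    ``probs`` and ``onehot`` are (N, C, H, W); p_t is the predicted
    probability of the true class, clipped away from 0/1 before the log.
    """
    _check_shapes(probs, onehot)
    if isinstance(cfg.alpha, (tuple, list)):
        a = np.asarray(cfg.alpha, dtype=np.float32).reshape(1, -1, 1, 1)
        weights = nn.Tensor(a) * onehot
    else:
        weights = onehot * float(cfg.alpha)
    pt = nn.clip(nn.reduce_sum(probs * onehot, axis=1, keepdims=True),
                 _PROB_CLIP, 1.0 - _PROB_CLIP)
    w = nn.reduce_sum(weights, axis=1, keepdims=True)
    modulator = nn.power(nn.clip(1.0 - pt + 0.0, 0.0, 1.0), cfg.gamma) \
        if cfg.gamma > 0 else None
    term = nn.log(pt) * -1.0
    if modulator is not None:
        term = term * modulator
    return (w * term).mean()


def dice_loss(probs: nn.Tensor, onehot: nn.Tensor,
              cfg: LossConfig = LossConfig()) -> nn.Tensor:
    """Soft Dice loss, computed per class and averaged over classes."""
    _check_shapes(probs, onehot)
    eps = cfg.epsilon
    inter = nn.reduce_sum(probs * onehot, axis=(0, 2, 3))
    sums = nn.reduce_sum(probs, axis=(0, 2, 3)) + nn.reduce_sum(onehot, axis=(0, 2, 3))
    # dice_c = (2 I_c + eps) / (S_c + eps); loss = 1 - mean_c dice_c
    dice = (inter * 2.0 + eps) * npow_inv(sums + eps)
    return 1.0 - dice.mean()


def npow_inv(t: nn.Tensor) -> nn.Tensor:
    return nn.power(t, -1.0)


def combined_loss(probs: nn.Tensor, onehot: nn.Tensor,
                  cfg: LossConfig = LossConfig()) -> nn.Tensor:
    return focal_loss(probs, onehot, cfg) * cfg.focal_weight \
        + dice_loss(probs, onehot, cfg) * cfg.dice_weight


# -- evaluation metrics (numpy) -------------------------------------------

@dataclass
class MetricsReport:
    dice: float
    accuracy: float
    iou: float
    ssim: float
    hd95: float
    boundary_f1: float
    per_class: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {k: getattr(self, k) for k in
               ("dice", "accuracy", "iou", "ssim", "hd95", "boundary_f1")}
        out["per_class"] = self.per_class
        return out


def _class_sets(pred, gt, n_classes=None):
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth shapes differ")
    if n_classes is None:
        n_classes = int(max(pred.max(), gt.max())) + 1
    return pred, gt, n_classes


def dice_coefficient(pred, gt, n_classes=None):
    """Per-class Dice 2|X∩Y|/(|X|+|Y|) and the macro mean.

    Classes absent from both maps are excluded from the macro mean;
    classes present in exactly one map score 0.
    """
    pred, gt, C = _class_sets(pred, gt, n_classes)
    per = {}
    for c in range(C):
        p, g = pred == c, gt == c
        np_, ng = p.sum(), g.sum()
        if np_ == 0 and ng == 0:
            continue
        per[c] = 2.0 * np.logical_and(p, g).sum() / (np_ + ng)
    if not per:
        raise ValueError("no class present in either map")
    return per, float(np.mean(list(per.values())))


def iou(pred, gt, n_classes=None):
    """Per-class intersection-over-union and the macro mean."""
    pred, gt, C = _class_sets(pred, gt, n_classes)
    per = {}
    for c in range(C):
        p, g = pred == c, gt == c
        union = np.logical_or(p, g).sum()
        if union == 0:
            continue
        per[c] = np.logical_and(p, g).sum() / union
    if not per:
        raise ValueError("no class present in either map")
    return per, float(np.mean(list(per.values())))


def pixel_accuracy(pred, gt) -> float:
    pred, gt, _ = _class_sets(pred, gt)
    return float((pred == gt).mean())


def ssim(img_a, img_b, dynamic_range: float, windowed: bool = False,
         window: int = 7) -> float:
    """Structural similarity from luminance, contrast and covariance terms.

    By default the statistics are global over the whole image; with
    ``windowed`` they are pooled over a sliding uniform window.  Stabilizers
    are c1 = (0.01 L)^2 and c2 = (0.03 L)^2 for dynamic range L.
    """
    x = np.asarray(img_a, dtype=np.float64)
    y = np.asarray(img_b, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("image shapes differ")
    c1 = (0.01 * dynamic_range) ** 2
    c2 = (0.03 * dynamic_range) ** 2
    if not windowed:
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cov = ((x - mx) * (y - my)).mean()
        return float((2 * mx * my + c1) * (2 * cov + c2)
                     / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))
    mx = uniform_filter(x, window)
    my = uniform_filter(y, window)
    vx = uniform_filter(x * x, window) - mx ** 2
    vy = uniform_filter(y * y, window) - my ** 2
    cov = uniform_filter(x * y, window) - mx * my
    smap = ((2 * mx * my + c1) * (2 * cov + c2)
            / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))
    return float(smap.mean())


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of a binary mask (8-connectivity erosion difference)."""
    if not mask.any():
        return mask
    eroded = binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    return mask & ~eroded


def _boundary_distances(a: np.ndarray, b: np.ndarray):
    """Distances from each boundary pixel of a to the nearest boundary of b."""
    ba, bb = _boundary(a), _boundary(b)
    dist_to_b = distance_transform_edt(~bb)
    return dist_to_b[ba], ba, bb


def hd95(pred, gt, n_classes=None) -> float:
    """Macro-average 95th-percentile symmetric boundary distance (pixels)."""
    pred, gt, C = _class_sets(pred, gt, n_classes)
    vals = []
    for c in range(C):
        p, g = pred == c, gt == c
        if not p.any() and not g.any():
            continue
        if not p.any() or not g.any():
            warnings.warn(f"class {c} missing from one map; skipped in HD95",
                          stacklevel=2)
            continue
        d_pg, _, _ = _boundary_distances(p, g)
        d_gp, _, _ = _boundary_distances(g, p)
        both = np.concatenate([d_pg, d_gp])
        vals.append(np.percentile(both, 95))
    if not vals:
        raise ValueError("no class present in both maps; HD95 undefined")
    return float(np.mean(vals))


def boundary_f1(pred, gt, tolerance_px: float = 1.0, n_classes=None) -> float:
    """Macro-average boundary F1 with a pixel-distance match tolerance."""
    if tolerance_px < 0:
        raise ValueError("tolerance must be >= 0")
    pred, gt, C = _class_sets(pred, gt, n_classes)
    vals = []
    for c in range(C):
        p, g = pred == c, gt == c
        if not p.any() and not g.any():
            continue
        if not p.any() or not g.any():
            warnings.warn(f"class {c} missing from one map; skipped in BF1",
                          stacklevel=2)
            continue
        d_pg, bp, bg = _boundary_distances(p, g)
        d_gp, _, _ = _boundary_distances(g, p)
        precision = (d_pg <= tolerance_px).mean() if bp.any() else 0.0
        recall = (d_gp <= tolerance_px).mean() if bg.any() else 0.0
        if precision + recall == 0:
            vals.append(0.0)
        else:
            vals.append(2 * precision * recall / (precision + recall))
    if not vals:
        raise ValueError("no class present in both maps; boundary F1 undefined")
    return float(np.mean(vals))


def evaluate(pred_labels, gt_labels, scheme: QuantizationScheme,
             bf1_tolerance_px: float = 1.0, windowed_ssim: bool = False
             ) -> MetricsReport:
    """Full metric suite for one prediction/ground-truth label pair.

    SSIM is computed on the SoS renderings of the label maps, with the
    scheme's SoS span as the dynamic range.
    """
    C = scheme.n_classes
    d_per, d_macro = dice_coefficient(pred_labels, gt_labels, C)
    i_per, i_macro = iou(pred_labels, gt_labels, C)
    acc = pixel_accuracy(pred_labels, gt_labels)
    s = ssim(labels_to_sos(pred_labels, scheme), labels_to_sos(gt_labels, scheme),
             scheme.sos_range, windowed=windowed_ssim)
    h = hd95(pred_labels, gt_labels, C)
    bf = boundary_f1(pred_labels, gt_labels, bf1_tolerance_px, C)
    return MetricsReport(d_macro, acc, i_macro, s, h, bf,
                         per_class={"dice": d_per, "iou": i_per})
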