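"""Tversky training objective and Jaccard-index evaluation protocol.

The Tversky index generalises Dice overlap with asymmetric penalties:
for one class, with predicted foreground probabilities ``P_b`` and binary
ground-truth indicators ``G_b`` (``P_nb = 1 - P_b``, ``G_nb = 1 - G_b``),

    T = (sum P_b G_b + w) /
        (sum P_b G_b + w  +  alpha * sum P_nb G_b  +  beta * sum P_b G_nb + w)

where ``alpha`` weights false negatives, ``beta`` false positives
(``alpha + beta = 1``) and ``w`` is a small smoothing constant guarding the
division.  The multi-class index averages the per-class indices (unweighted);
the training loss is ``1 - T``, minimised at perfect prediction.  At
``alpha = beta = 0.5`` and binary predictions the loss reduces to Dice loss.

Evaluation uses the Jaccard index JI_c = TP_c / (TP_c + FP_c + FN_c) from
pooled per-class pixel tallies; the mean JI is the unweighted mean over the
five classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np

from .model import CLASS_NAMES, NUM_CLASSES


@dataclass
class TverskyParams:
    """alpha penalises false negatives, beta false positives; alpha+beta=1."""

    alpha: float = 0.7
    beta: float = 0.3
    omega: float = 1e-6

    def __post_init__(self):
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise ValueError("alpha and beta must lie in (0, 1)")
        if abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ValueError("alpha + beta must equal 1")
        if self.omega <= 0:
            raise ValueError("omega must be positive")


def _check_pair(probs, gt):
    """Validate shapes/binarity; return (probs, gt, reduction axes).

    One-hot stacks (..., C) are reduced per class over all leading axes;
    a plain binary mask (no one-hot class axis) is treated as a single
    foreground class and reduced over everything.
    """
    probs = np.asarray(probs, dtype=np.float64)
    gt = np.asarray(gt)
    if probs.shape != gt.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs "
                         f"gt {gt.shape}")
    if not np.all(np.isfinite(probs)):
        raise ValueError("probabilities contain non-finite values")
    gtf = gt.astype(np.float64)
    if not np.all((gtf == 0) | (gtf == 1)):
        raise ValueError("ground truth must be binary (one-hot)")
    if gtf.ndim >= 3 and np.allclose(gtf.sum(axis=-1), 1.0):
        axes = tuple(range(probs.ndim - 1))   # per-class reduction
    else:
        axes = tuple(range(probs.ndim))       # single foreground mask
    return probs, gtf, axes


def _tversky_terms(probs, gt, axes, params: TverskyParams):
    """Per-class (numerator, denominator) of the Tversky index."""
    inter = (probs * gt).sum(axis=axes)
    fn = ((1.0 - probs) * gt).sum(axis=axes)
    fp = (probs * (1.0 - gt)).sum(axis=axes)
    w = params.omega
    num = inter + w
    den = inter + w + params.alpha * fn + params.beta * fp + w
    return num, den, fn, fp


def tversky_index(probs, gt, params: TverskyParams = TverskyParams()) -> float:
    """Multi-class Tversky index in (0, 1], averaged over classes.

    ``probs`` and ``gt`` share shape (..., H, W, C) with one-hot ``gt``;
    a plain binary mask pair is treated as a single foreground class.
    """
    probs, gt, axes = _check_pair(probs, gt)
    num, den, _, _ = _tversky_terms(probs, gt, axes, params)
    return float(np.mean(num / den))


def tversky_loss(probs, gt, params: TverskyParams = TverskyParams()) -> float:
    """1 - tversky_index; non-negative, zero at perfect prediction."""
    return 1.0 - tversky_index(probs, gt, params)


def tversky_loss_grad(probs, gt,
                      params: TverskyParams = TverskyParams()) -> np.ndarray:
    """Analytic d(loss)/d(probs), finite everywhere on (0, 1)."""
    probs, gt, axes = _check_pair(probs, gt)
    num, den, _, _ = _tversky_terms(probs, gt, axes, params)
    n_classes = probs.shape[-1] if len(axes) == probs.ndim - 1 else 1
    # dT/dp = (g * den - num * (g - alpha*g + beta*(1-g))) / den^2
    dden_dp = gt - params.alpha * gt + params.beta * (1.0 - gt)
    dT_dp = (gt * den - num * dden_dp) / (den ** 2)
    return (-dT_dp / n_classes).astype(np.float32)


def _loss_and_grad_fast(probs: np.ndarray, gt: np.ndarray,
                        params: TverskyParams):
    """(loss, dloss/dprobs) in float32 for the training loop.

    Skips input validation (the trainer controls its inputs) but is
    numerically identical to ``tversky_loss`` / ``tversky_loss_grad``
    up to float32 rounding.
    """
    axes = tuple(range(probs.ndim - 1))
    pg = probs * gt
    inter = pg.sum(axis=axes, dtype=np.float64)
    psum = probs.sum(axis=axes, dtype=np.float64)
    gsum = gt.sum(axis=axes, dtype=np.float64)
    fn = gsum - inter
    fp = psum - inter
    w = params.omega
    num = inter + w
    den = inter + w + params.alpha * fn + params.beta * fp + w
    loss = 1.0 - float(np.mean(num / den))
    c = probs.shape[-1]
    # dT/dp = (g*den - num*(g - alpha*g + beta*(1-g))) / den^2, per class
    cg = ((den - num * (1 - params.alpha - params.beta)) / den ** 2
          ).astype(np.float32)
    cb = (num * params.beta / den ** 2).astype(np.float32)
    # dT/dp = g*cg - cb for binary g, so dL/dp = (cb - g*cg) / C
    gprobs = (cb - gt * cg) / c
    return loss, gprobs.astype(np.float32)


# ---------------------------------------------------------------------------
# Confusion counts and Jaccard
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    """Per-class pixel tallies; arrays of length num_classes."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def num_classes(self) -> int:
        return len(self.tp)

    @property
    def total_pixels(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)

    @classmethod
    def zeros(cls, num_classes: int = NUM_CLASSES) -> "ConfusionCounts":
        z = np.zeros(num_classes, dtype=np.int64)
        return cls(z.copy(), z.copy(), z.copy(), z.copy())


def confusion_counts(pred, gt, num_classes: int = NUM_CLASSES
                     ) -> ConfusionCounts:
    """Pixel-level TP/FP/FN/TN per class from two label maps."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs "
                         f"gt {gt.shape}")
    p = pred.ravel().astype(np.int64)
    g = gt.ravel().astype(np.int64)
    for name, arr in (("pred", p), ("gt", g)):
        if arr.size and (arr.min() < 0 or arr.max() >= num_classes):
            raise ValueError(f"{name} labels outside [0, {num_classes})")
    cm = np.bincount(g * num_classes + p,
                     minlength=num_classes * num_classes
                     ).reshape(num_classes, num_classes)
    tp = np.diag(cm).copy()
    fn = cm.sum(axis=1) - tp      # gt = c, pred != c
    fp = cm.sum(axis=0) - tp      # pred = c, gt != c
    tn = p.size - tp - fn - fp
    return ConfusionCounts(tp, fp, fn, tn)


def jaccard_per_class(counts: ConfusionCounts) -> Dict[str, float]:
    """JI_c = TP / (TP + FP + FN) per class.

    A class absent from both prediction and ground truth (zero denominator)
    scores 1.0; callers can identify those via :func:`absent_classes`.
    """
    den = counts.tp + counts.fp + counts.fn
    ji = np.where(den > 0, counts.tp / np.maximum(den, 1), 1.0)
    names = CLASS_NAMES if counts.num_classes == NUM_CLASSES else \
        tuple(f"class{i}" for i in range(counts.num_classes))
    return {name: float(v) for name, v in zip(names, ji)}


def absent_classes(counts: ConfusionCounts) -> List[str]:
    """Classes in neither prediction nor ground truth (JI convention 1.0)."""
    den = counts.tp + counts.fp + counts.fn
    names = CLASS_NAMES if counts.num_classes == NUM_CLASSES else \
        tuple(f"class{i}" for i in range(counts.num_classes))
    return [name for name, d in zip(names, den) if d == 0]


def mean_ji(per_class: Dict[str, float]) -> float:
    """Unweighted arithmetic mean over the five classes."""
    missing = [c for c in CLASS_NAMES if c not in per_class]
    if missing:
        raise ValueError(f"missing class entries: {missing}")
    return float(np.mean([per_class[c] for c in CLASS_NAMES]))


@dataclass
class EvalReport:
    """Per-class and mean Jaccard indices over a pooled test set."""

    per_class_ji: Dict[str, float]
    mean_ji: float
    absent_classes: List[str] = field(default_factory=list)
    n_images: int = 0
    n_pixels: int = 0

    @classmethod
    def from_counts(cls, counts: ConfusionCounts, n_images: int = 0
                    ) -> "EvalReport":
        per_class = jaccard_per_class(counts)
        return cls(per_class_ji=per_class, mean_ji=mean_ji(per_class),
                   absent_classes=absent_classes(counts),
                   n_images=n_images, n_pixels=counts.total_pixels)

    def to_dict(self) -> dict:
        return {"per_class_ji": self.per_class_ji, "mean_ji": self.mean_ji,
                "absent_classes": self.absent_classes,
                "n_images": self.n_images, "n_pixels": self.n_pixels,
                "schema_version": 1}
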