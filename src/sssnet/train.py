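"""Training loop, inference and evaluation for SSS-Net.

Training minimises the Tversky loss (1 - index) with Adam (epsilon 1e-6),
a constant learning rate and gradient clipping by global L2 norm.  Batches
are drawn in a seed-deterministic order by reshuffling the training indices
each epoch.  Evaluation pools confusion counts over all test pixels before
computing per-class Jaccard indices (accumulate-then-divide, not a
per-image mean).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .metrics import (ConfusionCounts, EvalReport, TverskyParams,
                      _loss_and_grad_fast, confusion_counts)
from .model import SSSNet, save_checkpoint
from .nn import Adam, clip_global_norm, softmax, softmax_backward


@dataclass
class TrainConfig:
    """Reference optimisation settings: Adam at learning rate 1e-4 with
    epsilon 1e-6, mini-batches of 20 images, 11200 iterations, Tversky loss
    at alpha=0.7 / beta=0.3, gradient clipping at global L2 norm 1."""

    learning_rate: float = 1e-4
    adam_epsilon: float = 1e-6
    beta1: float = 0.9
    beta2: float = 0.999
    gradient_clip: Optional[float] = 1.0
    iterations: int = 11200
    batch_size: int = 20
    seed: int = 0
    loss: TverskyParams = field(default_factory=TverskyParams)
    val_fraction: float = 0.1
    val_interval: int = 0          # 0 disables periodic validation
    checkpoint_interval: int = 0   # 0: only a final checkpoint
    log_interval: int = 50

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size <= 0 or self.iterations <= 0:
            raise ValueError("batch_size and iterations must be positive")
        if isinstance(self.loss, dict):
            self.loss = TverskyParams(**self.loss)


@dataclass
class TrainLog:
    losses: List[float] = field(default_factory=list)
    val_iterations: List[int] = field(default_factory=list)
    val_mean_ji: List[float] = field(default_factory=list)
    wall_clock: List[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"losses": self.losses, "val_iterations": self.val_iterations,
                "val_mean_ji": self.val_mean_ji,
                "wall_clock": self.wall_clock, "schema_version": 1}


_FUSED_BUFS = {}


def _loss_and_score_grad(scores: np.ndarray, gt: np.ndarray,
                         params: TverskyParams):
    """Fused softmax + Tversky loss + gradient w.r.t. the raw scores.

    Numerically equivalent to softmax -> ``_loss_and_grad_fast`` ->
    ``softmax_backward`` (asserted in tests); the numba path avoids the
    large intermediate arrays of that sequence.
    """
    from . import _kernels

    if not _kernels.HAVE_NUMBA:
        probs = softmax(scores, axis=-1)
        loss, gprobs = _loss_and_grad_fast(probs, gt, params)
        return loss, softmax_backward(probs, gprobs, axis=-1)
    c = scores.shape[-1]
    scores2 = np.ascontiguousarray(scores).reshape(-1, c)
    gt2 = np.ascontiguousarray(gt).reshape(-1, c)
    key = (scores2.shape, c)
    if _FUSED_BUFS.get("key") != key:
        _FUSED_BUFS.update(
            key=key, probs=np.empty_like(scores2),
            gscores=np.empty_like(scores2),
            inter=np.zeros(c), psum=np.zeros(c), gsum=np.zeros(c))
    probs2 = _FUSED_BUFS["probs"]
    inter, psum, gsum = (_FUSED_BUFS["inter"], _FUSED_BUFS["psum"],
                         _FUSED_BUFS["gsum"])
    _kernels.softmax_stats_kernel(c)(scores2, gt2, probs2, inter, psum, gsum)
    fn = gsum - inter
    fp = psum - inter
    w = params.omega
    num = inter + w
    den = inter + w + params.alpha * fn + params.beta * fp + w
    loss = 1.0 - float(np.mean(num / den))
    cg = ((den - num * (1 - params.alpha - params.beta)) / den ** 2 / c
          ).astype(np.float32)
    cb = (num * params.beta / den ** 2 / c).astype(np.float32)
    gscores2 = _FUSED_BUFS["gscores"]
    _kernels.softmax_tversky_bwd_kernel(c)(probs2, gt2, cg, cb, gscores2)
    return loss, gscores2.reshape(scores.shape)


def _to_input(images: np.ndarray) -> np.ndarray:
    """uint8 images -> float32 network input in [-1, 1] (centered)."""
    x = np.ascontiguousarray(images, dtype=np.float32)
    x -= np.float32(127.5)
    x /= np.float32(127.5)
    return x


def _onehot_batch(labels: np.ndarray, num_classes: int) -> np.ndarray:
    return np.eye(num_classes, dtype=np.float32)[labels]


def train(model: SSSNet, dataset: Sequence[Tuple[np.ndarray, np.ndarray]],
          config: TrainConfig, out_dir=None,
          progress: bool = False) -> Tuple[SSSNet, TrainLog]:
    """Train ``model`` in place on (image, label map) pairs.

    A ``val_fraction`` slice of the training data is held aside for periodic
    mean-JI monitoring when ``val_interval`` > 0; it never touches test data.
    Aborts with a diagnostic naming the batch if the loss goes non-finite.
    """
    if not len(dataset):
        raise ValueError("dataset is empty")
    num_classes = model.spec.num_classes
    rng = np.random.default_rng(config.seed)

    n = len(dataset)
    idx = rng.permutation(n)
    n_val = int(round(n * config.val_fraction)) if config.val_interval else 0
    val_idx, train_idx = idx[:n_val], idx[n_val:]
    if not len(train_idx):
        raise ValueError("no training examples left after validation split")

    images = np.stack([np.asarray(dataset[i][0]) for i in train_idx])
    labels = np.stack([np.asarray(dataset[i][1]) for i in train_idx])
    if images.shape[1] % model.spec.input_divisor or \
            images.shape[2] % model.spec.input_divisor:
        raise ValueError("image dims must be divisible by "
                         f"{model.spec.input_divisor}")
    val_pairs = [dataset[i] for i in val_idx]

    params = [p for _, p in model.named_parameters()]
    opt = Adam(params, lr=config.learning_rate, beta1=config.beta1,
               beta2=config.beta2, eps=config.adam_epsilon)
    log = TrainLog()
    t0 = time.time()
    order = np.empty(0, dtype=np.int64)
    it_range = range(config.iterations)
    if progress:
        from tqdm import tqdm
        it_range = tqdm(it_range, desc="train")
    for it in it_range:
        while len(order) < config.batch_size:
            order = np.concatenate(
                [order, rng.permutation(len(train_idx))])
        batch, order = order[:config.batch_size], order[config.batch_size:]
        x = _to_input(images[batch])
        gt = _onehot_batch(labels[batch], num_classes)

        scores = model.forward(x, training=True)
        loss, gscores = _loss_and_score_grad(scores, gt, config.loss)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss at iteration {it} on batch indices "
                f"{train_idx[batch].tolist()}")
        model.backward(gscores)
        clip_global_norm(params, config.gradient_clip)
        opt.step()

        log.losses.append(float(loss))
        log.wall_clock.append(time.time() - t0)
        if config.val_interval and val_pairs and \
                (it + 1) % config.val_interval == 0:
            report = evaluate(model, val_pairs)
            log.val_iterations.append(it + 1)
            log.val_mean_ji.append(report.mean_ji)
        if out_dir and config.checkpoint_interval and \
                (it + 1) % config.checkpoint_interval == 0:
            save_checkpoint(model,
                            Path(out_dir) / f"checkpoint_{it + 1:06d}.npz")
    if out_dir:
        save_checkpoint(model, Path(out_dir) / "checkpoint_final.npz")
    return model, log


def predict(model: SSSNet, image: np.ndarray,
            return_masks: bool = False):
    """Segment one image: per-pixel argmax over the 5-channel probabilities.

    Ties break toward the lowest class index.  With ``return_masks`` the
    binary one-hot mask stack is returned alongside the label map.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    x = _to_input(image[None])
    probs = model.predict_probs(x)[0]
    label_map = probs.argmax(axis=-1).astype(np.int64)   # lowest-index ties
    if return_masks:
        masks = np.eye(model.spec.num_classes, dtype=np.uint8)[label_map]
        return label_map, masks
    return label_map


def evaluate(model: SSSNet,
             test_pairs: Sequence[Tuple[np.ndarray, np.ndarray]],
             batch_size: int = 8) -> EvalReport:
    """Pooled-confusion evaluation over a test set."""
    if not len(test_pairs):
        raise ValueError("test set is empty")
    counts = ConfusionCounts.zeros(model.spec.num_classes)
    for start in range(0, len(test_pairs), batch_size):
        chunk = test_pairs[start:start + batch_size]
        x = _to_input(np.stack([np.asarray(img) for img, _ in chunk]))
        probs = model.predict_probs(x)
        preds = probs.argmax(axis=-1)
        for (_, gt), pred in zip(chunk, preds):
            counts = counts + confusion_counts(pred, np.asarray(gt),
                                               model.spec.num_classes)
    return EvalReport.from_counts(counts, n_images=len(test_pairs))
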