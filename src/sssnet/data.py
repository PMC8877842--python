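"""Ground-truth palette handling, one-hot encoding, dataset split and the
x16 paired augmentation protocol.

Ground-truth label images are colour-coded: background black, zona pellucida
(ZP) green, trophectoderm (TE) red, blastocoel (BL) yellow, inner cell mass
(ICM) blue.  Label maps use the fixed ordering background=0, ZP=1, TE=2,
BL=3, ICM=4.  Pixel coordinates are row-major, origin top-left, 0-based.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
from PIL import Image
from scipy import ndimage

from .model import CLASS_NAMES, NUM_CLASSES


@dataclass(frozen=True)
class Palette:
    """Ordered class list with display colours."""

    names: Tuple[str, ...] = CLASS_NAMES
    colors: Tuple[Tuple[int, int, int], ...] = (
        (0, 0, 0),        # background: black
        (0, 255, 0),      # ZP: green
        (255, 0, 0),      # TE: red
        (255, 255, 0),    # BL: yellow
        (0, 0, 255),      # ICM: blue
    )

    def __post_init__(self):
        if len(self.names) != len(self.colors):
            raise ValueError("names and colors must align")
        if len(set(self.colors)) != len(self.colors):
            raise ValueError("palette colors must be pairwise distinct")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.colors, dtype=np.int32)

    def render(self, label_map: np.ndarray) -> np.ndarray:
        """Paint a label map with the palette colours -> uint8 RGB."""
        lm = _check_labelmap(label_map, len(self.names))
        return self.array[lm].astype(np.uint8)


DEFAULT_PALETTE = Palette()


def _check_labelmap(lm, num_classes=NUM_CLASSES):
    lm = np.asarray(lm)
    if lm.ndim != 2:
        raise ValueError("label map must be 2-D")
    if lm.size and (lm.min() < 0 or lm.max() >= num_classes):
        raise ValueError(f"labels outside [0, {num_classes})")
    return lm.astype(np.int64)


def decode_gt(color_image: np.ndarray, palette: Palette = DEFAULT_PALETTE,
              tolerance: float = 10.0) -> np.ndarray:
    """Map a colour-coded GT image to a label map by nearest palette colour.

    Each pixel takes the class of the nearest palette colour (Euclidean in
    RGB).  Any pixel farther than ``tolerance`` from every palette colour is
    an error; the message lists the offending colours and an example
    coordinate for each.
    """
    img = np.asarray(color_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) colour image")
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    flat = img.reshape(-1, 3).astype(np.float64)
    dists = np.linalg.norm(flat[:, None, :] - palette.array[None, :, :],
                           axis=2)
    labels = dists.argmin(axis=1)
    mind = dists[np.arange(len(flat)), labels]
    bad = mind > tolerance
    if bad.any():
        idx = np.flatnonzero(bad)
        h, w = img.shape[:2]
        samples = []
        seen = set()
        for i in idx:
            color = tuple(int(v) for v in flat[i])
            if color not in seen:
                seen.add(color)
                samples.append(f"{color} at (row={i // w}, col={i % w})")
            if len(samples) >= 5:
                break
        raise ValueError(
            f"{bad.sum()} pixel(s) beyond tolerance {tolerance} of every "
            f"palette color; offending colors include: {'; '.join(samples)}")
    return labels.reshape(img.shape[:2])


# ---------------------------------------------------------------------------
# One-hot mask stacks
# ---------------------------------------------------------------------------

def encode_onehot(label_map: np.ndarray,
                  num_classes: int = NUM_CLASSES) -> np.ndarray:
    """Label map (H, W) -> binary one-hot stack (H, W, num_classes)."""
    lm = _check_labelmap(label_map, num_classes)
    return (np.eye(num_classes, dtype=np.uint8))[lm]


def decode_onehot(mask_stack: np.ndarray, strict: bool = False) -> np.ndarray:
    """One-hot stack (H, W, C) -> label map; inverse of :func:`encode_onehot`.

    A stack that is not exactly one-hot raises when ``strict`` and otherwise
    resolves ties toward the lowest class index with a warning.
    """
    stack = np.asarray(mask_stack)
    if stack.ndim != 3:
        raise ValueError("mask stack must be (H, W, C)")
    sums = stack.sum(axis=-1)
    binary = np.all((stack == 0) | (stack == 1))
    if not (binary and np.all(sums == 1)):
        if strict:
            raise ValueError("mask stack is not one-hot")
        warnings.warn("mask stack is not one-hot; ties broken toward the "
                      "lowest class index", stacklevel=2)
    return stack.argmax(axis=-1).astype(np.int64)


# ---------------------------------------------------------------------------
# Dataset split
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    n_total: int
    train_fraction: float = 0.85
    seed: int = 0

    def __post_init__(self):
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


def split_dataset(spec: SplitSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index partition, seed-deterministic.

    Train size is round(n_total * train_fraction); e.g. 235 at 0.85 gives
    200 train / 35 test.
    """
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(spec.n_total)
    n_train = int(round(spec.n_total * spec.train_fraction))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairTransform:
    """One deterministic paired transform: flips, rotation, translation.

    ``kind`` is 'flip', 'rotate', 'translate' or 'flip_rotate'.  Images are
    interpolated bilinearly with edge replication at exposed borders; label
    maps use nearest-neighbour interpolation with background fill, so no new
    class value can be created.
    """

    kind: str
    angle: float = 0.0
    shift: Tuple[int, int] = (0, 0)     # (rows, cols)
    flip_axis: int = -1                  # 0 vertical, 1 horizontal, 2 both

    def apply_image(self, img: np.ndarray) -> np.ndarray:
        out = img.astype(np.float32)
        out = self._flip(out)
        if self.kind in ("rotate", "flip_rotate") and self.angle:
            out = ndimage.rotate(out, self.angle, axes=(0, 1), reshape=False,
                                 order=1, mode="nearest")
        if self.kind == "translate" and any(self.shift):
            shift = (*self.shift, 0) if out.ndim == 3 else self.shift
            out = ndimage.shift(out, shift, order=1, mode="nearest")
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)

    def apply_labelmap(self, lm: np.ndarray) -> np.ndarray:
        out = lm.astype(np.int32)
        out = self._flip(out)
        if self.kind in ("rotate", "flip_rotate") and self.angle:
            out = ndimage.rotate(out, self.angle, axes=(0, 1), reshape=False,
                                 order=0, mode="constant", cval=0)
        if self.kind == "translate" and any(self.shift):
            out = ndimage.shift(out, self.shift, order=0, mode="constant",
                                cval=0)
        return out.astype(np.int64)

    def _flip(self, arr):
        if self.kind in ("flip", "flip_rotate"):
            if self.flip_axis in (0, 2):
                arr = arr[::-1]
            if self.flip_axis in (1, 2):
                arr = arr[:, ::-1]
        return np.ascontiguousarray(arr)


@dataclass
class AugmentationPlan:
    """An ordered list of 16 deterministic paired transforms."""

    transforms: List[PairTransform]
    border_fill: str = "label: background fill; image: edge replication"

    def __post_init__(self):
        if len(self.transforms) != 16:
            raise ValueError("the plan must contain exactly 16 transforms")


def default_augmentation_plan() -> AugmentationPlan:
    """Flips (3), rotations +/-5, +/-10, +/-15 deg (6), translations of 10 px
    along each axis and the diagonal pair (6), plus one flipped rotation,
    totalling 16 transformed copies per source pair (200 -> 3200)."""
    t = [
        PairTransform("flip", flip_axis=1),                 # horizontal
        PairTransform("flip", flip_axis=0),                 # vertical
        PairTransform("flip", flip_axis=2),                 # both
        PairTransform("rotate", angle=5.0),
        PairTransform("rotate", angle=-5.0),
        PairTransform("rotate", angle=10.0),
        PairTransform("rotate", angle=-10.0),
        PairTransform("rotate", angle=15.0),
        PairTransform("rotate", angle=-15.0),
        PairTransform("translate", shift=(10, 0)),
        PairTransform("translate", shift=(-10, 0)),
        PairTransform("translate", shift=(0, 10)),
        PairTransform("translate", shift=(0, -10)),
        PairTransform("translate", shift=(10, 10)),
        PairTransform("translate", shift=(-10, -10)),
        PairTransform("flip_rotate", angle=5.0, flip_axis=1),
    ]
    return AugmentationPlan(t)


def augment(pairs: Sequence[Tuple[np.ndarray, np.ndarray]],
            plan: AugmentationPlan = None
            ) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Apply the plan to each (image, label map) pair: 16 x len(pairs) out.

    The same geometric operation is applied to image and GT; GT uses
    nearest-neighbour interpolation so labels are never blended.
    """
    plan = plan or default_augmentation_plan()
    out = []
    for img, lm in pairs:
        img = np.asarray(img)
        lm = np.asarray(lm)
        if img.shape[:2] != lm.shape[:2]:
            raise ValueError(f"image/GT dims mismatch: {img.shape[:2]} vs "
                             f"{lm.shape[:2]}")
        for t in plan.transforms:
            out.append((t.apply_image(img), t.apply_labelmap(lm)))
    return out


# ---------------------------------------------------------------------------
# Image / label-map I/O
# ---------------------------------------------------------------------------

_IMAGE_EXTS = {".png", ".bmp", ".jpg", ".jpeg"}


def read_image(path) -> np.ndarray:
    """Read an image as 8-bit RGB (H, W, 3).

    16-bit inputs are rescaled to 8 bits by dividing by 257 (65535 -> 255);
    grayscale images are replicated across the three channels.
    """
    path = Path(path)
    if path.suffix.lower() not in _IMAGE_EXTS:
        raise ValueError(f"unknown image extension: {path.suffix!r}")
    with Image.open(path) as im:
        im.load()
        arr = np.asarray(im)
    if arr.dtype == np.uint16:
        arr = (arr / 257.0).round().astype(np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return np.ascontiguousarray(arr, dtype=np.uint8)


def write_image(image: np.ndarray, path) -> None:
    path = Path(path)
    if path.suffix.lower() not in _IMAGE_EXTS:
        raise ValueError(f"unknown image extension: {path.suffix!r}")
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        raise ValueError("images are written as 8-bit")
    Image.fromarray(arr).save(path)


def write_labelmap(label_map: np.ndarray, path,
                   palette: Palette = DEFAULT_PALETTE) -> None:
    """Write a label map as a paletted PNG (lossless round trip)."""
    path = Path(path)
    if path.suffix.lower() != ".png":
        raise ValueError("label maps are stored as paletted PNG")
    lm = _check_labelmap(label_map, len(palette.names))
    im = Image.fromarray(lm.astype(np.uint8), mode="P")
    pal = np.zeros((256, 3), dtype=np.uint8)
    pal[:len(palette.colors)] = palette.array
    im.putpalette(pal.ravel().tolist())
    im.save(path)


def read_labelmap(path, palette: Palette = DEFAULT_PALETTE,
                  tolerance: float = 0.0) -> np.ndarray:
    """Read a label map from a paletted PNG (or a palette-coloured RGB)."""
    path = Path(path)
    with Image.open(path) as im:
        im.load()
        if im.mode == "P":
            return np.asarray(im).astype(np.int64)
        arr = np.asarray(im.convert("RGB"))
    return decode_gt(arr, palette, tolerance)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def write_manifest(rows: Sequence[dict], path) -> None:
    """Dataset manifest CSV: one row per pair (image path, GT path, split,
    plus any provenance columns)."""
    rows = list(rows)
    if not rows:
        raise ValueError("empty manifest")
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)


def read_manifest(path) -> List[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))
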