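"""Error-overlay rendering and mask-based morphometrics.

The overlay convention: pixels where prediction and ground truth agree are
painted with the class colour; disagreeing pixels whose ground truth is a
foreground class are painted pink (false negatives); disagreeing pixels on
ground-truth background (a foreground class predicted where there is none)
are painted black — which coincides with the background colour, so the
black FP population is only separable from correct background by consulting
the masks, a limitation of the convention itself.

Morphometrics summarise a predicted label map for embryological reading:
per-class areas and image fractions, mean zona-pellucida thickness from the
medial-axis distance transform (thickness = 2 x mean medial distance),
blastocoel presence (area fraction against a tool threshold, not a clinical
cut-off) and component centroids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.morphology import medial_axis

from .data import DEFAULT_PALETTE, Palette, _check_labelmap
from .model import CLASS_NAMES

_ZP_INDEX = CLASS_NAMES.index("ZP")
_BL_INDEX = CLASS_NAMES.index("BL")


@dataclass(frozen=True)
class OverlayStyle:
    palette: Palette = DEFAULT_PALETTE
    false_negative_color: Tuple[int, int, int] = (255, 105, 180)  # pink
    false_positive_color: Tuple[int, int, int] = (0, 0, 0)        # black

    def __post_init__(self):
        fg = set(self.palette.colors[1:])   # background exempt (see module
        for color in (self.false_negative_color,  # docstring)
                      self.false_positive_color):
            if color in fg:
                raise ValueError("FN/FP colors must differ from all "
                                 "foreground class colors")
        if self.false_negative_color == self.false_positive_color:
            raise ValueError("FN and FP colors must differ")


def overlay_errors(pred: np.ndarray, gt: np.ndarray,
                   style: OverlayStyle = OverlayStyle()) -> np.ndarray:
    """Render the agreement/disagreement overlay as an RGB image."""
    pred = _check_labelmap(pred)
    gt = _check_labelmap(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs "
                         f"gt {gt.shape}")
    out = style.palette.render(gt).copy()
    disagree = pred != gt
    fn = disagree & (gt != 0)      # ground truth foreground missed
    fp = disagree & (gt == 0)      # foreground predicted on background
    out[fn] = style.false_negative_color
    out[fp] = style.false_positive_color
    return out


# ---------------------------------------------------------------------------
# Morphometrics
# ---------------------------------------------------------------------------

def component_area(label_map: np.ndarray, cls: int) -> Tuple[int, float]:
    """Exact pixel count of one class and its fraction of the image."""
    lm = _check_labelmap(label_map)
    if not 0 <= cls < len(CLASS_NAMES):
        raise ValueError(f"class index {cls} outside [0, {len(CLASS_NAMES)})")
    count = int((lm == cls).sum())
    return count, count / lm.size


@dataclass
class ZpThickness:
    present: bool
    mean: Optional[float] = None
    min: Optional[float] = None
    max: Optional[float] = None
    profile: Optional[np.ndarray] = None   # (n_bins, 2): angle, thickness


def zp_thickness(label_map: np.ndarray, n_angle_bins: int = 36
                 ) -> ZpThickness:
    """ZP thickness from the medial axis: 2 x distance at skeleton pixels.

    Returns an absent-flagged result (no exception) when the ZP class is
    empty.  The per-angle profile bins skeleton pixels by angle about the
    ZP centroid.
    """
    lm = _check_labelmap(label_map)
    mask = lm == _ZP_INDEX
    if not mask.any():
        return ZpThickness(present=False)
    skel, dist = medial_axis(mask, return_distance=True)
    th = 2.0 * dist[skel]
    if th.size == 0:   # degenerate 1-px region
        return ZpThickness(present=True, mean=1.0, min=1.0, max=1.0,
                           profile=np.empty((0, 2)))
    cy, cx = ndimage.center_of_mass(mask)
    ys, xs = np.nonzero(skel)
    angles = np.arctan2(ys - cy, xs - cx)
    bins = np.linspace(-np.pi, np.pi, n_angle_bins + 1)
    which = np.clip(np.digitize(angles, bins) - 1, 0, n_angle_bins - 1)
    profile = []
    for b in range(n_angle_bins):
        sel = which == b
        if sel.any():
            profile.append(((bins[b] + bins[b + 1]) / 2,
                            float(th[sel].mean())))
    return ZpThickness(present=True, mean=float(th.mean()),
                       min=float(th.min()), max=float(th.max()),
                       profile=np.asarray(profile))


def blastocoel_presence(label_map: np.ndarray, min_fraction: float = 0.01
                        ) -> Tuple[bool, float]:
    """Blastocoel formation indicator: BL area fraction >= ``min_fraction``.

    The default threshold is a tool parameter for flagging an established
    cavity in a mask, not a clinical grading criterion.
    """
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must lie in [0, 1)")
    _, fraction = component_area(label_map, _BL_INDEX)
    return fraction >= min_fraction, fraction


@dataclass
class MorphometricsReport:
    areas_px: Dict[str, int]
    fractions: Dict[str, float]
    zp_thickness_mean: Optional[float]
    zp_present: bool
    bl_present: bool
    bl_fraction: float
    centroids: Dict[str, Optional[Tuple[float, float]]]

    def to_dict(self) -> dict:
        return {"areas_px": self.areas_px, "fractions": self.fractions,
                "zp_thickness_mean": self.zp_thickness_mean,
                "zp_present": self.zp_present, "bl_present": self.bl_present,
                "bl_fraction": self.bl_fraction,
                "centroids": {k: (list(v) if v is not None else None)
                              for k, v in self.centroids.items()},
                "schema_version": 1}


def compute_morphometrics(label_map: np.ndarray,
                          bl_min_fraction: float = 0.01
                          ) -> MorphometricsReport:
    """All mask morphometrics for one label map."""
    lm = _check_labelmap(label_map)
    areas, fractions, centroids = {}, {}, {}
    for i, name in enumerate(CLASS_NAMES):
        count, frac = component_area(lm, i)
        areas[name], fractions[name] = count, frac
        if count:
            cy, cx = ndimage.center_of_mass(lm == i)
            centroids[name] = (float(cy), float(cx))
        else:
            centroids[name] = None
    zp = zp_thickness(lm)
    bl_present, bl_fraction = blastocoel_presence(lm, bl_min_fraction)
    return MorphometricsReport(
        areas_px=areas, fractions=fractions,
        zp_thickness_mean=zp.mean if zp.present else None,
        zp_present=zp.present, bl_present=bl_present,
        bl_fraction=bl_fraction, centroids=centroids)
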