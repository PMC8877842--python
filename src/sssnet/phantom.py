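"""Synthetic blastocyst phantoms with exact ground truth.

A phantom emulates the appearance of a Hoffman-Modulation-Contrast
blastocyst micrograph: a bright zona pellucida (ZP) annulus enclosing a
trophectoderm (TE) cell band, a dark blastocoel (BL) cavity filling the
interior, and an inner-cell-mass (ICM) blob attached to the TE band on one
side.  Gray levels of TE and ICM are kept deliberately close
(``te_icm_contrast``), the field carries a smooth low-order illumination
ramp, and pixel noise is Gaussian.  The ground truth is derived from the
exact generating geometry before any intensity effects, so label maps are
noise-free by construction.

Phantoms are a statistical stand-in for real micrographs, not a claim of
optical realism.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

BACKGROUND, ZP, TE, BL, ICM = range(5)


@dataclass
class PhantomParams:
    """Geometry plus intensity/noise parameters of one phantom.

    Lengths are pixels; ``icm_angle`` is radians; ``ellipticity`` >= 1
    compresses the vertical semi-axis (boundary at
    sqrt((e*dy)^2 + dx^2) = r).  ``class_intensities`` are mean 8-bit gray
    levels per class in label order; the ICM level is clamped to within
    ``te_icm_contrast`` of the TE level.  ``illumination_gradient`` is the
    peak amplitude of a low-order polynomial ramp; ``noise_sigma`` the
    Gaussian pixel noise level.
    """

    image_size: int = 256
    center: Optional[Tuple[float, float]] = None   # (row, col)
    outer_radius: float = 96.0
    zp_thickness: float = 12.0
    te_thickness: float = 13.0
    icm_angle: float = 0.6
    icm_radius: float = 30.0
    ellipticity: float = 1.05
    class_intensities: Tuple[float, float, float, float, float] = (
        95.0, 175.0, 128.0, 62.0, 134.0)
    te_icm_contrast: float = 8.0
    illumination_gradient: float = 18.0
    noise_sigma: float = 8.0
    seed: int = 0

    def __post_init__(self):
        s = self.image_size
        if s <= 0 or s % 8:
            raise ValueError("image_size must be positive and divisible by 8")
        if self.center is None:
            self.center = (s / 2.0, s / 2.0)
        for name in ("outer_radius", "zp_thickness", "te_thickness",
                     "icm_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        inner = self.outer_radius - self.zp_thickness - self.te_thickness
        if not inner > self.icm_radius:
            raise ValueError(
                "nested geometry violated: outer_radius - zp_thickness - "
                f"te_thickness = {inner:.1f} must exceed icm_radius = "
                f"{self.icm_radius:.1f}")
        if self.ellipticity < 1:
            raise ValueError("ellipticity must be >= 1")
        r, c = self.center
        if (c - self.outer_radius < 0 or c + self.outer_radius > s
                or r - self.outer_radius / self.ellipticity < 0
                or r + self.outer_radius / self.ellipticity > s):
            raise ValueError("geometry does not fit inside the image")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class Phantom:
    image: np.ndarray      # (H, W, 3) uint8
    gt: np.ndarray         # (H, W) int label map
    params: PhantomParams


def _elliptic_radius(params: PhantomParams):
    s = params.image_size
    rows, cols = np.mgrid[0:s, 0:s].astype(np.float64) + 0.5
    dy = rows - params.center[0]
    dx = cols - params.center[1]
    return np.sqrt((params.ellipticity * dy) ** 2 + dx ** 2), rows, cols


def _te_disc_centers(params: PhantomParams, rng: np.random.Generator):
    """Cell-like discs placed on the TE mid-band ring."""
    r_zp_inner = params.outer_radius - params.zp_thickness
    mid = r_zp_inner - params.te_thickness / 2.0
    disc_r = 0.85 * params.te_thickness
    n = max(8, int(round(2 * np.pi * mid / (1.2 * disc_r))))
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    angles = angles + rng.uniform(-0.2, 0.2, size=n) / max(n, 1)
    radii = mid + rng.uniform(-0.15, 0.15, size=n) * params.te_thickness
    cy = params.center[0] + radii * np.sin(angles) / params.ellipticity
    cx = params.center[1] + radii * np.cos(angles)
    return np.stack([cy, cx], axis=1), disc_r


def generate_phantom(params: PhantomParams) -> Phantom:
    """Render one phantom; deterministic under ``params.seed``.

    The label map encodes the exact nested topology (ZP annulus containing
    the TE band, BL cavity and a one-sided ICM disc touching the band); the
    image adds class intensities, TE cell texture, the illumination ramp and
    Gaussian noise, clipped to [0, 255].
    """
    rng = np.random.default_rng(params.seed)
    rho, rows, cols = _elliptic_radius(params)
    r_out = params.outer_radius
    r_zp_inner = r_out - params.zp_thickness
    r_te_inner = r_zp_inner - params.te_thickness

    gt = np.full((params.image_size,) * 2, BACKGROUND, dtype=np.int64)
    inside = rho < r_out
    gt[inside & (rho >= r_zp_inner)] = ZP

    # TE: the annular band plus overlapping cell discs that scallop inward
    te_mask = inside & (rho < r_zp_inner) & (rho >= r_te_inner)
    centers, disc_r = _te_disc_centers(params, rng)
    for cy, cx in centers:
        d2 = (params.ellipticity * (rows - cy)) ** 2 + (cols - cx) ** 2
        te_mask |= (d2 < disc_r ** 2) & (rho < r_zp_inner)
    gt[te_mask & (gt == BACKGROUND)] = TE

    # ICM: a disc tangent to the inner TE boundary on one side
    d_icm = r_te_inner - params.icm_radius
    icm_cy = params.center[0] + d_icm * np.sin(params.icm_angle) \
        / params.ellipticity
    icm_cx = params.center[1] + d_icm * np.cos(params.icm_angle)
    d2 = (params.ellipticity * (rows - icm_cy)) ** 2 + (cols - icm_cx) ** 2
    icm_mask = (d2 < params.icm_radius ** 2) & (rho < r_zp_inner) \
        & (gt == BACKGROUND)
    gt[icm_mask] = ICM

    # BL: the remaining cavity inside the TE band
    gt[(rho < r_zp_inner) & (gt == BACKGROUND)] = BL

    # ---- intensity image -------------------------------------------------
    levels = np.asarray(params.class_intensities, dtype=np.float64).copy()
    delta = np.clip(levels[ICM] - levels[TE], -params.te_icm_contrast,
                    params.te_icm_contrast)
    levels[ICM] = levels[TE] + delta
    img = levels[gt]

    # TE cell texture: brighten disc rims slightly (zero-mean overall).
    # Texture and RGB jitter are noise-like realism effects: at
    # noise_sigma == 0 the phantom is the exact piecewise-constant limit.
    if params.noise_sigma > 0 and params.te_thickness >= 4:
        tex = rng.uniform(-6, 6, size=len(centers))
        tex -= tex.mean()
        for (cy, cx), t in zip(centers, tex):
            d2 = (params.ellipticity * (rows - cy)) ** 2 \
                + (cols - cx) ** 2
            img[(d2 < disc_r ** 2) & (gt == TE)] += t

    if params.illumination_gradient:
        xn = (cols / params.image_size) * 2 - 1
        yn = (rows / params.image_size) * 2 - 1
        a, b, c = rng.uniform(-1, 1, size=3)
        ramp = a * xn + b * yn + c * xn * yn
        m = np.abs(ramp).max()
        if m > 0:
            img = img + params.illumination_gradient * ramp / m

    # near-gray RGB: per-channel scalar jitter on a replicated gray image
    if params.noise_sigma > 0:
        img = img + rng.normal(0, params.noise_sigma, size=img.shape)
        jitter = rng.uniform(-2, 2, size=3)
    else:
        jitter = np.zeros(3)
    rgb = img[..., None] + jitter[None, None, :]
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    return Phantom(image=rgb, gt=gt, params=params)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def default_param_ranges(image_size: int = 256) -> Dict[str, Tuple[float,
                                                                   float]]:
    """Uniform sampling ranges, scaled with the image side length."""
    s = float(image_size)
    return {
        "outer_radius": (0.33 * s, 0.42 * s),
        "zp_thickness": (0.035 * s, 0.055 * s),
        "te_thickness": (0.042 * s, 0.062 * s),
        "icm_radius": (0.10 * s, 0.14 * s),
        "icm_angle": (0.0, 2 * np.pi),
        "ellipticity": (1.0, 1.15),
        "center_jitter": (-0.03 * s, 0.03 * s),
        "illumination_gradient": (10.0, 25.0),
        "noise_sigma": (6.0, 10.0),
    }


def generate_dataset(n: int, param_ranges: Optional[dict] = None,
                     seed: int = 0, image_size: int = 256
                     ) -> Tuple[List[Phantom], List[dict]]:
    """Generate ``n`` phantoms with parameters drawn uniformly from ranges.

    Each phantom gets an independent seed derived from ``seed``; the returned
    manifest records every generating parameter.  A degenerate range
    (min == max) pins the parameter to that value; an inverted range is an
    error.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    ranges = dict(default_param_ranges(image_size))
    if param_ranges:
        ranges.update(param_ranges)
    for k, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"empty range for {k!r}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2 ** 31 - 1, size=2 * n)
    phantoms, manifest = [], []
    for i in range(n):
        draw = np.random.default_rng(int(child_seeds[2 * i]))

        def u(key):
            lo, hi = ranges[key]
            return float(lo if lo == hi else draw.uniform(lo, hi))

        jr, jc = u("center_jitter"), u("center_jitter")
        params = PhantomParams(
            image_size=image_size,
            center=(image_size / 2.0 + jr, image_size / 2.0 + jc),
            outer_radius=u("outer_radius"),
            zp_thickness=u("zp_thickness"),
            te_thickness=u("te_thickness"),
            icm_angle=u("icm_angle"),
            icm_radius=u("icm_radius"),
            ellipticity=u("ellipticity"),
            illumination_gradient=u("illumination_gradient"),
            noise_sigma=u("noise_sigma"),
            seed=int(child_seeds[2 * i + 1]),
        )
        phantoms.append(generate_phantom(params))
        row = dataclasses.asdict(params)
        row["center"] = f"{params.center[0]:.2f};{params.center[1]:.2f}"
        row["class_intensities"] = ";".join(
            f"{v:g}" for v in params.class_intensities)
        row["index"] = i
        manifest.append(row)
    return phantoms, manifest
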