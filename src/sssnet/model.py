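"""SSS-Net: a shallow encoder-decoder semantic segmentation network.

The encoder stacks four sprint convolutional blocks (SCBs) interleaved with
three stride-2 convolutions, so the bottleneck sits at 1/8 of the input
resolution.  An SCB feeds a point-wise convolution into three parallel
branches — a pair of asymmetric kernels (1x3 and 3x1), and a plain 3x3 —
while a depth-wise separable branch taps the block input directly; the
branch outputs are aggregated by two-stage concatenation and fused by a 1x1
bottleneck.  The decoder is deliberately light: four 3x3 bridge convolutions
at the bottleneck followed by three 4x4/stride-2 transposed convolutions,
each merged with the encoder feature of matching resolution through either
element-wise addition (``residual`` variant) or depth-wise concatenation
(``dense`` variant).  Both merge styles end in a 1x1 fusion convolution
sized so the two variants have identical trainable-parameter totals.  A 3x3
head convolution emits one score channel per class; per-pixel class
probabilities come from a softmax over channels.

Convolutions followed by batch norm carry no bias (it would be absorbed by
the shift); the standalone head convolution does.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import yaml

from . import nn
from .nn import (BatchNorm2d, Conv2d, ConvTranspose2d, DepthwiseConv2d,
                 Parameter, ReLU, softmax)

CLASS_NAMES = ("background", "ZP", "TE", "BL", "ICM")
NUM_CLASSES = len(CLASS_NAMES)


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass
class SCBSpec:
    """Widths of one sprint convolutional block.

    ``in_channels`` is the channel count of the block input; ``pointwise_width``
    that of the leading 1x1 convolution; ``asym_width`` that of each asymmetric
    branch (1x3 and 3x1); ``conv3_width`` that of the 3x3 branch; ``sep_width``
    that of the depth-wise separable branch; ``out_width`` that of the final
    1x1 bottleneck.
    """

    in_channels: int
    pointwise_width: int
    asym_width: int
    conv3_width: int
    sep_width: int
    out_width: int

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"SCBSpec.{f.name} must be a positive "
                                 f"integer, got {v!r}")

    @property
    def da_channels(self) -> int:
        """Channels of the first-stage concatenation (two asym branches)."""
        return 2 * self.asym_width

    @property
    def db_channels(self) -> int:
        """Channels of the second-stage concatenation."""
        return self.da_channels + self.conv3_width + self.sep_width


@dataclass
class NetworkSpec:
    """Full architecture description; serialisable to/from YAML."""

    variant: str = "dense"
    in_channels: int = 3
    num_classes: int = NUM_CLASSES
    scb_specs: List[SCBSpec] = field(default_factory=list)
    downsample_positions: Tuple[int, int, int] = (0, 1, 2)
    bridge_widths: Tuple[int, int, int, int] = (240, 240, 240, 240)
    upsample_widths: Tuple[int, int, int] = (112, 80, 64)
    input_divisor: int = 8

    def __post_init__(self):
        if self.variant not in ("residual", "dense"):
            raise ValueError(
                f"variant must be 'residual' or 'dense', got {self.variant!r}")
        if len(self.scb_specs) != 4:
            raise ValueError("exactly 4 SCB specs are required")
        if len(self.bridge_widths) != 4:
            raise ValueError("exactly 4 bridge widths are required")
        if len(self.upsample_widths) != 3:
            raise ValueError("exactly 3 upsample widths are required")
        if tuple(self.downsample_positions) != (0, 1, 2):
            raise ValueError("the 3 strided convolutions sit after "
                             "SCB-1, SCB-2 and SCB-3 (positions 0, 1, 2)")
        if self.input_divisor != 2 ** len(self.downsample_positions):
            raise ValueError("input_divisor must be 8 (three halvings)")
        if self.scb_specs[0].in_channels != self.in_channels:
            raise ValueError("SCB-1 in_channels must equal image channels")

    # -- YAML round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["downsample_positions"] = list(self.downsample_positions)
        d["bridge_widths"] = list(self.bridge_widths)
        d["upsample_widths"] = list(self.upsample_widths)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        d["scb_specs"] = [SCBSpec(**s) for s in d["scb_specs"]]
        d["downsample_positions"] = tuple(d["downsample_positions"])
        d["bridge_widths"] = tuple(d["bridge_widths"])
        d["upsample_widths"] = tuple(d["upsample_widths"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkSpec":
        return cls.from_dict(yaml.safe_load(text))


def _scb_schedule(widths, in_channels):
    # SCB-1 consumes the image; each strided convolution projects to the
    # next stage width, so later SCBs see their own stage width as input.
    specs = []
    for k, w in enumerate(widths):
        specs.append(SCBSpec(in_channels=in_channels if k == 0 else w,
                             pointwise_width=w,
                             asym_width=w // 2, conv3_width=w // 2,
                             sep_width=w // 2, out_width=w))
    return specs


def reference_spec(variant: str = "dense") -> NetworkSpec:
    """The reference width schedule (4.04 M trainable parameters).

    Stage widths grow 64 -> 80 -> 112 -> 240 over SCB-1..SCB-4; the bridge
    runs at 240 channels and the decoder mirrors the encoder widths.
    """
    return NetworkSpec(
        variant=variant,
        scb_specs=_scb_schedule((64, 80, 112, 240), 3),
        bridge_widths=(240, 240, 240, 240),
        upsample_widths=(112, 80, 64),
    )


def small_spec(variant: str = "dense") -> NetworkSpec:
    """A slim schedule for desk-scale experiments and tests (~100 k params).

    The full-resolution decoder stage keeps 16 channels rather than
    mirroring the 8-channel first encoder stage: with only 8 channels the
    residual merge starves the TE/ICM distinction at desk scale.
    """
    return NetworkSpec(
        variant=variant,
        scb_specs=_scb_schedule((8, 16, 24, 32), 3),
        bridge_widths=(32, 32, 32, 32),
        upsample_widths=(24, 16, 16),
    )


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------

class _Block:
    """Composite of layers; exposes named parameters and buffers."""

    name = "block"

    def _sublayers(self):
        for attr, val in vars(self).items():
            if isinstance(val, nn.Layer):
                yield attr, val
            elif isinstance(val, _Block):
                yield attr, val

    def named_parameters(self, prefix=""):
        for attr, sub in self._sublayers():
            sub_prefix = f"{prefix}{attr}."
            if isinstance(sub, _Block):
                yield from sub.named_parameters(sub_prefix)
            else:
                for pname, p in sub.parameters():
                    yield sub_prefix + pname, p

    def named_buffers(self, prefix=""):
        for attr, sub in self._sublayers():
            sub_prefix = f"{prefix}{attr}."
            if isinstance(sub, _Block):
                yield from sub.named_buffers(sub_prefix)
            else:
                for bname, b in sub.buffers():
                    yield sub_prefix + bname, b


class ConvBNReLU(_Block):
    def __init__(self, cin, cout, kh, kw, stride=1, rng=None):
        self.conv = Conv2d(cin, cout, kh, kw, stride=stride, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.relu = ReLU()

    def forward(self, x, training=True):
        return self.relu.forward(
            self.bn.forward(self.conv.forward(x, training), training),
            training)

    def backward(self, gy):
        return self.conv.backward(self.bn.backward(self.relu.backward(gy)))


class SCB(_Block):
    """Sprint convolutional block.

    Given input ``I``: ``G = Conv1x1(I)``; ``KA = Conv1x3(G)``;
    ``KB = Conv3x1(G)``; ``L = Conv3x3(G)``; ``F = ConvSep(I)``.
    First-stage aggregation ``DA = concat(KA, KB)`` -> BN -> ReLU -> ``DA'``;
    ``L`` and ``F`` each pass BN+ReLU; second stage
    ``DB = concat(DA', L', F')`` -> 1x1 bottleneck -> BN -> ReLU -> ``DB'``.
    All branches preserve spatial size.
    """

    def __init__(self, spec: SCBSpec, rng=None, consumes_image=False):
        self.spec = spec
        self._consumes_image = consumes_image   # skip input grads if so
        s = spec
        self.conv_pw = Conv2d(s.in_channels, s.pointwise_width, 1, 1, rng=rng,
                              needs_input_grad=not consumes_image)
        self.conv_1x3 = Conv2d(s.pointwise_width, s.asym_width, 1, 3, rng=rng)
        self.conv_3x1 = Conv2d(s.pointwise_width, s.asym_width, 3, 1, rng=rng)
        self.conv_3x3 = Conv2d(s.pointwise_width, s.conv3_width, 3, 3,
                               rng=rng)
        self.sep_dw = DepthwiseConv2d(s.in_channels, 3, rng=rng,
                                      needs_input_grad=not consumes_image)
        self.sep_pw = Conv2d(s.in_channels, s.sep_width, 1, 1, rng=rng)
        self.bn_da = BatchNorm2d(s.da_channels)
        self.relu_da = ReLU()
        self.bn_l = BatchNorm2d(s.conv3_width)
        self.relu_l = ReLU()
        self.bn_f = BatchNorm2d(s.sep_width)
        self.relu_f = ReLU()
        self.bottleneck = Conv2d(s.db_channels, s.out_width, 1, 1, rng=rng)
        self.bn_out = BatchNorm2d(s.out_width)
        self.relu_out = ReLU()

    def forward(self, x, training=True):
        s = self.spec
        if x.shape[-1] != s.in_channels:
            raise ValueError(f"SCB expects {s.in_channels} channels, "
                             f"got {x.shape[-1]}")
        g = self.conv_pw.forward(x, training)
        ka = self.conv_1x3.forward(g, training)
        kb = self.conv_3x1.forward(g, training)
        da = np.concatenate([ka, kb], axis=-1)
        da_p = self.relu_da.forward(self.bn_da.forward(da, training), training)
        l_p = self.relu_l.forward(
            self.bn_l.forward(self.conv_3x3.forward(g, training), training),
            training)
        f = self.sep_pw.forward(self.sep_dw.forward(x, training), training)
        f_p = self.relu_f.forward(self.bn_f.forward(f, training), training)
        db = np.concatenate([da_p, l_p, f_p], axis=-1)
        out = self.relu_out.forward(
            self.bn_out.forward(self.bottleneck.forward(db, training),
                                training), training)
        return out

    def backward(self, gy):
        s = self.spec
        g_db = self.bottleneck.backward(
            self.bn_out.backward(self.relu_out.backward(gy)))
        g_da = g_db[..., :s.da_channels]
        g_l = g_db[..., s.da_channels:s.da_channels + s.conv3_width]
        g_f = g_db[..., s.da_channels + s.conv3_width:]
        g_da = self.bn_da.backward(self.relu_da.backward(g_da))
        g_ka = g_da[..., :s.asym_width]
        g_kb = g_da[..., s.asym_width:]
        g_g = self.conv_1x3.backward(np.ascontiguousarray(g_ka))
        g_g += self.conv_3x1.backward(np.ascontiguousarray(g_kb))
        g_g += self.conv_3x3.backward(
            self.bn_l.backward(self.relu_l.backward(np.ascontiguousarray(
                g_l))))
        g_x = self.conv_pw.backward(g_g)
        g_f = self.sep_pw.backward(
            self.bn_f.backward(self.relu_f.backward(
                np.ascontiguousarray(g_f))))
        g_dw = self.sep_dw.backward(g_f)
        if self._consumes_image:
            return None
        g_x += g_dw
        return g_x


class DecoderStage(_Block):
    """Upsample by 2 and merge with the encoder skip feature.

    residual: skip -> 1x1 projection, element-wise added to the upsampled
    feature, then a 1x1 fusion convolution (BN+ReLU).
    dense: skip concatenated with the upsampled feature, then a 1x1
    projection back to the stage width (BN+ReLU).
    The two wirings have identical parameter totals.
    """

    def __init__(self, variant, cin, skip_channels, out_width, rng=None):
        self.variant = variant
        self.out_width = out_width
        self.tconv = ConvTranspose2d(cin, out_width, rng=rng)
        self.bn_up = BatchNorm2d(out_width)
        self.relu_up = ReLU()
        if variant == "residual":
            self.proj = Conv2d(skip_channels, out_width, 1, 1, rng=rng)
            self.fuse = Conv2d(out_width, out_width, 1, 1, rng=rng)
        else:
            self.fuse = Conv2d(skip_channels + out_width, out_width, 1, 1,
                               rng=rng)
        self.bn_out = BatchNorm2d(out_width)
        self.relu_out = ReLU()
        self._skip_channels = skip_channels

    def forward(self, x, skip, training=True):
        up = self.relu_up.forward(
            self.bn_up.forward(self.tconv.forward(x, training), training),
            training)
        if up.shape[1:3] != skip.shape[1:3]:
            raise ValueError("skip/decoder resolution mismatch: "
                             f"{skip.shape[1:3]} vs {up.shape[1:3]}")
        if self.variant == "residual":
            merged = up + self.proj.forward(skip, training)
        else:
            merged = np.concatenate([skip, up], axis=-1)
        return self.relu_out.forward(
            self.bn_out.forward(self.fuse.forward(merged, training),
                                training), training)

    def backward(self, gy):
        g_m = self.fuse.backward(
            self.bn_out.backward(self.relu_out.backward(gy)))
        if self.variant == "residual":
            g_skip = self.proj.backward(g_m)
            g_up = g_m
        else:
            g_skip = np.ascontiguousarray(g_m[..., :self._skip_channels])
            g_up = np.ascontiguousarray(g_m[..., self._skip_channels:])
        g_x = self.tconv.backward(
            self.bn_up.backward(self.relu_up.backward(g_up)))
        return g_x, g_skip


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class SSSNet(_Block):
    """The assembled network.  ``forward`` maps (N, H, W, in_channels) score
    maps of shape (N, H, W, num_classes); H and W must be divisible by 8.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        s = spec
        self.scb1 = SCB(s.scb_specs[0], rng, consumes_image=True)
        self.down1 = ConvBNReLU(s.scb_specs[0].out_width,
                                s.scb_specs[1].in_channels, 3, 3, stride=2,
                                rng=rng)
        self.scb2 = SCB(s.scb_specs[1], rng)
        self.down2 = ConvBNReLU(s.scb_specs[1].out_width,
                                s.scb_specs[2].in_channels, 3, 3, stride=2,
                                rng=rng)
        self.scb3 = SCB(s.scb_specs[2], rng)
        self.down3 = ConvBNReLU(s.scb_specs[2].out_width,
                                s.scb_specs[3].in_channels, 3, 3, stride=2,
                                rng=rng)
        self.scb4 = SCB(s.scb_specs[3], rng)
        prev = s.scb_specs[3].out_width
        bridges = []
        for k, b in enumerate(s.bridge_widths):
            bridges.append(ConvBNReLU(prev, b, 3, 3, rng=rng))
            prev = b
        self.bridge1, self.bridge2, self.bridge3, self.bridge4 = bridges
        skips = [s.scb_specs[2].out_width, s.scb_specs[1].out_width,
                 s.scb_specs[0].out_width]
        stages = []
        for u, sk in zip(s.upsample_widths, skips):
            stages.append(DecoderStage(s.variant, prev, sk, u, rng))
            prev = u
        self.up1, self.up2, self.up3 = stages
        self.head = Conv2d(prev, s.num_classes, 3, 3, bias=True, rng=rng)

    # -- forward / backward --------------------------------------------------
    def _check_input(self, x):
        if x.ndim != 4:
            raise ValueError("expected a 4-D NHWC batch")
        n, h, w, c = x.shape
        d = self.spec.input_divisor
        if h % d or w % d:
            raise ValueError(
                f"input spatial dims must be divisible by {d}, got "
                f"{h}x{w}")
        if c != self.spec.in_channels:
            raise ValueError(f"expected {self.spec.in_channels} channels, "
                             f"got {c}")

    def forward(self, x, training=True):
        self._check_input(x)
        x = np.ascontiguousarray(x, dtype=nn.DTYPE)
        e1 = self.scb1.forward(x, training)                 # H
        e2 = self.scb2.forward(self.down1.forward(e1, training), training)
        e3 = self.scb3.forward(self.down2.forward(e2, training), training)
        e4 = self.scb4.forward(self.down3.forward(e3, training), training)
        b = self.bridge1.forward(e4, training)
        b = self.bridge2.forward(b, training)
        b = self.bridge3.forward(b, training)
        b = self.bridge4.forward(b, training)
        d = self.up1.forward(b, e3, training)
        d = self.up2.forward(d, e2, training)
        d = self.up3.forward(d, e1, training)
        return self.head.forward(d, training)

    def backward(self, gscores):
        g = self.head.backward(gscores)
        g, g_e1 = self.up3.backward(g)
        g, g_e2 = self.up2.backward(g)
        g, g_e3 = self.up1.backward(g)
        g = self.bridge4.backward(g)
        g = self.bridge3.backward(g)
        g = self.bridge2.backward(g)
        g = self.bridge1.backward(g)
        g = self.scb4.backward(g)
        g = self.down3.backward(g)
        g += g_e3
        g = self.scb3.backward(g)
        g = self.down2.backward(g)
        g += g_e2
        g = self.scb2.backward(g)
        g = self.down1.backward(g)
        g += g_e1
        return self.scb1.backward(g)

    def predict_probs(self, x):
        """Inference-mode class probabilities, softmax over channels."""
        return softmax(self.forward(x, training=False), axis=-1)

    # -- state ---------------------------------------------------------------
    def state_dict(self):
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({name: b for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            p.data[...] = state[name]
        for name, b in self.named_buffers():
            b[...] = state[name]


def build_scb(spec: SCBSpec, seed: int = 0) -> SCB:
    """Instantiate a single sprint convolutional block."""
    return SCB(spec, np.random.default_rng(seed))


def build_network(spec: NetworkSpec, seed: int = 0) -> SSSNet:
    """Instantiate SSS-Net from a :class:`NetworkSpec`."""
    return SSSNet(spec, seed=seed)


# ---------------------------------------------------------------------------
# Parameter / FLOP accounting
# ---------------------------------------------------------------------------

@dataclass
class ParameterReport:
    total_trainable: int
    per_layer: List[Tuple[str, int]]
    flops_per_forward: Optional[int] = None

    @property
    def total_millions(self) -> float:
        return round(self.total_trainable / 1e6, 2)


def count_trainable_parameters(model, input_hw: Optional[Tuple[int, int]]
                               = None) -> ParameterReport:
    """Exact count of learnable weights, biases and BN scale/shift.

    ``input_hw`` optionally adds an analytic FLOP count for one forward pass
    at that resolution (one multiply-add counted as 2 operations).
    """
    per_layer = [(name, p.size) for name, p in model.named_parameters()]
    total = sum(n for _, n in per_layer)
    flops = None
    if input_hw is not None:
        flops = _count_flops(model, input_hw)
    return ParameterReport(total_trainable=total, per_layer=per_layer,
                           flops_per_forward=flops)


def _count_flops(model: SSSNet, input_hw: Tuple[int, int]) -> int:
    """Multiply-adds (x2) of all convolutions for one image.

    Batch-norm, ReLU and element-wise merges are negligible and are not
    counted.
    """
    h, w = input_hw
    d = model.spec.input_divisor
    if h % d or w % d:
        raise ValueError(f"input spatial dims must be divisible by {d}")
    flops = 0

    def conv_flops(layer, ho, wo):
        macs = layer.kh * layer.kw * layer.cin * layer.cout * ho * wo
        if layer.bias is not None:
            macs += layer.cout * ho * wo
        return 2 * macs

    def scb_flops(scb, hh, ww):
        n = conv_flops(scb.conv_pw, hh, ww)
        n += conv_flops(scb.conv_1x3, hh, ww)
        n += conv_flops(scb.conv_3x1, hh, ww)
        n += conv_flops(scb.conv_3x3, hh, ww)
        n += 2 * (scb.sep_dw.k ** 2) * scb.sep_dw.channels * hh * ww
        n += conv_flops(scb.sep_pw, hh, ww)
        n += conv_flops(scb.bottleneck, hh, ww)
        return n

    res = [(h, w), (h // 2, w // 2), (h // 4, w // 4), (h // 8, w // 8)]
    for i, scb in enumerate([model.scb1, model.scb2, model.scb3, model.scb4]):
        flops += scb_flops(scb, *res[i])
    for i, down in enumerate([model.down1, model.down2, model.down3]):
        flops += conv_flops(down.conv, *res[i + 1])
    for br in [model.bridge1, model.bridge2, model.bridge3, model.bridge4]:
        flops += conv_flops(br.conv, *res[3])
    up_res = [res[2], res[1], res[0]]
    for i, up in enumerate([model.up1, model.up2, model.up3]):
        ho, wo = up_res[i]
        flops += 2 * up.tconv.k ** 2 * up.tconv.cin * up.tconv.cout \
            * (ho // 2) * (wo // 2)
        if up.variant == "residual":
            flops += conv_flops(up.proj, ho, wo)
        flops += conv_flops(up.fuse, ho, wo)
    flops += conv_flops(model.head, h, w)
    return flops


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: SSSNet, path) -> None:
    """Write weights plus the embedded NetworkSpec to an .npz container."""
    state = model.state_dict()
    np.savez(path, __spec_yaml__=np.frombuffer(
        model.spec.to_yaml().encode("utf-8"), dtype=np.uint8), **state)


def load_checkpoint(path) -> SSSNet:
    """Rebuild a model from a self-describing .npz checkpoint."""
    with np.load(path) as data:
        spec = NetworkSpec.from_yaml(
            bytes(data["__spec_yaml__"]).decode("utf-8"))
        model = build_network(spec)
        state = {k: data[k] for k in data.files if k != "__spec_yaml__"}
    model.load_state_dict(state)
    return model
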