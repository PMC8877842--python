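"""Minimal NumPy neural-network engine used by the segmentation model.

All tensors are float32 in NHWC layout (batch, height, width, channels).
Convolutions are lowered to a single BLAS matmul per layer via im2col (one
slice copy per kernel offset builds the column matrix, which is cached for
the backward pass); stride-1 input gradients are computed as a correlation
with the transposed kernel (im2col of the output gradient) rather than a
scatter, and transposed convolutions use the adjoint col2im scatter.
Batch-norm statistics are computed in one pass with ``einsum``.  Large
intermediates are written into per-layer scratch buffers that persist
across iterations, which matters on a single core where page faults from
fresh allocations would otherwise dominate.

Every layer implements ``forward``/``backward`` and exposes its learnable
tensors as :class:`Parameter` objects; gradients are written by
``backward`` and consumed by :class:`Adam`.  Weight initialisation is
He-uniform for convolution kernels and (1, 0) for batch-norm scale/shift;
a :class:`numpy.random.Generator` is threaded through construction so
models are reproducible bit-for-bit under a seed.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from ._kernels import HAVE_NUMBA

DTYPE = np.float32
BN_EPS = 1e-5

# direct numba kernels beat the im2col+GEMM route only for narrow layers;
# wide layers stay on BLAS
_NUMBA_CHANNEL_LIMIT = 1024


class Parameter:
    """A learnable tensor together with its gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


def he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Layer:
    """Base class: subclasses define forward/backward and parameters()."""

    def parameters(self):
        """Yield (name, Parameter) pairs."""
        return
        yield  # pragma: no cover

    def buffers(self):
        """Yield (name, ndarray) pairs for non-learnable state."""
        return
        yield  # pragma: no cover

    # scratch-buffer pool, reused across iterations
    def _buf(self, key, shape):
        pool = self.__dict__.setdefault("_scratch", {})
        arr = pool.get(key)
        if arr is None or arr.shape != tuple(shape):
            arr = np.zeros(shape, dtype=DTYPE)
            pool[key] = arr
        return arr


def _im2col(x, kh, kw, stride, out, ho, wo):
    """Gather kh*kw shifted views of ``x`` into ``out`` (n, ho, wo, kk, c)."""
    k = 0
    for i in range(kh):
        for j in range(kw):
            out[:, :, :, k, :] = x[:, i:i + (ho - 1) * stride + 1:stride,
                                   j:j + (wo - 1) * stride + 1:stride, :]
            k += 1
    return out


class Conv2d(Layer):
    """2-D convolution, NHWC, arbitrary (kh, kw), symmetric zero padding.

    ``pad`` defaults to 'same' padding for stride 1 (and exact halving for
    odd kernels at stride 2 on even inputs).  Weights are stored as
    (kh*kw*cin, cout) so the forward pass is one GEMM on the im2col matrix.
    ``needs_input_grad=False`` skips the input-gradient computation for
    layers that consume the raw image.
    """

    def __init__(self, cin, cout, kh, kw, stride=1, bias=False, pad=None,
                 rng=None, needs_input_grad=True):
        if cin <= 0 or cout <= 0:
            raise ValueError("channel counts must be positive")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cin, self.cout, self.kh, self.kw = cin, cout, kh, kw
        self.stride = stride
        self.pad = ((kh - 1) // 2, (kw - 1) // 2) if pad is None else pad
        self.needs_input_grad = needs_input_grad
        fan_in = kh * kw * cin
        self.weight = Parameter(he_uniform(rng, (kh * kw * cin, cout),
                                           fan_in))
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self._cache = None
        self._wt_flip = None   # (kh*kw*cout, cin) for correlation backward

    def parameters(self):
        yield "weight", self.weight
        if self.bias is not None:
            yield "bias", self.bias

    def _pad_input(self, x):
        ph, pw = self.pad
        if not (ph or pw):
            return x
        n, h, w, c = x.shape
        xp = self._buf("xp", (n, h + 2 * ph, w + 2 * pw, c))
        xp[:, ph:ph + h, pw:pw + w, :] = x
        return xp

    def _use_numba(self):
        return (HAVE_NUMBA and self.stride == 1 and self.kh * self.kw > 1
                and self.cin * self.cout <= _NUMBA_CHANNEL_LIMIT)

    def forward(self, x, training=True):
        n, h, w, cin = x.shape
        if cin != self.cin:
            raise ValueError(
                f"expected {self.cin} input channels, got {cin}")
        ph, pw = self.pad
        s = self.stride
        kk = self.kh * self.kw
        xp = self._pad_input(x)
        ho = (h + 2 * ph - self.kh) // s + 1
        wo = (w + 2 * pw - self.kw) // s + 1
        if self._use_numba():
            out = self._buf("out", (n, ho, wo, self.cout))
            _kernels.conv_fwd_kernel(self.kh, self.kw, self.cin, self.cout)(
                np.ascontiguousarray(xp), self.weight.data, out)
            if self.bias is not None:
                out += self.bias.data
            self._cache = (xp, x.shape, (ho, wo))
            return out
        if kk == 1 and s == 1:
            cols = xp.reshape(-1, cin)
        else:
            cols = _im2col(xp, self.kh, self.kw, s,
                           self._buf("cols", (n, ho, wo, kk, cin)), ho, wo
                           ).reshape(-1, kk * cin)
        out = self._buf("out", (n * ho * wo, self.cout))
        np.matmul(cols, self.weight.data, out=out)
        if self.bias is not None:
            out += self.bias.data
        self._cache = (cols, x.shape, (ho, wo))
        return out.reshape(n, ho, wo, self.cout)

    def _flipped_weight(self):
        """(kh*kw*cout, cin) kernel for the correlation form of dgrad."""
        wt = self.weight.data.reshape(self.kh, self.kw, self.cin,
                                      self.cout)[::-1, ::-1]
        return np.ascontiguousarray(wt.transpose(0, 1, 3, 2)).reshape(
            self.kh * self.kw * self.cout, self.cin)

    def backward(self, gy):
        cached, xshape, (ho, wo) = self._cache
        n, h, w, _ = xshape
        ph, pw = self.pad
        s = self.stride
        kk = self.kh * self.kw
        g2 = gy.reshape(-1, self.cout)
        if self._use_numba():
            xp = cached
            gyc = np.ascontiguousarray(gy)
            _kernels.conv_wgrad_kernel(self.kh, self.kw, self.cin,
                                       self.cout)(
                np.ascontiguousarray(xp), gyc, self.weight.grad)
            if self.bias is not None:
                self.bias.grad[...] = g2.sum(axis=0)
            if not self.needs_input_grad:
                return None
            gyp = self._buf("gyp", (n, ho + self.kh - 1, wo + self.kw - 1,
                                    self.cout))
            gyp[:, self.kh - 1 - ph:self.kh - 1 - ph + ho,
                self.kw - 1 - pw:self.kw - 1 - pw + wo, :] = gy
            dx = self._buf("dx", xshape)
            _kernels.conv_fwd_kernel(self.kh, self.kw, self.cout, self.cin)(
                gyp, self._flipped_weight(), dx)
            return dx
        cols = cached
        np.matmul(cols.T, g2, out=self.weight.grad)
        if self.bias is not None:
            self.bias.grad[...] = g2.sum(axis=0)
        if not self.needs_input_grad:
            return None
        if kk == 1 and s == 1:
            dx = self._buf("dx2", (n * h * w, self.cin))
            np.matmul(g2, self.weight.data.T, out=dx)
            return dx.reshape(xshape)
        if s == 1:
            # correlation with the flipped kernel: one im2col of gy
            gyp = self._buf("gyp", (n, ho + self.kh - 1, wo + self.kw - 1,
                                    self.cout))
            gyp[:, self.kh - 1 - ph:self.kh - 1 - ph + ho,
                self.kw - 1 - pw:self.kw - 1 - pw + wo, :] = gy
            gcols = _im2col(gyp, self.kh, self.kw, 1,
                            self._buf("gcols", (n, h, w, kk, self.cout)),
                            h, w).reshape(-1, kk * self.cout)
            dx = self._buf("dx2", (n * h * w, self.cin))
            np.matmul(gcols, self._flipped_weight(), out=dx)
            return dx.reshape(xshape)
        # strided: scatter per-offset contributions (col2im)
        dcols = (g2 @ self.weight.data.T).reshape(n, ho, wo, kk, self.cin)
        dxp = self._buf("dxp", (n, h + 2 * ph, w + 2 * pw, self.cin))
        dxp[...] = 0
        k = 0
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, i:i + (ho - 1) * s + 1:s,
                    j:j + (wo - 1) * s + 1:s, :] += dcols[:, :, :, k, :]
                k += 1
        if ph or pw:
            return np.ascontiguousarray(dxp[:, ph:ph + h, pw:pw + w, :])
        return dxp.copy()

    # convenience view for hand counting / inspection
    @property
    def kernel(self) -> np.ndarray:
        return self.weight.data.reshape(self.kh, self.kw, self.cin,
                                        self.cout)


class DepthwiseConv2d(Layer):
    """Per-channel (depth-wise) k x k convolution, stride 1, same padding."""

    def __init__(self, channels, k=3, rng=None, needs_input_grad=True):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels, self.k = channels, k
        self.pad = (k - 1) // 2
        self.needs_input_grad = needs_input_grad
        self.weight = Parameter(he_uniform(rng, (k, k, channels), k * k))
        self._cache = None

    def parameters(self):
        yield "weight", self.weight

    def forward(self, x, training=True):
        n, h, w, c = x.shape
        if c != self.channels:
            raise ValueError(
                f"expected {self.channels} input channels, got {c}")
        p = self.pad
        xp = self._buf("xp", (n, h + 2 * p, w + 2 * p, c))
        xp[:, p:p + h, p:p + w, :] = x
        out = self._buf("out", x.shape)
        if HAVE_NUMBA:
            _kernels.depthwise_fwd_kernel(self.k, c)(xp, self.weight.data,
                                                     out)
        else:
            out[...] = 0
            for i in range(self.k):
                for j in range(self.k):
                    out += xp[:, i:i + h, j:j + w, :] * self.weight.data[i, j]
        self._cache = (xp, x.shape)
        return out

    def backward(self, gy):
        xp, (n, h, w, c) = self._cache
        p = self.pad
        dw = self.weight.grad
        if HAVE_NUMBA:
            dxp = self._buf("dxp", xp.shape)
            _kernels.depthwise_bwd_kernel(self.k, c, self.needs_input_grad)(
                xp, np.ascontiguousarray(gy), self.weight.data, dw, dxp)
            if not self.needs_input_grad:
                return None
            return np.ascontiguousarray(dxp[:, p:p + h, p:p + w, :])
        for i in range(self.k):
            for j in range(self.k):
                xs = xp[:, i:i + h, j:j + w, :]
                dw[i, j] = np.einsum("nhwc,nhwc->c", xs, gy, optimize=True)
        if not self.needs_input_grad:
            return None
        dxp = self._buf("dxp", xp.shape)
        dxp[...] = 0
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i:i + h, j:j + w, :] += gy * self.weight.data[i, j]
        return np.ascontiguousarray(dxp[:, p:p + h, p:p + w, :])


class ConvTranspose2d(Layer):
    """Transposed convolution, kernel 4, stride 2, padding 1: doubles H, W.

    Forward is one GEMM producing per-offset contributions which are
    scattered (col2im); backward gathers them back.
    """

    def __init__(self, cin, cout, k=4, stride=2, pad=1, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.padv = stride, pad
        # fan-in of the equivalent forward conv path
        fan_in = max(1, cin * k * k // (stride * stride))
        self.weight = Parameter(he_uniform(rng, (cin, k * k * cout), fan_in))
        self._cache = None

    def parameters(self):
        yield "weight", self.weight

    def out_hw(self, h, w):
        s, k, p = self.stride, self.k, self.padv
        return (h - 1) * s - 2 * p + k, (w - 1) * s - 2 * p + k

    def forward(self, x, training=True):
        n, h, w, cin = x.shape
        if cin != self.cin:
            raise ValueError(
                f"expected {self.cin} input channels, got {cin}")
        s, k, p = self.stride, self.k, self.padv
        hf, wf = (h - 1) * s + k, (w - 1) * s + k
        xc = np.ascontiguousarray(x)
        x2 = xc.reshape(-1, cin)
        contrib = self._buf("contrib", (n * h * w, k * k * self.cout))
        np.matmul(x2, self.weight.data, out=contrib)
        contrib = contrib.reshape(n, h, w, k * k, self.cout)
        out = self._buf("out", (n, hf, wf, self.cout))
        out[...] = 0
        idx = 0
        for i in range(k):
            for j in range(k):
                out[:, i:i + (h - 1) * s + 1:s,
                    j:j + (w - 1) * s + 1:s, :] += contrib[:, :, :, idx, :]
                idx += 1
        self._cache = (xc, (n, h, w), (hf, wf))
        return np.ascontiguousarray(out[:, p:hf - p, p:wf - p, :])

    def backward(self, gy):
        xc, (n, h, w), (hf, wf) = self._cache
        s, k, p = self.stride, self.k, self.padv
        gyp = self._buf("gyp", (n, hf, wf, self.cout))
        gyp[:, p:hf - p, p:wf - p, :] = gy
        gcols = self._buf("gcols", (n, h, w, k * k, self.cout))
        idx = 0
        for i in range(k):
            for j in range(k):
                gcols[:, :, :, idx, :] = gyp[:, i:i + (h - 1) * s + 1:s,
                                             j:j + (w - 1) * s + 1:s, :]
                idx += 1
        g2 = gcols.reshape(-1, k * k * self.cout)
        x2 = xc.reshape(-1, self.cin)
        np.matmul(x2.T, g2, out=self.weight.grad)
        dx = self._buf("dx2", (n * h * w, self.cin))
        np.matmul(g2, self.weight.data.T, out=dx)
        return dx.reshape(n, h, w, self.cin)

    @property
    def kernel(self) -> np.ndarray:
        return self.weight.data.reshape(self.cin, self.k, self.k, self.cout)


class BatchNorm2d(Layer):
    """Batch normalisation over (N, H, W) with learnable scale/shift."""

    def __init__(self, channels, eps=BN_EPS, momentum=0.1):
        self.channels = channels
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache = None

    def parameters(self):
        yield "gamma", self.gamma
        yield "beta", self.beta

    def buffers(self):
        yield "running_mean", self.running_mean
        yield "running_var", self.running_var

    def _buf64(self, key, n):
        pool = self.__dict__.setdefault("_scratch64", {})
        arr = pool.get(key)
        if arr is None or arr.shape != (n,):
            arr = np.zeros(n, dtype=np.float64)
            pool[key] = arr
        return arr

    def forward(self, x, training=True):
        m = float(np.prod(x.shape[:3]))
        c = self.channels
        x2 = np.ascontiguousarray(x).reshape(-1, c)
        if training:
            if HAVE_NUMBA:
                s1 = self._buf64("s1", c)
                s2 = self._buf64("s2", c)
                _kernels.bn_stats_kernel(c)(x2, s1, s2)
            else:
                s1 = np.einsum("nc->c", x2, optimize=True)
                s2 = np.einsum("nc,nc->c", x2, x2, optimize=True)
            mean = s1 / m
            var = np.maximum(s2 / m - mean * mean, 0.0)
            mom = self.momentum
            self.running_mean[...] = (1 - mom) * self.running_mean \
                + mom * mean
            self.running_var[...] = (1 - mom) * self.running_var + mom * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        meanf = np.asarray(mean, dtype=DTYPE)
        xhat = self._buf("xhat", x.shape)
        out = self._buf("out", x.shape)
        if HAVE_NUMBA:
            _kernels.bn_norm_kernel(c)(
                x2, meanf, invstd, self.gamma.data, self.beta.data,
                xhat.reshape(-1, c), out.reshape(-1, c))
        else:
            np.subtract(x, meanf, out=xhat)
            xhat *= invstd
            np.multiply(xhat, self.gamma.data, out=out)
            out += self.beta.data
        self._cache = (xhat, invstd)
        return out

    def backward(self, gy):
        xhat, invstd = self._cache
        c = self.channels
        m = float(np.prod(gy.shape[:3]))
        g2 = np.ascontiguousarray(gy).reshape(-1, c)
        xh2 = xhat.reshape(-1, c)
        gx = self._buf("gx", gy.shape)
        if HAVE_NUMBA:
            sg = self._buf64("sg", c)
            sgx = self._buf64("sgx", c)
            _kernels.bn_bwd_kernel(c)(g2, xh2, self.gamma.data, invstd,
                                      sg, sgx, gx.reshape(-1, c))
            self.gamma.grad[...] = sgx
            self.beta.grad[...] = sg
            return gx
        sg = np.einsum("nc->c", g2, optimize=True)
        sgx = np.einsum("nc,nc->c", g2, xh2, optimize=True)
        self.gamma.grad[...] = sgx
        self.beta.grad[...] = sg
        np.multiply(xhat, (sgx / m).astype(DTYPE), out=gx)
        gx += (sg / m).astype(DTYPE)
        np.subtract(gy, gx, out=gx)
        gx *= self.gamma.data * invstd
        return gx


class ReLU(Layer):
    """Rectifier; the backward mask is recomputed from the cached output."""

    def __init__(self):
        self._act = None

    def forward(self, x, training=True):
        out = self._buf("out", x.shape)
        if HAVE_NUMBA:
            _kernels.relu_kernels()[0](np.ascontiguousarray(x), out)
        else:
            np.maximum(x, 0, out=out)
        self._act = out
        return out

    def backward(self, gy):
        gx = self._buf("gx", gy.shape)
        if HAVE_NUMBA:
            _kernels.relu_kernels()[1](self._act, np.ascontiguousarray(gy),
                                       gx)
        else:
            np.multiply(gy, self._act > 0, out=gx)
        return gx


def softmax(scores: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax; rejects non-finite inputs."""
    if not np.all(np.isfinite(scores)):
        raise ValueError("softmax input contains non-finite values")
    z = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(z, out=z) if isinstance(z, np.ndarray) else np.exp(z)
    e /= e.sum(axis=axis, keepdims=True)
    return e


def softmax_backward(probs: np.ndarray, gprobs: np.ndarray,
                     axis: int = -1) -> np.ndarray:
    """Gradient of the loss w.r.t. pre-softmax scores, given dL/dprobs."""
    dot = (gprobs * probs).sum(axis=axis, keepdims=True)
    return probs * (gprobs - dot)


def global_grad_norm(params) -> float:
    total = 0.0
    for p in params:
        g = p.grad.ravel()
        total += float(g @ g)
    return float(np.sqrt(total))


def clip_global_norm(params, max_norm: float) -> float:
    """Scale all gradients so the global L2 norm is at most ``max_norm``.

    Returns the pre-clip norm.
    """
    norm = global_grad_norm(params)
    if max_norm is not None and norm > max_norm and norm > 0:
        scale = DTYPE(max_norm / norm)
        for p in params:
            p.grad *= scale
    return norm


class Adam:
    """Adam optimizer (Kingma & Ba) with configurable epsilon."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-6):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p.data -= (self.lr / bc1) * m / (
                np.sqrt(v / bc2) + self.eps)
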