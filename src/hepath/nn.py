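"""A compact convolutional encoder-decoder for per-pixel tissue classification.

Pure-numpy implementation (forward and hand-written backward passes) of a
U-Net-style network with three distinguishing features:

1. *Input-aware encoding*: each encoder stage concatenates an average-pooled
   copy of the raw input with its feature maps, so downsampled stages keep
   direct access to image evidence.
2. *Dense encoder-to-decoder connections*: every decoder stage receives
   resized feature maps from **all** encoder stages at the same or coarser
   resolution, not just its mirror stage.
3. *Multi-path decoding*: each decoder resolution contributes its own class
   logits; the per-path logits are upsampled to input resolution and summed
   before the softmax.

Spatial context inside a stage comes from an efficient spatial-pyramid
block: parallel 3x3 convolutions at dilation rates 1 and 2 whose outputs are
concatenated and added back residually.

The network is deliberately small (two downsampling stages, configurable
width) so that it trains on a single CPU; width/depth are knobs, the wiring
is fixed.  All arithmetic is float64 numpy, so training is bit-reproducible
for a fixed seed and input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# Primitive layers (stateless functions + parameter dicts)
# ---------------------------------------------------------------------------


def conv2d_forward(x, w, b, stride=1, dilation=1):
    """Same-padded KxK convolution. x: (N,C,H,W); w: (F,C,k,k); b: (F,)."""
    n, c, h, wd = x.shape
    f, _, k, _ = w.shape
    pad = dilation * (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - dilation * (k - 1) - 1) // stride + 1
    wo = (wd + 2 * pad - dilation * (k - 1) - 1) // stride + 1
    out = np.zeros((n, f, ho, wo))
    for di in range(k):
        for dj in range(k):
            xs = xp[
                :,
                :,
                di * dilation : di * dilation + stride * ho : stride,
                dj * dilation : dj * dilation + stride * wo : stride,
            ]
            out += np.tensordot(xs, w[:, :, di, dj], axes=([1], [1])).transpose(0, 3, 1, 2)
    out += b[None, :, None, None]
    return out, (x.shape, xp, pad)


def conv2d_backward(dout, w, cache, stride=1, dilation=1):
    x_shape, xp, pad = cache
    n, c, h, wd = x_shape
    f, _, k, _ = w.shape
    ho, wo = dout.shape[2], dout.shape[3]
    dw = np.zeros_like(w)
    db = dout.sum(axis=(0, 2, 3))
    dxp = np.zeros_like(xp)
    for di in range(k):
        for dj in range(k):
            sl_i = slice(di * dilation, di * dilation + stride * ho, stride)
            sl_j = slice(dj * dilation, dj * dilation + stride * wo, stride)
            xs = xp[:, :, sl_i, sl_j]
            # dW[f,c] = sum_{n,i,j} dout[n,f,i,j] * xs[n,c,i,j]
            dw[:, :, di, dj] = np.tensordot(dout, xs, axes=([0, 2, 3], [0, 2, 3]))
            dxp[:, :, sl_i, sl_j] += np.tensordot(
                dout, w[:, :, di, dj], axes=([1], [0])
            ).transpose(0, 3, 1, 2)
    dx = dxp[:, :, pad : pad + h, pad : pad + wd] if pad else dxp
    return dx, dw, db


def relu_forward(x):
    return np.maximum(x, 0.0), x > 0


def relu_backward(dout, mask):
    return dout * mask


def avgpool_forward(x, factor):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // factor, factor, w // factor, factor)
    return xr.mean(axis=(3, 5))


def avgpool_backward(dout, factor):
    scale = 1.0 / (factor * factor)
    return np.repeat(np.repeat(dout, factor, axis=2), factor, axis=3) * scale


def upsample_forward(x, factor):
    """Nearest-neighbor upsampling by an integer factor."""
    return np.repeat(np.repeat(x, factor, axis=2), factor, axis=3)


def upsample_backward(dout, factor):
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // factor, factor, w // factor, factor).sum(axis=(3, 5))


def softmax_cross_entropy(logits, targets):
    """Mean per-pixel CE. logits: (N,C,H,W); targets: (N,H,W) int indices."""
    shifted = logits - logits.max(axis=1, keepdims=True)
    exp = np.exp(shifted)
    probs = exp / exp.sum(axis=1, keepdims=True)
    n, c, h, w = logits.shape
    idx_n, idx_h, idx_w = np.indices(targets.shape)
    p_true = probs[idx_n, targets, idx_h, idx_w]
    loss = float(-np.log(np.maximum(p_true, 1e-300)).mean())
    dlogits = probs.copy()
    dlogits[idx_n, targets, idx_h, idx_w] -= 1.0
    dlogits /= targets.size
    return loss, probs, dlogits


# ---------------------------------------------------------------------------
# Parameterized modules
# ---------------------------------------------------------------------------


class _Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


def _he_init(rng, f, c, k):
    std = np.sqrt(2.0 / (c * k * k))
    return rng.normal(0.0, std, size=(f, c, k, k))


class _Conv:
    """Conv + optional ReLU with stored cache for one forward/backward pair."""

    def __init__(self, rng, c_in, c_out, k=3, stride=1, dilation=1, relu=True):
        self.w = _Param(_he_init(rng, c_out, c_in, k))
        self.b = _Param(np.zeros(c_out))
        self.stride = stride
        self.dilation = dilation
        self.relu = relu
        self._cache = None

    def forward(self, x):
        out, cache = conv2d_forward(x, self.w.value, self.b.value, self.stride, self.dilation)
        mask = None
        if self.relu:
            out, mask = relu_forward(out)
        self._cache = (cache, mask)
        return out

    def backward(self, dout):
        cache, mask = self._cache
        if self.relu:
            dout = relu_backward(dout, mask)
        dx, dw, db = conv2d_backward(dout, self.w.value, cache, self.stride, self.dilation)
        self.w.grad += dw
        self.b.grad += db
        return dx

    def params(self):
        return [self.w, self.b]


class _ESPBlock:
    """Efficient spatial-pyramid block: parallel dilated 3x3 convs + residual.

    Channels must be even; each branch produces half the channels and the
    concatenation is added back to the input.
    """

    def __init__(self, rng, channels):
        assert channels % 2 == 0, "ESP block needs an even channel count"
        half = channels // 2
        self.b1 = _Conv(rng, channels, half, k=3, dilation=1, relu=True)
        self.b2 = _Conv(rng, channels, half, k=3, dilation=2, relu=True)
        self.half = half

    def forward(self, x):
        y1 = self.b1.forward(x)
        y2 = self.b2.forward(x)
        return x + np.concatenate([y1, y2], axis=1)

    def backward(self, dout):
        d1 = self.b1.backward(dout[:, : self.half])
        d2 = self.b2.backward(dout[:, self.half :])
        return dout + d1 + d2

    def params(self):
        return self.b1.params() + self.b2.params()


@dataclass
class SegNetConfig:
    """Architecture knobs for :class:`EncoderDecoder`.

    ``width`` is the channel count of the first encoder stage (doubled at
    the second); ``n_stages`` is fixed wiring-wise at 2 but validated so a
    nonsense config fails early.  ``patch_size`` is the training/inference
    tile side; inputs are padded internally to a multiple of 4.
    """

    n_classes: int = 8
    width: int = 8
    n_stages: int = 2
    patch_size: int = 384
    class_codes: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        if self.width < 2 or self.width % 2:
            raise ValueError("width must be an even integer >= 2")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


class EncoderDecoder:
    """Two-stage input-aware encoder-decoder with dense skips (see module doc).

    Resolutions: input (1x) -> e1 (1/2) -> e2 (1/4) -> d_half (1/2) ->
    d_full (1x).  Class logits are emitted at both decoder resolutions and
    summed at input resolution.
    """

    def __init__(self, config: SegNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        w = config.width
        c = config.n_classes
        # Encoder stage 1: stride-2 conv from RGB, ESP context block.
        self.enc1 = _Conv(rng, 3, w, k=3, stride=2)
        self.esp1 = _ESPBlock(rng, w)
        # Input-aware: stage-1 features travel with a 1/2-pooled RGB copy.
        self.enc2 = _Conv(rng, w + 3, 2 * w, k=3, stride=2)
        self.esp2 = _ESPBlock(rng, 2 * w)
        # Decoder at 1/2: dense skips from e2 (upsampled) and e1.
        self.dec_half = _Conv(rng, (2 * w + 3) + (w + 3), w, k=3)
        # Decoder at 1x: skips from d_half, e1, and e2 (both upsampled).
        self.dec_full = _Conv(rng, w + (w + 3) + (2 * w + 3), w, k=3)
        # Per-path classification heads (1x1, no ReLU).
        self.head_half = _Conv(rng, w, c, k=1, relu=False)
        self.head_full = _Conv(rng, w, c, k=1, relu=False)
        self._modules = [
            self.enc1, self.esp1, self.enc2, self.esp2,
            self.dec_half, self.dec_full, self.head_half, self.head_full,
        ]
        self._step = 0

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N,3,H,W) float in [0,1], H and W multiples of 4 -> (N,C,H,W)."""
        n, _, h, wd = x.shape
        if h % 4 or wd % 4:
            raise ValueError("input height/width must be multiples of 4")
        x_half = avgpool_forward(x, 2)
        x_quarter = avgpool_forward(x, 4)
        e1 = self.esp1.forward(self.enc1.forward(x))          # (N,w,H/2,W/2)
        e1a = np.concatenate([e1, x_half], axis=1)            # input-aware
        e2 = self.esp2.forward(self.enc2.forward(e1a))        # (N,2w,H/4,W/4)
        e2a = np.concatenate([e2, x_quarter], axis=1)
        e2a_up = upsample_forward(e2a, 2)
        d_half = self.dec_half.forward(np.concatenate([e2a_up, e1a], axis=1))
        d_half_up = upsample_forward(d_half, 2)
        e1a_up = upsample_forward(e1a, 2)
        e2a_up4 = upsample_forward(e2a, 4)
        d_full = self.dec_full.forward(
            np.concatenate([d_half_up, e1a_up, e2a_up4], axis=1)
        )
        logits_half = upsample_forward(self.head_half.forward(d_half), 2)
        logits_full = self.head_full.forward(d_full)
        return logits_half + logits_full

    def backward(self, dlogits: np.ndarray) -> None:
        w = self.config.width
        d_dfull = self.head_full.backward(dlogits)
        d_dhalf_from_head = self.head_half.backward(upsample_backward(dlogits, 2))
        d_cat_full = self.dec_full.backward(d_dfull)
        d_dhalf_up = d_cat_full[:, :w]
        d_e1a_up = d_cat_full[:, w : 2 * w + 3]
        d_e2a_up4 = d_cat_full[:, 2 * w + 3 :]
        d_dhalf = upsample_backward(d_dhalf_up, 2) + d_dhalf_from_head
        d_cat_half = self.dec_half.backward(d_dhalf)
        d_e2a_up = d_cat_half[:, : 2 * w + 3]
        d_e1a = d_cat_half[:, 2 * w + 3 :]
        d_e2a = upsample_backward(d_e2a_up, 2) + upsample_backward(d_e2a_up4, 4)
        d_e1a = d_e1a + upsample_backward(d_e1a_up, 2)
        d_e2 = d_e2a[:, : 2 * w]  # pooled-input branches need no gradient
        d_e1a = d_e1a + self.enc2.backward(self.esp2.backward(d_e2))
        d_e1 = d_e1a[:, :w]
        self.enc1.backward(self.esp1.backward(d_e1))

    # -- optimization -------------------------------------------------------

    def params(self):
        out = []
        for m in self._modules:
            out.extend(m.params())
        return out

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def adam_step(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self._step += 1
        t = self._step
        for p in self.params():
            p.m = beta1 * p.m + (1 - beta1) * p.grad
            p.v = beta2 * p.v + (1 - beta2) * p.grad**2
            mhat = p.m / (1 - beta1**t)
            vhat = p.v / (1 - beta2**t)
            p.value -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- serialization ------------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.params()]

    def set_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.params()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.value = a.astype(np.float64)
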