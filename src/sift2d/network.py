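"""A small numpy neural-network engine and the residual scorer trunk.

The quality scorer is a residual CNN with metadata fusion. Layers here
implement exactly what it needs — strided convolution, batch normalization,
ReLU, adaptive average pooling and affine layers — each with a hand-written
backward pass, plus the Adam optimizer. Everything is float32/float64 numpy
and fully deterministic given a seed, on any CPU.

Architecture (``ResidualScorerNet``):

* stem: 3x3 convolution (pad 1) to ``stem_channels``, BN, ReLU;
* per stage: a *pair* of 2x2 stride-2 convolutions (each followed by BN and
  ReLU) instead of pooling — downsampling that learns a weighted average —
  then ``blocks_per_stage`` residual blocks (3x3 conv, BN, ReLU, 3x3 conv,
  BN, identity skip, ReLU);
* adaptive average pooling to a fixed 6x6 grid, so any input side >= 31 maps
  to the same flattened width;
* head: the 6x6 pooled activations are flattened, concatenated with the
  6 standardized metadata features, and passed through two affine layers
  with a ReLU between, producing one unbounded real score.

Stride-2 2x2 convolutions use ceil-halving padding (an odd side is padded by
one) so arbitrary sides survive repeated downsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError

__all__ = ["NetConfig", "ResidualScorerNet", "Adam", "DEFAULT_CONFIG", "DESK_CONFIG"]

_EPS = 1e-5


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay  # weight-decay applies to weights, not BN/bias


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (n, c, ho, wo, k, k), (s0, s1, s2 * stride, s3 * stride, s2, s3)
    )
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols, xshape, k, stride, pad, ho, wo):
    n, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    dx = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    dview = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                dview[:, :, :, :, i, j]
            )
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Conv2d:
    """2D convolution, NCHW, square kernel, optional ceil-halving padding."""

    def __init__(self, c_in, c_out, k, stride=1, pad=0, ceil_pad=False, rng=None):
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.w = Param(rng.standard_normal((c_out, c_in, k, k)) * scale)
        self.b = Param(np.zeros(c_out), decay=False)
        self.k, self.stride, self.pad, self.ceil_pad = k, stride, pad, ceil_pad
        self._cache = None

    def parameters(self):
        return [self.w, self.b]

    def _effective_pad(self, side):
        if not self.ceil_pad:
            return self.pad
        # pad so the output side is ceil(side / stride) for k == stride == 2
        return 1 if (side % 2 or side < self.k) else 0

    def forward(self, x, train=True):
        pad = self._effective_pad(x.shape[2])
        cols, ho, wo = _im2col(x, self.k, self.stride, pad)
        wmat = self.w.value.reshape(self.w.value.shape[0], -1)
        out = cols @ wmat.T + self.b.value
        n = x.shape[0]
        out = out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)
        self._cache = (x.shape, cols, pad, ho, wo)
        return out

    def backward(self, dout):
        xshape, cols, pad, ho, wo = self._cache
        n, c_out = dout.shape[0], dout.shape[1]
        dmat = dout.transpose(0, 2, 3, 1).reshape(-1, c_out)
        wmat = self.w.value.reshape(c_out, -1)
        self.w.grad += (dmat.T @ cols).reshape(self.w.value.shape)
        self.b.grad += dmat.sum(axis=0)
        dcols = dmat @ wmat
        return _col2im(dcols, xshape, self.k, self.stride, pad, ho, wo)


class BatchNorm2d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c, momentum=0.1):
        self.gamma = Param(np.ones(c), decay=False)
        self.beta = Param(np.zeros(c), decay=False)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + _EPS)
        xhat = (x - mean[None, :, None, None]) * inv_sd[None, :, None, None]
        self._cache = (xhat, inv_sd, train, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, dout):
        xhat, inv_sd, train, shape = self._cache
        n_eff = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None] * inv_sd[None, :, None, None]
        if not train:
            return dout * g
        dsum = dout.sum(axis=(0, 2, 3))[None, :, None, None]
        dxhat_sum = (dout * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return g * (dout - dsum / n_eff - xhat * dxhat_sum / n_eff)


class ReLU:
    def __init__(self):
        self._mask = None

    def parameters(self):
        return []

    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class AdaptiveAvgPool2d:
    """Average pooling to a fixed output grid, any input size.

    Cell (i, j) averages rows floor(i*H/out)..ceil((i+1)*H/out) (and likewise
    columns), so inputs smaller than the grid are replicated — the contract
    is only that the output grid is fixed.
    """

    def __init__(self, out_side: int):
        self.out = out_side
        self._cache = None

    def parameters(self):
        return []

    @staticmethod
    def _bounds(size, out):
        starts = [(i * size) // out for i in range(out)]
        ends = [-(-((i + 1) * size) // out) for i in range(out)]  # ceil div
        return starts, ends

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        rs, re = self._bounds(h, self.out)
        cs, ce = self._bounds(w, self.out)
        out = np.empty((n, c, self.out, self.out), dtype=x.dtype)
        for i in range(self.out):
            for j in range(self.out):
                out[:, :, i, j] = x[:, :, rs[i] : re[i], cs[j] : ce[j]].mean(
                    axis=(2, 3)
                )
        self._cache = (x.shape, rs, re, cs, ce)
        return out

    def backward(self, dout):
        shape, rs, re, cs, ce = self._cache
        dx = np.zeros(shape, dtype=dout.dtype)
        for i in range(self.out):
            for j in range(self.out):
                area = (re[i] - rs[i]) * (ce[j] - cs[j])
                dx[:, :, rs[i] : re[i], cs[j] : ce[j]] += (
                    dout[:, :, i, j][:, :, None, None] / area
                )
        return dx


class Linear:
    def __init__(self, n_in, n_out, rng):
        scale = np.sqrt(2.0 / n_in)
        self.w = Param(rng.standard_normal((n_out, n_in)) * scale)
        self.b = Param(np.zeros(n_out), decay=False)
        self._x = None

    def parameters(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dout):
        self.w.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value


class ResidualBlock:
    """conv3x3-BN-ReLU-conv3x3-BN with identity skip, ReLU after the add."""

    def __init__(self, c, rng):
        self.conv1 = Conv2d(c, c, 3, pad=1, rng=rng)
        self.bn1 = BatchNorm2d(c)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c, c, 3, pad=1, rng=rng)
        self.bn2 = BatchNorm2d(c)
        self.relu_out = ReLU()

    def parameters(self):
        return (
            self.conv1.parameters()
            + self.bn1.parameters()
            + self.conv2.parameters()
            + self.bn2.parameters()
        )

    def forward(self, x, train=True):
        out = self.bn1.forward(self.conv1.forward(x, train), train)
        out = self.relu1.forward(out, train)
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        return self.relu_out.forward(out + x, train)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        dskip = d
        d = self.bn2.backward(d)
        d = self.conv2.backward(d)
        d = self.relu1.backward(d)
        d = self.bn1.backward(d)
        d = self.conv1.backward(d)
        return d + dskip


# ---------------------------------------------------------------------------
# the scorer network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters of the residual scorer trunk."""

    stem_channels: int = 32
    stage_channels: tuple[int, ...] = (64, 128)
    blocks_per_stage: int = 2
    pool_side: int = 6
    head_hidden: int = 64
    n_features: int = 6

    def __post_init__(self):
        if self.stem_channels < 1 or any(c < 1 for c in self.stage_channels):
            raise ValidationError("channel widths must be positive")
        if self.blocks_per_stage < 1:
            raise ValidationError("blocks_per_stage must be >= 1")


DEFAULT_CONFIG = NetConfig()
# reduced widths for CPU-scale experiments and tests
DESK_CONFIG = NetConfig(
    stem_channels=4, stage_channels=(8, 16), blocks_per_stage=1, head_hidden=32
)


class ResidualScorerNet:
    """Residual CNN + metadata fusion regressing one quality score."""

    MIN_SIDE = 31

    def __init__(self, config: NetConfig = DEFAULT_CONFIG, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.stem_channels
        self.stem = [Conv2d(1, c, 3, pad=1, rng=rng), BatchNorm2d(c), ReLU()]
        self.stages = []
        for c_out in config.stage_channels:
            stage = [
                Conv2d(c, c_out, 2, stride=2, ceil_pad=True, rng=rng),
                BatchNorm2d(c_out),
                ReLU(),
                Conv2d(c_out, c_out, 2, stride=2, ceil_pad=True, rng=rng),
                BatchNorm2d(c_out),
                ReLU(),
            ]
            stage += [ResidualBlock(c_out, rng) for _ in range(config.blocks_per_stage)]
            self.stages.append(stage)
            c = c_out
        self.pool = AdaptiveAvgPool2d(config.pool_side)
        flat = c * config.pool_side**2
        self.head = [
            Linear(flat + config.n_features, config.head_hidden, rng),
            ReLU(),
            Linear(config.head_hidden, 1, rng),
        ]
        self._trunk_out_channels = c
        self._cache_n = None

    # -- plumbing ----------------------------------------------------------

    def parameters(self) -> list[Param]:
        ps = []
        for layer in self.stem:
            ps += layer.parameters()
        for stage in self.stages:
            for layer in stage:
                ps += layer.parameters()
        for layer in self.head:
            ps += layer.parameters()
        return ps

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All weights and BN running statistics, keyed for serialization."""
        out = {}
        for i, p in enumerate(self.parameters()):
            out[f"param_{i:04d}"] = p.value
        bn_i = 0
        for layer in self._all_layers():
            if isinstance(layer, BatchNorm2d):
                out[f"bn_{bn_i:04d}_mean"] = layer.running_mean
                out[f"bn_{bn_i:04d}_var"] = layer.running_var
                bn_i += 1
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            src = arrays[f"param_{i:04d}"]
            if src.shape != p.value.shape:
                raise ValidationError(
                    f"weight shape mismatch for param_{i:04d}: "
                    f"{src.shape} vs {p.value.shape}"
                )
            p.value[...] = src
        bn_i = 0
        for layer in self._all_layers():
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = arrays[f"bn_{bn_i:04d}_mean"]
                layer.running_var[...] = arrays[f"bn_{bn_i:04d}_var"]
                bn_i += 1

    def _all_layers(self):
        for layer in self.stem:
            yield layer
        for stage in self.stages:
            for layer in stage:
                if isinstance(layer, ResidualBlock):
                    yield layer.bn1
                    yield layer.bn2
                else:
                    yield layer
        for layer in self.head:
            yield layer

    # -- forward / backward ------------------------------------------------

    def trunk(self, images: np.ndarray, train: bool = True) -> np.ndarray:
        """Convolutional trunk up to (and including) the 6x6 pooling."""
        if images.ndim == 3:
            images = images[:, None]
        if images.shape[2] < self.MIN_SIDE or images.shape[3] < self.MIN_SIDE:
            raise ValidationError(
                f"input side {images.shape[2:]} below the "
                f"{self.MIN_SIDE}x{self.MIN_SIDE} pixel minimum"
            )
        x = images.astype(np.float64)
        for layer in self.stem:
            x = layer.forward(x, train)
        for stage in self.stages:
            for layer in stage:
                x = layer.forward(x, train)
        return self.pool.forward(x, train)

    def forward(
        self, images: np.ndarray, features: np.ndarray, train: bool = True
    ) -> np.ndarray:
        """Score a batch: images (N, H, W) + standardized features (N, 6)."""
        pooled = self.trunk(images, train)
        n = pooled.shape[0]
        flat = pooled.reshape(n, -1)
        fused = np.concatenate([flat, np.asarray(features, dtype=np.float64)], axis=1)
        h = fused
        for layer in self.head:
            h = layer.forward(h, train)
        self._cache_n = n
        return h[:, 0]

    def backward(self, dscores: np.ndarray) -> None:
        """Accumulate parameter gradients for a loss gradient d(loss)/d(score)."""
        n = self._cache_n
        d = dscores.reshape(n, 1)
        for layer in reversed(self.head):
            d = layer.backward(d)
        flat_width = self._trunk_out_channels * self.config.pool_side**2
        d_flat = d[:, :flat_width]
        d = self.pool.backward(
            d_flat.reshape(n, self._trunk_out_channels, self.config.pool_side, -1)
        )
        for stage in reversed(self.stages):
            for layer in reversed(stage):
                d = layer.backward(d)
        for layer in reversed(self.stem):
            d = layer.backward(d)


class Adam:
    """Adam with the optimizer's native L2 penalty added to the gradient."""

    def __init__(self, params, lr=1e-4, weight_decay=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.weight_decay = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.value
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
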