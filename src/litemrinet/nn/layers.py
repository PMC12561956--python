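"""Neural-network layers on top of the autograd engine.

All image tensors are channels-last ``(N, H, W, C)``; token tensors are
``(N, T, C)``.  Convolution is computed as a sum of nine shifted
pointwise matmuls, which keeps the inner loop inside BLAS without an
im2col copy of the whole feature map.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Parameter, Tensor, concat


def _conv2d(x: Tensor, weight: Parameter, bias: Parameter | None) -> Tensor:
    """Same-padded 2-D convolution as k*k shifted GEMMs (fused op).

    The backward pass is hand-written: it recomputes the column views
    instead of storing them, so training memory stays at one padded
    copy of the input per layer.
    """
    k = weight.shape[0]
    p = k // 2
    xd = x.data
    n, h, w, cin = xd.shape
    cout = weight.shape[-1]
    wd = weight.data.reshape(k * k, cin, cout)
    xp = np.pad(xd, ((0, 0), (p, p), (p, p), (0, 0))) if p else xd
    acc = np.zeros((n * h * w, cout), dtype=xd.dtype)
    for i in range(k * k):
        dy, dx = divmod(i, k)
        col = np.ascontiguousarray(xp[:, dy:dy + h, dx:dx + w, :]).reshape(-1, cin)
        acc += col @ wd[i]
    if bias is not None:
        acc += bias.data
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor._from_op(acc.reshape(n, h, w, cout), parents, None)

    def backward(g):
        g2 = np.ascontiguousarray(g).reshape(-1, cout)
        gw = np.empty((k * k, cin, cout), dtype=wd.dtype)
        gxp = np.zeros_like(xp)
        for i in range(k * k):
            dy, dx = divmod(i, k)
            col = np.ascontiguousarray(xp[:, dy:dy + h, dx:dx + w, :]).reshape(-1, cin)
            gw[i] = col.T @ g2
            gxp[:, dy:dy + h, dx:dx + w, :] += (g2 @ wd[i].T).reshape(n, h, w, cin)
        gx = gxp[:, p:-p, p:-p, :] if p else gxp
        gw = gw.reshape(weight.shape)
        return (gx, gw) if bias is None else (gx, gw, g2.sum(axis=0))

    out._set_backward(backward)
    return out


def _batchnorm_train(x: Tensor, gamma: Parameter, beta: Parameter,
                     eps: float) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused batch normalization over (N, H, W); returns (out, mean, var)."""
    xd = x.data
    axes = (0, 1, 2)
    m = xd.size // xd.shape[-1]
    mu = xd.mean(axis=axes)
    xc = xd - mu
    var = np.mean(xc * xc, axis=axes)
    std = np.sqrt(var + eps)
    xhat = xc / std
    out = Tensor._from_op(xhat * gamma.data + beta.data, (x, gamma, beta), None)

    def backward(g):
        dgamma = np.sum(g * xhat, axis=axes)
        dbeta = np.sum(g, axis=axes)
        dx = (gamma.data / std) * (g - dbeta / m - xhat * (dgamma / m))
        return dx, dgamma, dbeta

    out._set_backward(backward)
    return out, mu, var

__all__ = [
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "ConvBNReLU",
    "Linear",
    "LayerNorm",
    "MaxPool2x2",
    "BilinearUpsample2x",
    "MultiHeadAttention",
    "TransformerBlock",
    "PositionalEmbedding",
]


class Module:
    """Base class with parameter registration and train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield (f"{prefix}{name}", p)
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-trainable state (e.g. batch-norm running statistics)."""
        out = {}
        for name, m in self._modules.items():
            for k, v in m.buffers().items():
                out[f"{name}.{k}"] = v
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {k: p.data for k, p in self.named_parameters()}
        for k, v in self.buffers().items():
            d[f"buffer:{k}"] = v
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        bufs = self.buffers()
        for k, v in d.items():
            if k.startswith("buffer:"):
                tgt = bufs[k[len("buffer:"):]]
                tgt[...] = v
            else:
                p = params[k]
                if p.data.shape != v.shape:
                    raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {v.shape}")
                p.data = v.astype(p.data.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list = []
        for m in modules:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(ModuleList):
    def forward(self, x):
        for m in self:
            x = m(x)
        return x


class Conv2d(Module):
    """2-D convolution with symmetric zero padding (spatial size preserved)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        k = kernel_size
        std = np.sqrt(2.0 / (k * k * in_channels))  # He init for ReLU stacks
        self.weight = Parameter(rng.normal(0.0, std, size=(k, k, in_channels, out_channels)))
        self.bias = Parameter(np.zeros(out_channels), penalized=False) if bias else None
        self.kernel_size = k
        self.in_channels = in_channels
        self.out_channels = out_channels

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_channels:
            raise ValueError(
                f"channel mismatch: input has {x.shape[-1]} channels, "
                f"layer expects {self.in_channels}"
            )
        return _conv2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel, with running stats.

    ``stats_groups > 1`` keeps one set of running statistics per input
    stream while the affine parameters stay shared.  The scale-shared
    encoder uses one group per pyramid level: its *trainable* store is
    single, but each scale is normalized at inference with the
    statistics actually observed at that scale during training.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 stats_groups: int = 1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels), penalized=False)
        self.beta = Parameter(np.zeros(channels), penalized=False)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros((stats_groups, channels), dtype=np.float32)
        self.running_var = np.ones((stats_groups, channels), dtype=np.float32)

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: Tensor, group: int = 0) -> Tensor:
        if self.training:
            out, mu, var = _batchnorm_train(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean[group] = (1 - m) * self.running_mean[group] + m * mu
            self.running_var[group] = (1 - m) * self.running_var[group] + m * var
            return out
        xhat = (x - self.running_mean[group]) * (
            1.0 / np.sqrt(self.running_var[group] + self.eps))
        return xhat * self.gamma + self.beta


class ConvBNReLU(Module):
    """The standard encoder/decoder layer: 3x3 conv, stride 1, BatchNorm, ReLU."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 rng: np.random.Generator | None = None, stats_groups: int = 1):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, kernel_size, rng=rng)
        self.bn = BatchNorm2d(out_channels, stats_groups=stats_groups)

    def forward(self, x: Tensor, group: int = 0) -> Tensor:
        return self.bn(self.conv(x), group=group).relu()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = np.sqrt(6.0 / (in_features + out_features))  # Glorot uniform
        self.weight = Parameter(rng.uniform(-bound, bound, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features), penalized=False)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, features: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(features), penalized=False)
        self.beta = Parameter(np.zeros(features), penalized=False)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / (var + self.eps).sqrt() * self.gamma + self.beta


class MaxPool2x2(Module):
    """2x2 max pooling with stride 2."""

    def forward(self, x: Tensor) -> Tensor:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max pool requires even spatial sides, got {h}x{w}")
        x = x.reshape(n, h // 2, 2, w // 2, 2, c)
        return x.max(axis=2).max(axis=3)


class BilinearUpsample2x(Module):
    """Bilinear x2 upsampling (align_corners=False convention, edges clamped)."""

    @staticmethod
    def _axis_up(x: Tensor, axis: int) -> Tensor:
        n = x.shape[axis]
        sl = [slice(None)] * x.ndim

        def take(a, b):
            s = list(sl)
            s[axis] = slice(a, b)
            return x[tuple(s)]

        prev = concat([take(0, 1), take(0, n - 1)], axis=axis)
        nxt = concat([take(1, n), take(n - 1, n)], axis=axis)
        even = 0.75 * x + 0.25 * prev
        odd = 0.75 * x + 0.25 * nxt
        shape = list(x.shape)
        shape.insert(axis + 1, 1)
        stacked = concat([even.reshape(shape), odd.reshape(shape)], axis=axis + 1)
        out_shape = list(x.shape)
        out_shape[axis] = 2 * n
        return stacked.reshape(out_shape)

    def forward(self, x: Tensor) -> Tensor:
        return self._axis_up(self._axis_up(x, 1), 2)


class MultiHeadAttention(Module):
    def __init__(self, channels: int, heads: int, rng: np.random.Generator | None = None):
        super().__init__()
        if channels % heads:
            raise ValueError(f"heads ({heads}) must divide channels ({channels})")
        self.qkv = Linear(channels, 3 * channels, rng=rng)
        self.proj = Linear(channels, channels, rng=rng)
        self.heads = heads
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        n, t, c = x.shape
        h, d = self.heads, c // self.heads
        qkv = self.qkv(x).reshape(n, t, 3, h, d).transpose(2, 0, 3, 1, 4)  # (3,N,h,T,d)
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, c)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm Transformer block: MHA and GELU feed-forward, residual adds."""

    def __init__(self, channels: int, heads: int, ffn_expansion: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.ln1 = LayerNorm(channels)
        self.attn = MultiHeadAttention(channels, heads, rng=rng)
        self.ln2 = LayerNorm(channels)
        self.ffn1 = Linear(channels, ffn_expansion * channels, rng=rng)
        self.ffn2 = Linear(ffn_expansion * channels, channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.ffn2(self.ffn1(self.ln2(x)).gelu())


class PositionalEmbedding(Module):
    """Learned additive positional embedding over a fixed token lattice."""

    def __init__(self, tokens: int, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.embedding = Parameter(rng.normal(0.0, 0.02, size=(tokens, channels)),
                                   penalized=False)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.embedding
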