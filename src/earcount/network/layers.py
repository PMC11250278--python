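"""Neural-network building blocks on top of the autograd engine.

Contains the generic layers (conv, batch/layer norm, linear) plus the three
architecture-specific blocks of the counting network: CBS (conv + batch norm
+ SiLU), the cross-stage-partial (CSP) stage, the pyramid-pooling multi-head
self-attention transformer block, and the attentional feature fusion (AFF)
operator.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from . import autograd as ag
from .autograd import Tensor


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class: attribute-scan parameter registry, train/eval switch."""

    def __init__(self):
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    # -- registry ------------------------------------------------------------
    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, value in self._buffers.items():
            yield prefix + name, value
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({k: v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        for key, val in state.items():
            if key in own:
                if own[key].data.shape != val.shape:
                    raise ValueError(f"shape mismatch for {key}: "
                                     f"{own[key].data.shape} vs {val.shape}")
                own[key].data = val.astype(np.float32).copy()
            else:
                self._load_buffer(key, val)

    def _load_buffer(self, key: str, val: np.ndarray):
        modules: dict[str, Module] = {"": self}
        stack: list[tuple[str, Module]] = [("", self)]
        while stack:
            prefix, mod = stack.pop()
            for name, child in mod._children():
                modules[prefix + name] = child
                stack.append((prefix + name + ".", child))
        mod_path, _, buf = key.rpartition(".")
        owner = modules.get(mod_path)
        if owner is None or buf not in owner._buffers:
            raise KeyError(f"unknown state entry {key!r}")
        owner._buffers[buf] = val.copy()

    # -- mode ---------------------------------------------------------------
    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    def __init__(self, cin, cout, k=1, stride=1, padding=None, dilation=1,
                 bias=True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        if padding is None:
            padding = dilation * (k // 2)
        self.stride, self.padding, self.dilation = stride, padding, dilation
        fan_in = cin * k * k
        std = math.sqrt(2.0 / fan_in)  # He init, ReLU-family activations
        self.weight = parameter(rng.normal(0.0, std, size=(cout, cin, k, k)))
        self.bias = parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, dilation=self.dilation)


class Linear(Module):
    def __init__(self, cin, cout, bias=True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = math.sqrt(6.0 / (cin + cout))  # Xavier uniform
        self.weight = parameter(rng.uniform(-bound, bound, size=(cin, cout)))
        self.bias = parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        y = ag.matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = parameter(np.ones(c))
        self.beta = parameter(np.zeros(c))
        self._buffers["running_mean"] = np.zeros(c, dtype=np.float32)
        self._buffers["running_var"] = np.ones(c, dtype=np.float32)

    def forward(self, x):
        c = x.shape[1]
        shape = (1, c, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"] + m * mu.data.reshape(c))
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"] + m * var.data.reshape(c))
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(shape))
            var = Tensor(self._buffers["running_var"].reshape(shape))
        xhat = (x - mu) / ag.sqrt(var + self.eps)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class LayerNorm(Module):
    """Normalisation over the channel (last) axis of a token sequence."""

    def __init__(self, c, eps=1e-6):
        super().__init__()
        self.eps = eps
        self.gamma = parameter(np.ones(c))
        self.beta = parameter(np.zeros(c))

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ag.sqrt(var + self.eps) * self.gamma + self.beta


class CBS(Module):
    """Conv + BatchNorm + SiLU, the elementary block of the CSP backbone."""

    def __init__(self, cin, cout, k=1, stride=1, dilation=1, rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride=stride, dilation=dilation,
                           bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)

    def forward(self, x):
        return ag.silu(self.bn(self.conv(x)))


class Bottleneck(Module):
    """1x1 -> 3x3 CBS pair with a residual shortcut."""

    def __init__(self, c, rng=None):
        super().__init__()
        self.cv1 = CBS(c, c, 1, rng=rng)
        self.cv2 = CBS(c, c, 3, rng=rng)

    def forward(self, x):
        return x + self.cv2(self.cv1(x))


class CSPStage(Module):
    """Cross-stage-partial stage with a stride-2 entry convolution.

    The entry CBS halves the spatial resolution and sets the stage width;
    the body splits channels into a bottleneck path and a shortcut path,
    concatenates them, and mixes with a final 1x1 CBS.
    """

    def __init__(self, cin, cout, n_bottlenecks=1, rng=None):
        super().__init__()
        half = cout // 2
        self.down = CBS(cin, cout, 3, stride=2, rng=rng)
        self.split_main = CBS(cout, half, 1, rng=rng)
        self.split_short = CBS(cout, half, 1, rng=rng)
        self.blocks = [Bottleneck(half, rng=rng) for _ in range(n_bottlenecks)]
        self.mix = CBS(2 * half, cout, 1, rng=rng)

    def forward(self, x):
        x = self.down(x)
        main = self.split_main(x)
        for blk in self.blocks:
            main = blk(main)
        short = self.split_short(x)
        return self.mix(ag.concat([main, short], axis=1))


def _tokens(xmap):
    """(N,C,H,W) feature map -> (N, H*W, C) token sequence."""
    n, c, h, w = xmap.shape
    return xmap.reshape((n, c, h * w)).transpose((0, 2, 1))


def _to_map(tokens, h, w):
    n, _, c = tokens.shape
    return tokens.transpose((0, 2, 1)).reshape((n, c, h, w))


class PyramidPoolAttention(Module):
    """Multi-head self-attention with pyramid-pooled keys/values.

    Queries come from every token; keys and values come from the feature map
    adaptively average-pooled to a small pyramid of bin sizes (default
    1, 2, 3, 6), so the attended sequence is much shorter than the query
    sequence while still mixing context at several scales.
    """

    def __init__(self, c, heads, pool_bins: Sequence[int] = (1, 2, 3, 6), rng=None):
        super().__init__()
        if c % heads:
            raise ValueError(f"channels ({c}) must be divisible by heads ({heads})")
        self.heads = heads
        self.dim_head = c // heads
        self.pool_bins = tuple(pool_bins)
        self.wq = Linear(c, c, rng=rng)
        self.wk = Linear(c, c, rng=rng)
        self.wv = Linear(c, c, rng=rng)
        self.proj = Linear(c, c, rng=rng)

    def pooled_tokens(self, xmap):
        n, c, h, w = xmap.shape
        parts = []
        for b in self.pool_bins:
            size = (min(b, h), min(b, w))
            parts.append(_tokens(ag.adaptive_avg_pool2d(xmap, size)))
        return ag.concat(parts, axis=1)

    def _split_heads(self, t):
        n, L, c = t.shape
        return t.reshape((n, L, self.heads, self.dim_head)).transpose((0, 2, 1, 3))

    def forward(self, tokens, xmap):
        n, L, c = tokens.shape
        kv = self.pooled_tokens(xmap)
        q = self._split_heads(self.wq(tokens))            # (N,h,L,d)
        k = self._split_heads(self.wk(kv))                # (N,h,S,d)
        v = self._split_heads(self.wv(kv))
        attn = ag.softmax(ag.matmul(q, k.transpose((0, 1, 3, 2))) *
                          (1.0 / math.sqrt(self.dim_head)), axis=-1)
        out = ag.matmul(attn, v)                          # (N,h,L,d)
        out = out.transpose((0, 2, 1, 3)).reshape((n, L, c))
        return self.proj(out)


class P2TBlock(Module):
    """Transformer block: pooled-KV attention, then FFN, each with
    a residual connection followed by layer normalisation."""

    def __init__(self, c, heads, pool_bins=(1, 2, 3, 6), ffn_expansion=4, rng=None):
        super().__init__()
        self.attn = PyramidPoolAttention(c, heads, pool_bins, rng=rng)
        self.norm1 = LayerNorm(c)
        self.norm2 = LayerNorm(c)
        self.ffn_in = Linear(c, c * ffn_expansion, rng=rng)
        self.ffn_out = Linear(c * ffn_expansion, c, rng=rng)

    def forward(self, xmap):
        n, c, h, w = xmap.shape
        t = _tokens(xmap)
        t = self.norm1(t + self.attn(t, xmap))
        t = self.norm2(t + self.ffn_out(ag.gelu(self.ffn_in(t))))
        return _to_map(t, h, w)


class P2TEncoder(Module):
    """1x1 patch embedding followed by a stack of P2T blocks; the spatial
    resolution of the input feature grid is preserved."""

    def __init__(self, c, depth=2, heads=8, pool_bins=(1, 2, 3, 6),
                 ffn_expansion=4, rng=None):
        super().__init__()
        self.embed = Linear(c, c, rng=rng)
        self.blocks = [P2TBlock(c, heads, pool_bins, ffn_expansion, rng=rng)
                       for _ in range(depth)]

    def forward(self, xmap):
        n, c, h, w = xmap.shape
        xmap = _to_map(self.embed(_tokens(xmap)), h, w)
        for blk in self.blocks:
            xmap = blk(xmap)
        return xmap


class AFF(Module):
    """Attentional feature fusion of two equally-shaped feature streams.

    A global (image-pooled) and a local (pointwise) channel-attention branch
    are computed from the sum of the inputs; their sigmoid produces a
    per-channel, per-position weight M and the output is the convex
    combination M*a + (1-M)*b.
    """

    def __init__(self, c, reduction=4, rng=None):
        super().__init__()
        cr = max(c // reduction, 4)
        self.local_in = Conv2d(c, cr, 1, bias=False, rng=rng)
        self.local_bn = BatchNorm2d(cr)
        self.local_out = Conv2d(cr, c, 1, bias=False, rng=rng)
        self.local_bn2 = BatchNorm2d(c)
        self.glob_in = Conv2d(c, cr, 1, bias=False, rng=rng)
        self.glob_bn = BatchNorm2d(cr)
        self.glob_out = Conv2d(cr, c, 1, bias=False, rng=rng)
        self.glob_bn2 = BatchNorm2d(c)

    def attention(self, s):
        loc = self.local_bn2(self.local_out(ag.relu(self.local_bn(self.local_in(s)))))
        pooled = ag.adaptive_avg_pool2d(s, (1, 1))
        glo = self.glob_bn2(self.glob_out(ag.relu(self.glob_bn(self.glob_in(pooled)))))
        return ag.sigmoid(loc + glo)

    def forward(self, a, b):
        if a.shape != b.shape:
            raise ValueError(f"AFF inputs must match: {a.shape} vs {b.shape}")
        m = self.attention(a + b)
        return m * a + (1.0 - m) * b


class Adam:
    """Adam optimiser (the training recipe's adaptive gradient method)."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
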