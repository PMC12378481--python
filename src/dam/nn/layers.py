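"""Neural-network building blocks on top of the autograd core.

Includes the pieces the dynamic-aware model is assembled from: linear
and convolutional layers, per-sample normalisation, multi-head
attention with key masking, pre-norm transformer blocks, and an
18-layer residual CNN with a configurable base width.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Module", "Parameter", "Linear", "LayerNorm", "InstanceNorm2d",
    "Conv2d", "ResNet18", "MultiHeadAttention", "TransformerBlock",
    "PoolingAttention", "MLP", "Adam",
]

_NEG_INF = -1e30  # exp() underflows to exactly 0.0 → masked keys are inert


def Parameter(data) -> Tensor:
    t = Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)
    t.is_param = True
    return t


class Module:
    """Tiny container protocol: recursive parameter discovery."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.is_param and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((d_in, d_out))
        else:
            bound = np.sqrt(6.0 / (d_in + d_out))
            w = rng.uniform(-bound, bound, size=(d_in, d_out))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta


class InstanceNorm2d(Module):
    """Per-sample, per-channel spatial normalisation with affine.

    No batch statistics: outputs are independent of how images are
    batched, which keeps evaluation exactly deterministic.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta


def _conv_indices(C: int, Hp: int, Wp: int, kh: int, kw: int, stride: int):
    oh = (Hp - kh) // stride + 1
    ow = (Wp - kw) // stride + 1
    i0 = np.repeat(np.arange(oh) * stride, ow)
    j0 = np.tile(np.arange(ow) * stride, oh)
    c = np.repeat(np.arange(C), kh * kw)
    u = np.tile(np.repeat(np.arange(kh), kw), C)
    v = np.tile(np.tile(np.arange(kw), kh), C)
    flat = (c[None, :] * Hp * Wp
            + (i0[:, None] + u[None, :]) * Wp
            + (j0[:, None] + v[None, :]))
    return flat, oh, ow


class Conv2d(Module):
    """2-D convolution on (N, C, H, W) via gathered-column matmul."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 pad: int, rng: np.random.Generator):
        fan_in = c_in * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(c_out))
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._idx_cache: dict[tuple, tuple] = {}

    def __call__(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel, self.stride, self.pad
        N, C, H, W = x.shape
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
        Hp, Wp = H + 2 * p, W + 2 * p
        key = (C, Hp, Wp)
        if key not in self._idx_cache:
            self._idx_cache[key] = _conv_indices(C, Hp, Wp, k, k, s)
        idx, oh, ow = self._idx_cache[key]
        cols = xp.reshape(N, -1)[:, idx]                      # (N, P, C*k*k)
        wmat = self.weight.data.reshape(self.weight.shape[0], -1).T
        out = cols @ wmat + self.bias.data                    # (N, P, c_out)
        out = out.transpose(0, 2, 1).reshape(N, -1, oh, ow)

        weight, bias = self.weight, self.bias

        def backward(g):
            gmat = g.reshape(N, g.shape[1], oh * ow).transpose(0, 2, 1)
            if weight.requires_grad:
                gw = np.einsum("npk,npo->ok", cols, gmat)
                weight._accum(gw.reshape(weight.shape))
            if bias.requires_grad:
                bias._accum(gmat.sum(axis=(0, 1)))
            if x.requires_grad:
                dcols = gmat @ wmat.T
                gxp = np.zeros((N, C * Hp * Wp))
                np.add.at(gxp, (np.arange(N)[:, None, None], idx[None]), dcols)
                gxp = gxp.reshape(N, C, Hp, Wp)
                if p:
                    gxp = gxp[:, :, p:-p, p:-p]
                x._accum(gxp)

        return Tensor._make(out, (x, weight, bias), backward)


class _ResBlock(Module):
    def __init__(self, c_in: int, c_out: int, stride: int, rng):
        self.conv1 = Conv2d(c_in, c_out, 3, stride, 1, rng)
        self.norm1 = InstanceNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, 1, 1, rng)
        self.norm2 = InstanceNorm2d(c_out)
        self.down = (Conv2d(c_in, c_out, 1, stride, 0, rng)
                     if (stride != 1 or c_in != c_out) else None)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.norm1(self.conv1(x)).relu()
        h = self.norm2(self.conv2(h))
        skip = self.down(x) if self.down is not None else x
        return (h + skip).relu()


class ResNet18(Module):
    """18-layer residual CNN: stem conv + 8 two-conv blocks + linear head.

    Base channel width is configurable; the standard topology fixes the
    per-stage doubling and stride-2 downsampling. Global average pooling
    makes the output independent of input size (any H, W >= 32 works).
    """

    def __init__(self, width: int, d_out: int, rng: np.random.Generator):
        w = width
        self.stem = Conv2d(3, w, 3, 1, 1, rng)
        self.stem_norm = InstanceNorm2d(w)
        self.stages = []
        c_in = w
        for i, c in enumerate((w, 2 * w, 4 * w, 8 * w)):
            stride = 1 if i == 0 else 2
            self.stages.append(_ResBlock(c_in, c, stride, rng))
            self.stages.append(_ResBlock(c, c, 1, rng))
            c_in = c
        self.fc = Linear(8 * w, d_out, rng)
        self.feature_dim = 8 * w
        self._last_conv_act: Tensor | None = None

    def forward_conv(self, x: Tensor) -> Tensor:
        """All convolutional stages; output (N, 8w, H', W').

        The returned tensor is also stashed as the Grad-CAM target
        (the final convolutional layer's activations).
        """
        h = self.stem_norm(self.stem(x)).relu()
        for block in self.stages:
            h = block(h)
        self._last_conv_act = h
        return h

    def pooled(self, x: Tensor) -> Tensor:
        """Global average pooled convolutional features, (N, 8w)."""
        return self.forward_conv(x).mean(axis=(2, 3))

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc(self.pooled(x))


class MultiHeadAttention(Module):
    """Multi-head scaled dot-product attention with key masking.

    Works for self- and cross-attention; `last_weights` retains the
    head-resolved softmax weights of the most recent call (plain
    ndarray, no graph) for the interpretability module.
    """

    def __init__(self, d: int, n_heads: int, rng, zero_out_proj: bool = False):
        if d % n_heads:
            raise ValueError("embed dim must be divisible by n_heads")
        self.d, self.n_heads, self.dh = d, n_heads, d // n_heads
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng, zero_init=zero_out_proj)
        self.last_weights: np.ndarray | None = None

    def __call__(self, q_in: Tensor, kv_in: Tensor,
                 key_mask: np.ndarray | None = None) -> Tensor:
        Tq = q_in.shape[0]
        Tk = kv_in.shape[0]
        h, dh = self.n_heads, self.dh
        q = self.wq(q_in).reshape(Tq, h, dh).transpose(1, 0, 2)
        k = self.wk(kv_in).reshape(Tk, h, dh).transpose(1, 0, 2)
        v = self.wv(kv_in).reshape(Tk, h, dh).transpose(1, 0, 2)
        scores = (q @ k.transpose(0, 2, 1)) * (dh ** -0.5)    # (h, Tq, Tk)
        if key_mask is not None:
            bias = np.where(np.asarray(key_mask, bool), 0.0, _NEG_INF)
            scores = scores + bias[None, None, :]
        attn = scores.softmax(axis=-1)
        self.last_weights = attn.data.copy()
        out = (attn @ v).transpose(1, 0, 2).reshape(Tq, self.d)
        return self.wo(out)


class _FFN(Module):
    def __init__(self, d: int, rng, mult: int = 2):
        self.fc1 = Linear(d, mult * d, rng)
        self.fc2 = Linear(mult * d, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class TransformerBlock(Module):
    """Pre-norm residual block: x + MHA(LN x), then x + FFN(LN x)."""

    def __init__(self, d: int, n_heads: int, rng):
        self.ln1 = LayerNorm(d)
        self.attn = MultiHeadAttention(d, n_heads, rng)
        self.ln2 = LayerNorm(d)
        self.ffn = _FFN(d, rng)

    def __call__(self, x: Tensor, key_mask: np.ndarray | None = None) -> Tensor:
        h = self.ln1(x)
        x = x + self.attn(h, h, key_mask=key_mask)
        x = x + self.ffn(self.ln2(x))
        return x


class PoolingAttention(Module):
    """Attention pooling of a set: a learnable token queries the members.

    The token is a query only — it is never among the keys — so the
    softmax weights over the members sum to one and serve directly as
    per-member importance scores. Pooling is permutation-invariant, and
    duplicated members share the mass their original carried.
    """

    def __init__(self, d: int, n_heads: int, rng):
        self.token = Parameter(rng.normal(0.0, 0.02, size=(1, d)))
        self.ln_q = LayerNorm(d)
        self.ln_kv = LayerNorm(d)
        self.attn = MultiHeadAttention(d, n_heads, rng)
        self.ln_out = LayerNorm(d)
        self.ffn = _FFN(d, rng)

    def __call__(self, members: Tensor) -> Tensor:
        q = self.token + self.attn(self.ln_q(self.token), self.ln_kv(members))
        q = q + self.ffn(self.ln_out(q))
        return q.reshape(q.shape[-1])

    def member_weights(self) -> np.ndarray:
        """Head-averaged softmax weights of the last call, shape (n,)."""
        return self.attn.last_weights.mean(axis=0)[0]


class MLP(Module):
    """Plain fully connected stack with ReLU between layers."""

    def __init__(self, widths: list[int], rng):
        self.layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


class Adam:
    """Adam optimiser (bias-corrected first/second moments)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
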