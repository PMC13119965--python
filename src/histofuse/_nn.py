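"""Neural-network building blocks (layers, initializers, Adam) on the autodiff engine.

Initialization is He-uniform for rectifier layers, drawn from an explicit
``numpy.random.Generator`` so that a single seed determines every parameter.
All layers follow the train/eval convention: dropout and batch statistics are
active only in training mode; inference is deterministic.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import DTYPE, Tensor, concat

__all__ = [
    "Dense",
    "Conv2d",
    "BatchNorm1d",
    "BatchNorm2d",
    "Adam",
    "dropout",
    "log_softmax",
    "softmax",
    "cross_entropy",
    "l2_normalize_rows",
]


def _he_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable parameter arrays (views, not copies)."""
        return [p.data for p in self.parameters()]

    def _norm_modules(self) -> list["_BatchNorm"]:
        mods: list[_BatchNorm] = []
        for value in vars(self).values():
            if isinstance(value, _BatchNorm):
                mods.append(value)
            elif isinstance(value, Module):
                mods.extend(value._norm_modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item._norm_modules())
                    elif isinstance(item, tuple):
                        for sub in item:
                            if isinstance(sub, Module):
                                mods.extend(sub._norm_modules())
        return mods

    def norm_state(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Snapshot of every batch-norm submodule's running statistics."""
        return [(m.running_mean.copy(), m.running_var.copy()) for m in self._norm_modules()]

    def set_norm_state(self, state) -> None:
        mods = self._norm_modules()
        if len(mods) != len(state):
            raise ValueError("norm-state length mismatch")
        for m, (mu, var) in zip(mods, state):
            m.running_mean = mu.copy()
            m.running_var = var.copy()


class Dense(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Tensor(_he_uniform(rng, in_dim, (in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


_CONV_IDX_CACHE: dict[tuple, np.ndarray] = {}


def _conv_indices(c: int, h: int, w: int, k: int, pad: int) -> np.ndarray:
    """Flat gather indices for same-size k x k convolution; out-of-bounds
    positions map to a trailing zero slot (index c*h*w)."""
    key = (c, h, w, k, pad)
    cached = _CONV_IDX_CACHE.get(key)
    if cached is not None:
        return cached
    zero_slot = c * h * w
    rows = np.arange(h)[:, None, None, None, None] - pad + np.arange(k)[None, None, :, None, None]
    cols = np.arange(w)[None, :, None, None, None] - pad + np.arange(k)[None, None, None, :, None]
    chan = np.arange(c)[None, None, None, None, :]
    valid = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    flat = chan * (h * w) + rows * w + cols
    flat = np.where(valid, flat, zero_slot)
    # (h, w, k, k, c) -> (h*w, c*k*k) with channel-major patch layout
    idx = np.broadcast_to(flat, (h, w, k, k, c)).transpose(0, 1, 4, 2, 3).reshape(h * w, c * k * k)
    _CONV_IDX_CACHE[key] = np.ascontiguousarray(idx)
    return _CONV_IDX_CACHE[key]


class Conv2d(Module):
    """3x3 (or k x k) same-padding, stride-1 convolution via im2col gather."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 kernel_size: int = 3):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Tensor(_he_uniform(rng, fan_in, (fan_in, out_channels)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        k = self.kernel_size
        idx = _conv_indices(c, h, w, k, k // 2)
        flat = x.reshape(n, c * h * w)
        flat = concat([flat, Tensor(np.zeros((n, 1), dtype=DTYPE))], axis=1)
        patches = flat.gather_cols(idx)              # (n, h*w, c*k*k)
        patches = patches.reshape(n * h * w, c * k * k)
        out = patches @ self.weight + self.bias      # (n*h*w, F)
        return out.reshape(n, h, w, self.out_channels).transpose(0, 3, 1, 2)


class _BatchNorm(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(num_features, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def _normalize(self, x: Tensor, axes: tuple, shape: tuple, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(-1)).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(-1)).astype(DTYPE)
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        inv = (var + DTYPE(self.eps)).sqrt()
        g = self.gamma.reshape(*shape)
        b = self.beta.reshape(*shape)
        return (x - mu) / inv * g + b


class BatchNorm1d(_BatchNorm):
    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return self._normalize(x, (0,), (1, -1), training)


class BatchNorm2d(_BatchNorm):
    def __call__(self, x: Tensor, training: bool) -> Tensor:
        c = x.shape[1]
        return self._normalize(x, (0, 2, 3), (1, c, 1, 1), training)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p).astype(DTYPE) / DTYPE(1.0 - p)
    return x * Tensor(keep)


def log_softmax(logits: Tensor) -> Tensor:
    shift = logits - Tensor(logits.data.max(axis=1, keepdims=True))
    lse = shift.exp().sum(axis=1, keepdims=True).log()
    return shift - lse


def softmax(logits: Tensor) -> Tensor:
    return log_softmax(logits).exp()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    lp = log_softmax(logits)
    onehot = np.zeros(lp.shape, dtype=DTYPE)
    onehot[np.arange(len(labels)), labels] = 1.0
    return -(lp * Tensor(onehot)).sum(axis=1).mean()


def l2_normalize_rows(x: Tensor, eps: float = 1e-12) -> Tensor:
    norm = ((x**2).sum(axis=1, keepdims=True) + DTYPE(eps)).sqrt()
    return x / norm


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + eps)).astype(DTYPE)
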