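"""Neural-network building blocks on top of :mod:`permutedds.autograd`.

Layers follow the usual conventions: fan-in uniform initialization
``U(-1/sqrt(fan_in), 1/sqrt(fan_in))`` drawn from a caller-supplied seeded
generator, LayerNorm with eps 1e-5 and affine parameters (gamma=1, beta=0),
and a plain Adam optimizer. ``Module.state_dict`` / ``load_state_dict``
round-trip parameters bit-identically for checkpointing.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.astype(p.data.dtype, copy=True)


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Linear(Module):
    """Affine map ``x @ W + b`` with W of shape (in_dim, out_dim)."""

    def __init__(self, in_dim, out_dim, rng, dtype=np.float64, zero_init: bool = False):
        if zero_init:
            self.weight = Parameter(np.zeros((in_dim, out_dim), dtype=dtype))
        else:
            self.weight = Parameter(_fan_in_uniform(rng, (in_dim, out_dim), in_dim, dtype))
        self.bias = Parameter(np.zeros(out_dim, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        data_ndim = x.data.ndim
        if data_ndim == 2:
            return ag.matmul(x, self.weight) + self.bias
        # fold leading axes into rows for the 2-D matmul
        lead = x.shape[:-1]
        flat = ag.reshape(x, (-1, x.shape[-1]))
        out = ag.matmul(flat, self.weight) + self.bias
        return ag.reshape(out, lead + (self.weight.shape[1],))


class Conv1d(Module):
    """Length-preserving 1-D convolution over (batch, length, channels)."""

    def __init__(self, in_channels, out_channels, kernel, rng, dtype=np.float64):
        self.kernel = kernel
        fan_in = kernel * in_channels
        self.weight = Parameter(
            _fan_in_uniform(rng, (fan_in, out_channels), fan_in, dtype)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        batch, length, _ = x.shape
        windows = ag.conv_windows(x, self.kernel)  # (B, L, k*C_in)
        flat = ag.reshape(windows, (batch * length, windows.shape[-1]))
        out = ag.matmul(flat, self.weight) + self.bias
        return ag.reshape(out, (batch, length, self.weight.shape[1]))


class LayerNorm(Module):
    def __init__(self, dim, dtype=np.float64, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Parameter(np.ones(dim, dtype=dtype))
        self.beta = Parameter(np.zeros(dim, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.layer_norm(x, self.gamma, self.beta, eps=self.eps)


class Adam:
    """Adam with bias-corrected moment estimates."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            m, v = self.m[i], self.v[i]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p.data = p.data - (self.lr / corr1) * m / (np.sqrt(v / corr2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
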