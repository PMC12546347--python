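"""Layers, parameter containers and SGD on top of the autodiff engine.

Initialization is fully seeded: every layer draws its weights from a
``numpy.random.Generator`` passed in at construction, so two builds from the
same seed are bitwise identical.  Parameters live in a flat
``name -> array`` state dict (saved as ``.npz``) for checkpointing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .engine import Tensor, conv2d


class Module:
    """Base class: child modules/parameters are discovered by attribute walk."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{key}.{i}", item

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={missing}, unexpected={extra}")
        for k, v in own.items():
            arr = np.asarray(state[k])
            if arr.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {v.data.shape}")
            v.data = arr.astype(v.data.dtype, copy=True)

    def save(self, path: str | Path) -> None:
        np.savez(str(path), **self.state_dict())

    def load(self, path: str | Path) -> None:
        with np.load(str(path)) as npz:
            self.load_state_dict({k: npz[k] for k in npz.files})

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kw):
        return self.forward(*args, **kw)


def _param(rng: np.random.Generator, shape, std: float, dtype=np.float32) -> Tensor:
    return Tensor(rng.normal(0.0, std, size=shape).astype(dtype), requires_grad=True)


class Conv2d(Module):
    """Square-kernel grouped convolution with He-normal seeded init."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int | None = None,
        groups: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.stride = stride
        self.padding = kernel_size // 2 if padding is None else padding
        self.groups = groups
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        self.weight = _param(
            rng, (out_channels, in_channels // groups, kernel_size, kernel_size),
            np.sqrt(2.0 / fan_in), dtype,
        )
        self.bias = (
            Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(
            x, self.weight, self.bias, stride=self.stride, padding=self.padding,
            groups=self.groups,
        )


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        self.weight = _param(rng, (out_features, in_features), np.sqrt(2.0 / in_features), dtype)
        self.bias = (
            Tensor(np.zeros(out_features, dtype=dtype), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        # x: [..., in_features]
        y = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            y = y + self.bias
        return y


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.layers = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class InstanceNorm(Module):
    """Per-sample, per-channel spatial normalization with affine parameters.

    Batch-size independent (important for batch-1 training) and composed
    from primitive ops, so it is differentiable without a dedicated kernel.
    """

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        self.eps = eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1), dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        m = x.mean(axis=(2, 3), keepdims=True)
        d = x - m
        v = (d * d).mean(axis=(2, 3), keepdims=True)
        return d * (v + self.eps).pow(-0.5) * self.gamma + self.beta


class SGD:
    """Stochastic gradient descent with momentum and decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0, clip_norm: float | None = 10.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        scale = 1.0
        if self.clip_norm is not None:
            total = np.sqrt(
                sum(float((p.grad ** 2).sum()) for p in self.params if p.grad is not None)
            )
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad * scale + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
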