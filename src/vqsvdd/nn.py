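"""Layers, parameter containers and the Adam optimizer.

Initialization is He-style and fully determined by the numpy Generator
passed to each layer, so a model built twice from the same seed has
bit-identical weights.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Container tracking parameters through attribute discovery."""

    def parameters(self) -> Iterator[Parameter]:
        seen: set[int] = set()
        for value in vars(self).values():
            if isinstance(value, Parameter):
                if id(value) not in seen:
                    seen.add(id(value))
                    yield value
            elif isinstance(value, Module):
                yield from value.parameters()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.parameters()
                    elif isinstance(item, Parameter):
                        yield item

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping for checkpointing."""
        out: dict[str, np.ndarray] = {}

        def walk(obj, prefix):
            for name, value in vars(obj).items():
                key = f"{prefix}{name}"
                if isinstance(value, Parameter):
                    out[key] = value.data
                elif isinstance(value, Module):
                    walk(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")
                        elif isinstance(item, Parameter):
                            out[f"{key}.{i}"] = item.data

        walk(self, "")
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)}")
        for key, arr in own.items():
            if arr.shape != state[key].shape:
                raise ValueError(f"shape mismatch for {key}: "
                                 f"{arr.shape} vs {state[key].shape}")
            arr[...] = state[key]


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 padding: int, rng: np.random.Generator):
        self.stride, self.padding = stride, padding
        std = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.weight = Parameter(rng.normal(0.0, std, (c_out, c_in, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 padding: int, rng: np.random.Generator):
        self.stride, self.padding = stride, padding
        std = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.weight = Parameter(rng.normal(0.0, std, (c_in, c_out, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv_transpose2d(self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / f_in)
        self.weight = Parameter(rng.normal(0.0, std, (f_in, f_out)))
        self.bias = Parameter(np.zeros(f_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ResidualBlock(Module):
    """Pre-activation residual block: x + conv3(lrelu(conv3(lrelu(x))))."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = Conv2d(channels, channels, 3, 1, 1, rng)
        self.conv2 = Conv2d(channels, channels, 3, 1, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.conv2(self.conv1(x.leaky_relu()).leaky_relu())


class Adam:
    """Adaptive-moment estimation over an explicit parameter list."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
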