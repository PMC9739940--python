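"""Network building blocks on the autodiff engine.

``LBR`` is the linear -> batch-normalization -> LeakyReLU unit used
throughout the encoder and heads; ``MLP2`` the two-fully-connected-layer
block of the point-mixer; ``LayerNorm`` the pre-mixing normalizer.  All
parameters are float64 tensors initialized from an explicit RNG so runs are
bit-reproducible on CPU.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor, leaky_relu, mean_axis, sqrt, sum_axis

__all__ = ["Module", "Linear", "BatchNorm", "LayerNorm", "LBR", "MLP2", "Dropout"]


class Module:
    """Parameter container with recursive traversal and train/eval modes."""

    training: bool = True

    def parameters(self) -> Iterator[Tensor]:
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                yield value
            elif isinstance(value, Module):
                yield from value.parameters()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.parameters()

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, flag: bool = True) -> "Module":
        for m in self.modules():
            m.training = flag
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array map of parameters and buffers (for checkpoints)."""
        out: dict[str, np.ndarray] = {}

        def walk(obj: "Module", prefix: str) -> None:
            for name, value in vars(obj).items():
                key = f"{prefix}{name}"
                if isinstance(value, Tensor):
                    out[key] = value.data
                elif isinstance(value, np.ndarray):
                    out[key] = value
                elif isinstance(value, Module):
                    walk(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")

        walk(self, "")
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        current = self.state_arrays()
        missing = set(current) - set(arrays)
        if missing:
            raise ValueError(f"checkpoint is missing arrays: {sorted(missing)[:5]}...")

        def walk(obj: "Module", prefix: str) -> None:
            for name, value in vars(obj).items():
                key = f"{prefix}{name}"
                if isinstance(value, Tensor):
                    value.data = np.asarray(arrays[key], dtype=np.float64).reshape(value.shape)
                elif isinstance(value, np.ndarray):
                    setattr(obj, name, np.asarray(arrays[key], dtype=value.dtype).reshape(value.shape))
                elif isinstance(value, Module):
                    walk(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")

        walk(self, "")


class Linear(Module):
    """Affine map on the last axis, Kaiming-uniform initialized."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / d_in)
        self.weight = Tensor(rng.uniform(-bound, bound, (d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm(Module):
    """Normalization over all leading axes, per channel (last axis).

    Training mode normalizes with batch statistics and updates running
    moments; eval mode uses the running moments, so eval outputs are
    deterministic functions of the parameters.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = mean_axis(x, axis=0) if x.ndim == 2 else _mean_over(x, axes)
            xc = x - mu
            var = _mean_over(xc * xc, axes) if x.ndim != 2 else mean_axis(xc * xc, axis=0)
            n = int(np.prod([x.shape[a] for a in axes]))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data.reshape(-1)
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
            return self.gamma * (xc / sqrt(var + self.eps)) + self.beta
        xh = (x - self.running_mean) * (1.0 / np.sqrt(self.running_var + self.eps))
        return self.gamma * xh + self.beta


def _mean_over(x: Tensor, axes: tuple[int, ...]) -> Tensor:
    out = x
    for a in sorted(axes, reverse=True):
        out = mean_axis(out, axis=a)
    return out


class LayerNorm(Module):
    """Normalization over the last axis with learned affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = mean_axis(x, axis=-1, keepdims=True)
        xc = x - mu
        var = mean_axis(xc * xc, axis=-1, keepdims=True)
        return self.gamma * (xc / sqrt(var + self.eps)) + self.beta


class LBR(Module):
    """Linear -> BatchNorm -> LeakyReLU, the standard unit of the network."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, negative_slope: float = 0.01):
        self.linear = Linear(d_in, d_out, rng)
        self.bn = BatchNorm(d_out)
        self.negative_slope = negative_slope

    def __call__(self, x: Tensor) -> Tensor:
        return leaky_relu(self.bn(self.linear(x)), self.negative_slope)


class MLP2(Module):
    """Two fully connected layers with a LeakyReLU between (mixer MLP block)."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng: np.random.Generator,
                 negative_slope: float = 0.01):
        self.fc1 = Linear(d_in, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_out, rng)
        self.negative_slope = negative_slope

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(leaky_relu(self.fc1(x), self.negative_slope))


class Dropout(Module):
    """Inverted dropout driven by an explicit RNG for reproducible masks."""

    def __init__(self, p: float = 0.5):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an RNG")
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)
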