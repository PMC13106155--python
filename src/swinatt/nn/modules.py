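"""Layers, containers and the SGD optimizer used by the classifier.

Modules register parameters, buffers and sub-modules through attribute
assignment (``self.fc = Linear(...)``), mirroring the convention of the
major deep-learning frameworks so the backbone code reads familiarly.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Parameter, Tensor, gelu, matmul

__all__ = [
    "Module",
    "ModuleList",
    "Linear",
    "LayerNorm",
    "BatchNorm2d",
    "Mlp",
    "SGD",
    "trunc_normal",
]


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal draws re-sampled into [-2*std, 2*std] (rejection by clipping)."""
    values = rng.normal(0.0, std, size=shape)
    return np.clip(values, -2.0 * std, 2.0 * std)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=np.float64)
        object.__setattr__(self, name, self._buffers[name])

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=np.float64)
        object.__setattr__(self, name, self._buffers[name])

    # ------------------------------------------------------------- traversal
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, param in self._params.items():
            yield prefix + name, param
        for name, module in self._modules.items():
            yield from module.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, self._buffers[name]
        for name, module in self._modules.items():
            yield from module.named_buffers(prefix + name + ".")

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for module in self._modules.values():
            module.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # ---------------------------------------------------------- persistence
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buffer:" + n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, value in state.items():
            if name.startswith("buffer:"):
                self._assign_buffer(name[len("buffer:"):], value)
            else:
                if name not in params:
                    raise KeyError(f"unknown parameter {name!r}")
                if params[name].shape != value.shape:
                    raise ValueError(f"shape mismatch for {name!r}")
                params[name].data = np.asarray(value, dtype=np.float64).copy()

    def _assign_buffer(self, dotted: str, value: np.ndarray) -> None:
        module = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            module = module._modules[part]
        if parts[-1] not in module._buffers:
            raise KeyError(f"unknown buffer {dotted!r}")
        module._set_buffer(parts[-1], value)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, module: Module) -> None:
        self._modules[str(len(self._list))] = module
        self._list.append(module)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, index):
        return self._list[index]


class Linear(Module):
    """Affine map on the trailing axis: ``y = x @ W.T + b``."""

    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, std: float = 0.02):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(trunc_normal(rng, (out_features, in_features), std))
        self.bias = Parameter(np.zeros(out_features)) if bias else None
        self.in_features = in_features
        self.out_features = out_features

    def forward(self, x: Tensor) -> Tensor:
        out = matmul(x, self.weight.transpose(1, 0))
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered / (var + self.eps).sqrt()
        return normed * self.weight + self.bias


class BatchNorm2d(Module):
    """Per-channel normalization over (N, H, W) of an (N, C, H, W) map.

    Batch statistics in train mode; exponentially averaged running
    statistics (momentum 0.1) in eval mode, unbiased variance stored.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))
        self.momentum = momentum
        self.eps = eps
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != self.channels:
            raise ValueError(
                f"expected (N, {self.channels}, H, W) input, got {x.shape}")
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            n = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self._set_buffer("running_mean",
                             (1 - self.momentum) * self.running_mean
                             + self.momentum * mu.data.reshape(-1))
            self._set_buffer("running_var",
                             (1 - self.momentum) * self.running_var
                             + self.momentum * unbiased)
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
            centered = x - mu
        normed = centered / (var + self.eps).sqrt()
        return normed * self.weight.reshape(1, -1, 1, 1) + self.bias.reshape(1, -1, 1, 1)


class Mlp(Module):
    """Two-layer feed-forward block with GELU, as used inside each stage."""

    def __init__(self, dim: int, hidden_dim: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(dim, hidden_dim, rng=rng)
        self.fc2 = Linear(hidden_dim, dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


class SGD:
    """Stochastic gradient descent with momentum and (coupled) weight decay.

    Update per parameter p: ``d = grad + wd * p; v = mu * v + d; p -= lr * v``.
    """

    def __init__(self, params: list[Parameter], lr: float,
                 momentum: float = 0.0, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                grad = np.zeros_like(p.data)
            else:
                grad = p.grad
            d = grad + self.weight_decay * p.data
            v *= self.momentum
            v += d
            p.data = p.data - self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
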