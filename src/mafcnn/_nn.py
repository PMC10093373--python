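"""Neural-network building blocks over the autodiff core.

Initialisation draws from a caller-supplied `numpy.random.Generator` so that
every network built with the same seed is bit-identical.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor

__all__ = ["Module", "Conv2d", "BatchNorm2d", "Linear", "Dropout", "ReLU",
           "Sequential", "SGD"]


class Module:
    """Base class: tracks parameters and sub-modules, toggles train/eval."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for name, m in self._modules.items():
            out.extend(m.named_parameters(prefix + name + "."))
        return out

    def modules(self) -> list["Module"]:
        out = [self]
        for m in self._modules.values():
            out.extend(m.modules())
        return out

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {n: p.data.copy() for n, p in self.named_parameters()}
        d.update({n: b.copy() for n, b in self._named_buffers("")})
        return d

    def _named_buffers(self, prefix: str) -> list[tuple[str, np.ndarray]]:
        out = [(prefix + k, v) for k, v in self._buffers().items()]
        for name, m in self._modules.items():
            out.extend(m._named_buffers(prefix + name + "."))
        return out

    def load_state_dict(self, d: dict[str, np.ndarray]):
        for n, p in self.named_parameters():
            p.data = np.asarray(d[n], dtype=np.float64).copy()
        self._load_buffers(d, "")
        return self

    def _buffers(self) -> dict[str, np.ndarray]:
        return {}

    def _load_buffers(self, d, prefix):
        for k in self._buffers():
            setattr(self, k, np.asarray(d[prefix + k], dtype=np.float64).copy())
        for name, m in self._modules.items():
            m._load_buffers(d, prefix + name + ".")

    def __call__(self, x):
        return self.forward(x)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, stride: int = 1,
                 padding: int = 0, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator):
        super().__init__()
        if in_ch % groups or out_ch % groups:
            raise ValueError("channels must be divisible by groups")
        fan_in = (in_ch // groups) * kernel * kernel
        self.weight = Tensor(_kaiming(rng, (out_ch, in_ch // groups, kernel, kernel),
                                      fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding, groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros((1, channels, 1, 1))
        self.running_var = np.ones((1, channels, 1, 1))

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
            xhat = xc / (var + self.eps).sqrt()
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps))
        return xhat * self.gamma + self.beta


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator, init_std: float | None = None):
        super().__init__()
        if init_std is None:
            w = _kaiming(rng, (in_features, out_features), in_features)
        else:
            w = rng.normal(0.0, init_std, (in_features, out_features))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Dropout(Module):
    """Inverted dropout; the mask comes from the generator handed to the
    trainer so runs are reproducible."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if self.rng is None:
            raise RuntimeError("dropout used in training mode without an rng")
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p.data) for p in params]

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
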