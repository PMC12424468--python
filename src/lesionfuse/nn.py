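"""Neural-network building blocks on top of the autodiff engine.

Layers follow the familiar conventions: NCHW feature maps, fan-in scaled
initialization, batch-norm with running statistics, inverted dropout.  Every
module owns a ``training`` flag toggled recursively by ``train()``/``eval()``.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, conv2d, max_pool2d

__all__ = [
    "Module", "Linear", "Conv2d", "BatchNorm2d", "Dropout",
    "ReLU", "LeakyReLU", "Sequential", "Adam",
]


class Module:
    """Base class: parameter registration by attribute discovery."""

    def __init__(self):
        self.training = True

    # -- parameter / submodule discovery -----------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield (f"{prefix}{name}", value)
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield (f"{prefix}{name}.{i}", item)

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

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
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        # batch-norm running statistics are state but not parameters
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bn{i}.running_mean"] = m.running_mean.copy()
                state[f"__bn{i}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        bn_keys = {}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                bn_keys[f"__bn{i}.running_mean"] = (m, "running_mean")
                bn_keys[f"__bn{i}.running_var"] = (m, "running_var")
        expected = set(own) | set(bn_keys)
        if expected != set(state):
            missing = expected - set(state)
            unexpected = set(state) - expected
            raise ValueError(
                f"incompatible state: missing={sorted(missing)!r} "
                f"unexpected={sorted(unexpected)!r}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: "
                    f"expected {p.data.shape}, got {arr.shape}")
            p.data = arr.copy()
        for key, (m, attr) in bn_keys.items():
            setattr(m, attr, np.asarray(state[key], dtype=np.float32).copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        scale = 1.0 / np.sqrt(in_features)
        self.weight = _param(rng, (in_features, out_features), scale)
        self.bias = _param(rng, (out_features,), scale) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        shape = x.shape
        if len(shape) > 2:                     # apply to the last axis
            out = x.reshape(-1, shape[-1]) @ self.weight
            if self.bias is not None:
                out = out + self.bias
            return out.reshape(*shape[:-1], self.weight.shape[1])
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size
        scale = 1.0 / np.sqrt(fan_in)
        self.weight = _param(
            rng, (out_channels, in_channels, kernel_size, kernel_size), scale)
        self.bias = _param(rng, (out_channels,), scale) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.num_batches = 0

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            # seed the running statistics from the first batch so that short
            # training runs are not biased towards the (0, 1) initialization
            m = 1.0 if self.num_batches == 0 else self.momentum
            self.num_batches += 1
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.ravel())
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.ravel())
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class Dropout(Module):
    """Inverted dropout; identity in eval mode or at p == 0."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1): {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask.astype(np.float32))


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel, self.stride, self.padding)


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
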